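"""Synthetic-data generators with recorded ground truth.

Every downstream stage of the package (duplication labeling, breakpoint
detection, dN/dS estimation, the correlation layer) consumes data of the
kind generated here, so each simulator records the truth it planted:

* :func:`simulate_species_tree` — pure-birth (Yule) ultrametric species tree;
* :func:`simulate_gene_family` — birth–death gene duplication/loss along the
  species tree, recording every duplication that leaves >= 2 surviving
  descendant lineages;
* :func:`simulate_codon_pair` — two coding sequences diverged from a common
  ancestor under a GY94-style codon model with known omega, kappa and t;
* :func:`simulate_gene_orders` — gene orders rearranged from a reference by
  inversions/translocations/swaps, recording the broken adjacencies;
* :func:`simulate_ratio_dataset` — (x, y) pairs with a known linear signal.

All simulators are pure functions of their arguments including the seed:
each call builds its own ``numpy.random.Generator``; no global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from Bio.Data import CodonTable


class SimulationFailure(RuntimeError):
    """All gene lineages went extinct (after the retry cap)."""


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeSim:
    """Ultrametric species tree plus the pairwise divergence-time table."""

    tree: dendropy.Tree
    divergence_times: dict[frozenset, float]
    seed: int

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def simulate_species_tree(n_taxa: int, birth_rate: float, seed: int) -> SpeciesTreeSim:
    """Simulate a pure-birth (Yule) ultrametric species tree.

    Lineages split at rate ``birth_rate`` each; after the ``n_taxa``-th
    lineage appears, all tips are extended by one further exponential
    waiting time so terminal branches have positive length.  Leaf labels
    are ``T01, T02, ...`` in order of appearance.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed)

    # grow the tree forward in time; active = (node, time-of-birth)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    t_now = 0.0
    active: list[tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    while len(active) < n_taxa:
        k = len(active)
        t_now += rng.exponential(1.0 / (birth_rate * k))
        idx = rng.integers(k)
        node, born = active.pop(idx)
        node.edge.length = t_now - born
        kids = [dendropy.Node(), dendropy.Node()]
        for c in kids:
            node.add_child(c)
        active.extend((c, t_now) for c in kids)
    t_end = t_now + rng.exponential(1.0 / (birth_rate * n_taxa))
    # deterministic label order: by preorder position of the tips
    tips = [nd for nd, _ in active]
    born_of = dict(active)
    order = {nd: i for i, nd in enumerate(tree.preorder_node_iter())}
    tips.sort(key=order.get)
    width = max(2, len(str(n_taxa)))
    for i, nd in enumerate(tips, start=1):
        nd.edge.length = t_end - born_of[nd]
        nd.taxon = taxa.new_taxon(label=f"T{i:0{width}d}")

    div = _divergence_times(tree, t_end)
    return SpeciesTreeSim(tree=tree, divergence_times=div, seed=seed)


def _divergence_times(tree: dendropy.Tree, depth: float) -> dict[frozenset, float]:
    """Age of the MRCA for every leaf pair (time before the present)."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    out: dict[frozenset, float] = {}
    for node in tree.postorder_internal_node_iter():
        age = depth - node.root_distance
        kids = node.child_nodes()
        for c1, c2 in itertools.combinations(kids, 2):
            for l1 in c1.leaf_iter():
                for l2 in c2.leaf_iter():
                    out[frozenset((l1.taxon.label, l2.taxon.label))] = age
    return out


# ---------------------------------------------------------------------------
# gene families (birth-death duplication/loss inside the species tree)
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilySim:
    """Gene tree evolved inside a species tree, with duplication truth.

    ``true_duplication_nodes`` holds the labels of internal gene-tree nodes
    created by a duplication event with >= 2 surviving descendant lineages
    (the tree-visible duplications, i.e. what reconciliation can recover).
    ``events`` maps each such node label to the species-tree node whose
    parent edge hosted the event (useful for leaf-count bookkeeping).
    """

    gene_tree: dendropy.Tree
    true_duplication_nodes: set[str]
    events: dict[str, str] = field(default_factory=dict)
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    seed: int = 0

    @property
    def newick(self) -> str:
        return self.gene_tree.as_string(schema="newick", suppress_rooting=True).strip()


class _GNode:
    __slots__ = ("children", "length", "label", "is_dup", "species_head")

    def __init__(self, length: float = 0.0):
        self.children: list[_GNode] = []
        self.length = length
        self.label: str | None = None
        self.is_dup = False
        self.species_head: str | None = None


def simulate_gene_family(
    sp: SpeciesTreeSim,
    dup_rate: float,
    loss_rate: float,
    seed: int,
    max_retries: int = 100,
) -> GeneFamilySim:
    """Evolve one gene family by birth-death along the species tree.

    A single gene lineage enters at the species-tree root.  Along each
    species branch a lineage duplicates at ``dup_rate`` and dies at
    ``loss_rate`` (both per unit branch time); at each species-tree split
    every surviving lineage speciates into one copy per descendant branch.
    Extinct subtrees are pruned and unary nodes suppressed; duplication
    nodes retaining two sides become the recorded truth.

    If every lineage dies, the simulation is retried with seed+1, up to
    ``max_retries`` times; total extinction after that raises
    :class:`SimulationFailure`.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    for attempt in range(max_retries + 1):
        s = int((seed + attempt) % (2**31 - 1))
        rng = np.random.default_rng(s)
        root = _evolve_gene_edge(sp.tree.seed_node, 0.0, dup_rate, loss_rate, rng)
        root = _prune_dead(root)
        if root is not None:
            break
    else:  # pragma: no cover - loop always breaks or exhausts
        root = None
    if root is None:
        raise SimulationFailure(
            f"all gene lineages extinct after {max_retries} retries (seed={seed})"
        )

    tree, dup_labels, events = _to_dendropy(root)
    return GeneFamilySim(
        gene_tree=tree,
        true_duplication_nodes=dup_labels,
        events=events,
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        seed=seed,
    )


def _evolve_gene_edge(sp_node, t_edge: float, d: float, l: float, rng) -> _GNode:
    """One gene lineage entering the species branch above ``sp_node``
    with ``t_edge`` time remaining on that branch."""
    node = _GNode()
    total = d + l
    t_left = t_edge
    elapsed = 0.0
    while total > 0:
        wait = rng.exponential(1.0 / total)
        if wait >= t_left:
            break
        elapsed += wait
        t_left -= wait
        if rng.random() < d / total:  # duplication
            node.length = elapsed
            node.is_dup = True
            node.species_head = _sp_label(sp_node)
            for _ in range(2):
                node.children.append(_evolve_gene_edge(sp_node, t_left, d, l, rng))
            return node
        # loss: lineage dies on this branch
        node.length = elapsed
        node.children = []
        node.label = None
        node.is_dup = False
        node.species_head = "__dead__"
        return node
    # reached the bottom of the species branch
    node.length = elapsed + t_left
    if sp_node.is_leaf():
        node.label = sp_node.taxon.label  # gene id appended later
    else:
        for child in sp_node.child_nodes():
            node.children.append(
                _evolve_gene_edge(child, child.edge.length, d, l, rng)
            )
        node.species_head = _sp_label(sp_node)
    return node


def _sp_label(sp_node) -> str:
    if sp_node.taxon is not None:
        return sp_node.taxon.label
    if sp_node.label is None:
        # stable synthetic label: preorder index within its tree
        tree = sp_node  # walk up to root to enumerate once
        while tree.parent_node is not None:
            tree = tree.parent_node
        for i, nd in enumerate(tree.preorder_iter()):
            if nd.label is None and nd.taxon is None:
                nd.label = f"sp{i}"
    return sp_node.label


def _prune_dead(node: _GNode) -> _GNode | None:
    """Remove extinct subtrees, suppress unary nodes; None if all dead."""
    if not node.children:
        return None if node.species_head == "__dead__" else node
    kept = []
    for c in node.children:
        p = _prune_dead(c)
        if p is not None:
            kept.append(p)
    if not kept:
        return None
    if len(kept) == 1:
        only = kept[0]
        only.length += node.length
        return only
    node.children = kept
    return node


def _to_dendropy(root: _GNode):
    """Convert to a dendropy tree; label nodes, collect duplication truth."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    dup_labels: set[str] = set()
    events: dict[str, str] = {}
    counters: dict[str, int] = {}
    n_internal = 0

    def build(g: _GNode, d_node):
        nonlocal n_internal
        d_node.edge.length = g.length
        if not g.children:
            counters[g.label] = counters.get(g.label, 0) + 1
            d_node.taxon = taxa.new_taxon(label=f"{g.label}|g{counters[g.label]}")
            return
        n_internal += 1
        lab = f"nd{n_internal}"
        d_node.label = lab
        if g.is_dup:
            dup_labels.add(lab)
            events[lab] = g.species_head
        for c in g.children:
            child = dendropy.Node()
            d_node.add_child(child)
            build(c, child)

    build(root, tree.seed_node)
    return tree, dup_labels, events


# ---------------------------------------------------------------------------
# codon pairs (GY94-style forward simulation)
# ---------------------------------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _STANDARD.forward_table if len(c) == 3 and set(c) <= set("ACGT"))
)
_AA = {c: _STANDARD.forward_table[c] for c in SENSE_CODONS}
_PURINES = {"A", "G"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES) == (y in _PURINES)


def gy94_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """GY94-style 61x61 rate matrix, uniform codon frequencies.

    Single-nucleotide changes only; transitions scaled by kappa,
    nonsynonymous changes by omega; stop codons inaccessible.  Normalized
    to one expected substitution per codon per unit time.
    """
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            rate = 1.0
            if _is_transition(*diffs[0]):
                rate *= kappa
            if _AA[a] != _AA[b]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.mean(np.diag(Q))  # uniform frequencies
    if mu > 0:
        Q /= mu
    return Q


@dataclass
class CodonPairSim:
    """A pair of coding sequences with known divergence parameters."""

    seq_a: str
    seq_b: str
    true_omega: float
    true_t: float
    true_kappa: float
    seed: int

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


def simulate_codon_pair(
    omega: float, t: float, kappa: float, n_codons: int, seed: int
) -> CodonPairSim:
    """Simulate two sequences diverged for total time ``t``.

    The ancestor is drawn uniformly over the 61 sense codons per site and
    each descendant evolves independently for t/2 under
    :func:`gy94_rate_matrix`, so ``t`` is the expected number of
    substitutions per codon separating the pair (at omega = kappa = 1).
    """
    if omega < 0 or t < 0 or kappa <= 0:
        raise ValueError("need omega >= 0, t >= 0, kappa > 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    anc = rng.integers(len(SENSE_CODONS), size=n_codons)
    if t == 0:
        a = b = anc
    else:
        P = expm(gy94_rate_matrix(omega, kappa) * (t / 2.0))
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        a = _sample_rows(cum, anc, rng)
        b = _sample_rows(cum, anc, rng)
    to_str = lambda idx: "".join(SENSE_CODONS[i] for i in idx)  # noqa: E731
    return CodonPairSim(
        seq_a=to_str(a), seq_b=to_str(b),
        true_omega=omega, true_t=t, true_kappa=kappa, seed=seed,
    )


def _sample_rows(cum: np.ndarray, states: np.ndarray, rng) -> np.ndarray:
    u = rng.random(states.shape[0])
    return np.array(
        [np.searchsorted(cum[s], x, side="right") for s, x in zip(states, u)]
    ).clip(0, cum.shape[1] - 1)


# ---------------------------------------------------------------------------
# gene orders
# ---------------------------------------------------------------------------

@dataclass
class GeneOrderSim:
    """Rearranged gene orders with the planted broken adjacencies."""

    reference_order: list[str]
    target_orders: dict[str, list[str]]
    planted_breakpoints: dict[str, set[frozenset]]
    seed: int


def _apply_op(order: list[str], op: tuple) -> list[str]:
    name, *args = op
    n = len(order)
    out = list(order)
    if name == "inversion":
        i, j = args
        if not (0 <= i <= j < n):
            raise ValueError(f"inversion indices out of range: {op}")
        out[i : j + 1] = reversed(out[i : j + 1])
    elif name == "swap":
        i, j = args
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"swap indices out of range: {op}")
        out[i], out[j] = out[j], out[i]
    elif name == "translocation":
        # move the segment [i, j] so it starts at position k of the remainder
        i, j, k = args
        if not (0 <= i <= j < n):
            raise ValueError(f"translocation indices out of range: {op}")
        seg = out[i : j + 1]
        rest = out[:i] + out[j + 1 :]
        if not (0 <= k <= len(rest)):
            raise ValueError(f"translocation insertion point out of range: {op}")
        out = rest[:k] + seg + rest[k:]
    else:
        raise ValueError(f"unknown rearrangement op: {name!r}")
    return out


def adjacency_set(order: list[str]) -> set[frozenset]:
    """Unsigned adjacency set of a gene order (orientation ignored)."""
    return {frozenset(p) for p in zip(order, order[1:])}


def simulate_gene_orders(
    n_genes: int,
    species_ops: dict[str, list[tuple]],
    seed: int = 0,
    gene_prefix: str = "g",
) -> GeneOrderSim:
    """Apply per-species rearrangement ops to a reference gene order.

    The reference is ``g1..gN``; each species' target order is the result
    of its op list applied in sequence; ``planted_breakpoints[s]`` is the
    set of reference adjacencies (unordered pairs) no longer adjacent in
    the target — the ground truth for breakpoint detection.
    """
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4")
    reference = [f"{gene_prefix}{i}" for i in range(1, n_genes + 1)]
    ref_adj = adjacency_set(reference)
    targets, planted = {}, {}
    for species, ops in species_ops.items():
        order = list(reference)
        for op in ops:
            order = _apply_op(order, op)
        targets[species] = order
        planted[species] = ref_adj - adjacency_set(order)
    return GeneOrderSim(
        reference_order=reference,
        target_orders=targets,
        planted_breakpoints=planted,
        seed=seed,
    )


def random_inversion_ops(
    n_genes: int, k: int, rng: np.random.Generator, min_gap: int = 1
) -> list[tuple]:
    """k interior, pairwise non-adjacent inversions (each plants 2 breakpoints).

    Segments are drawn inside (0, n_genes-1) and kept >= ``min_gap`` apart
    so their breakpoints never coincide or touch.
    """
    for _ in range(1000):
        cuts = np.sort(rng.choice(np.arange(1, n_genes - 1), size=2 * k, replace=False))
        pairs = cuts.reshape(k, 2)
        gaps = pairs[1:, 0] - pairs[:-1, 1] if k > 1 else np.array([min_gap + 1])
        if np.all(gaps > min_gap):
            return [("inversion", int(i), int(j)) for i, j in pairs]
    raise ValueError(f"cannot place {k} non-adjacent inversions in {n_genes} genes")


# ---------------------------------------------------------------------------
# linear ratio pairs
# ---------------------------------------------------------------------------

def simulate_ratio_dataset(
    n: int, slope: float, intercept: float, noise_sd: float, seed: int
) -> pd.DataFrame:
    """(x, y) pairs with x ~ U(0,1) and y = slope*x + intercept + N(0, sd)."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame({"x": x, "y": y})
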
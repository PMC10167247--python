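"""Gene-tree statistics: duplication labeling, duplication ratio, congruence.

The central statistic is the *duplication ratio* of a gene-family tree:
the number of internal nodes labeled as gene duplications divided by the
total number of (internal) nodes.  Duplications are labeled with the
deterministic species-overlap criterion: an internal node is a duplication
if and only if at least two of its child subtrees contain the same species
— the signature left by a duplication that predates the divergence of
those species.

Congruence utilities: Robinson–Foulds distance between topologies, Fitch
parsimony length, and a permutation-based incongruence-length-difference
(ILD) test between two character partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class UndefinedRatioError(ZeroDivisionError):
    """Ratio requested over an empty node set."""


DEFAULT_DELIMITER = "|"


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def read_newick(text: str, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Parse one Newick tree; raises :class:`NewickParseError` on bad input."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise NewickParseError("malformed Newick: no leaves parsed")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# species-overlap duplication labeling
# ---------------------------------------------------------------------------

@dataclass
class DuplicationAnnotation:
    """Per-internal-node duplication/speciation labels plus the counts.

    ``flags`` maps a node key (the node's label, or ``nd{postorder index}``
    for unlabeled nodes) to True for duplication, False for speciation.
    """

    flags: dict[str, bool]
    duplication_count: int
    n_internal: int
    n_all: int
    species_sets: dict[str, frozenset] = field(default_factory=dict, repr=False)

    @property
    def node_total(self) -> int:
        return self.n_internal

    @property
    def ratio(self) -> float:
        return duplication_ratio(self)


def leaf_species(label: str, species_map: dict[str, str] | None, delimiter: str) -> str:
    if species_map is not None:
        if label not in species_map:
            raise ValueError(f"leaf {label!r} missing from the species map")
        return species_map[label]
    if delimiter not in label:
        raise ValueError(
            f"leaf {label!r} has no {delimiter!r} delimiter and no species map was given"
        )
    return label.split(delimiter, 1)[0]


def node_key(node: dendropy.Node, index: int) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label if node.label else f"nd{index}"


def species_overlap_labels(
    gene_tree: dendropy.Tree,
    species_map: dict[str, str] | None = None,
    delimiter: str = DEFAULT_DELIMITER,
) -> DuplicationAnnotation:
    """Label every internal node duplication/speciation by species overlap.

    A node is a duplication iff the species sets of at least two of its
    child subtrees intersect (multifurcations included: ANY overlapping
    pair suffices).  Leaf species come from ``species_map`` or, if none is
    given, from the prefix before ``delimiter`` in the leaf label.
    """
    flags: dict[str, bool] = {}
    sets: dict[str, frozenset] = {}
    node_sets: dict[int, frozenset] = {}
    dup = n_int = n_all = 0
    for idx, node in enumerate(gene_tree.postorder_node_iter()):
        n_all += 1
        key = node_key(node, idx)
        if node.is_leaf():
            sp = leaf_species(node.taxon.label if node.taxon else node.label,
                              species_map, delimiter)
            node_sets[id(node)] = frozenset((sp,))
            continue
        n_int += 1
        child_sets = [node_sets[id(c)] for c in node.child_nodes()]
        is_dup = any(
            s1 & s2 for s1, s2 in itertools.combinations(child_sets, 2)
        )
        merged = frozenset().union(*child_sets)
        node_sets[id(node)] = merged
        flags[key] = is_dup
        sets[key] = merged
        dup += is_dup
    return DuplicationAnnotation(
        flags=flags, duplication_count=dup, n_internal=n_int, n_all=n_all,
        species_sets=sets,
    )


def duplication_ratio(ann: DuplicationAnnotation, node_total: str = "internal") -> float:
    """Duplicate nodes over total nodes.

    ``node_total='internal'`` divides by the internal-node count (where the
    duplication/speciation labels live); ``'all'`` divides by every node
    including leaves.
    """
    if node_total == "internal":
        denom = ann.n_internal
    elif node_total == "all":
        denom = ann.n_all
    else:
        raise ValueError(f"node_total must be 'internal' or 'all', got {node_total!r}")
    if denom == 0:
        raise UndefinedRatioError("tree has no internal nodes; ratio undefined")
    return ann.duplication_count / denom


# ---------------------------------------------------------------------------
# Robinson-Foulds congruence
# ---------------------------------------------------------------------------

def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson–Foulds (symmetric-difference) distance."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    ns = dendropy.TaxonNamespace()
    a = read_newick(write_newick(t1), taxon_namespace=ns)
    b = read_newick(write_newick(t2), taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


# ---------------------------------------------------------------------------
# Fitch parsimony and the ILD permutation test
# ---------------------------------------------------------------------------

def fitch_length(tree: dendropy.Tree, site: dict[str, str]) -> int:
    """Minimum number of state changes on ``tree`` for one character.

    Classic Fitch bottom-up pass; internal nodes must be bifurcating.
    ``site`` maps every leaf label to its state.
    """
    changes = 0
    state_sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in site:
                raise ValueError(f"leaf {label!r} has no state")
            state_sets[id(node)] = frozenset((site[label],))
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError("fitch_length requires a binary tree")
        s1, s2 = (state_sets[id(c)] for c in kids)
        inter = s1 & s2
        if inter:
            state_sets[id(node)] = inter
        else:
            state_sets[id(node)] = s1 | s2
            changes += 1
    return changes


def _tree_arrays(tree: dendropy.Tree) -> tuple[list[str], list[tuple[int, int, int]]]:
    """Postorder (parent, left, right) index triples for a binary tree."""
    leaves: list[str] = []
    index: dict[int, int] = {}
    ops: list[tuple[int, int, int]] = []
    nxt = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            index[id(node)] = nxt
            leaves.append(node.taxon.label if node.taxon else node.label)
            nxt += 1
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("ILD fixed-topology search requires a binary tree")
            index[id(node)] = nxt
            ops.append((nxt, index[id(kids[0])], index[id(kids[1])]))
            nxt += 1
    return leaves, ops


def _fitch_lengths_columns(ops, leaf_masks: np.ndarray, n_nodes: int) -> np.ndarray:
    """Vectorized Fitch over columns; leaf_masks is (n_leaves, n_cols) bitmasks."""
    n_cols = leaf_masks.shape[1]
    masks = np.zeros((n_nodes, n_cols), dtype=np.int64)
    masks[: leaf_masks.shape[0]] = leaf_masks
    changes = np.zeros(n_cols, dtype=np.int64)
    for parent, left, right in ops:
        inter = masks[left] & masks[right]
        empty = inter == 0
        masks[parent] = np.where(empty, masks[left] | masks[right], inter)
        changes += empty
    return changes


def fixed_tree_search(tree: dendropy.Tree):
    """Parsimony 'search' that scores matrices on one fixed topology.

    Returns a callable mapping a character matrix (``{taxon: state
    string}``) to its total Fitch length on ``tree`` — the fast,
    deterministic default for the ILD test.
    """
    leaves, ops = _tree_arrays(tree)
    n_nodes = len(leaves) + len(ops)

    def search(matrix: dict[str, str]) -> int:
        masks = _matrix_to_masks(matrix, leaves)
        return int(_fitch_lengths_columns(ops, masks, n_nodes).sum())

    search.leaves = leaves  # type: ignore[attr-defined]
    search.ops = ops  # type: ignore[attr-defined]
    search.n_nodes = n_nodes  # type: ignore[attr-defined]
    return search


def _matrix_to_masks(matrix: dict[str, str], leaves: list[str]) -> np.ndarray:
    lengths = {len(v) for v in matrix.values()}
    if len(lengths) != 1:
        raise ValueError("all taxa must have the same number of characters")
    alphabet: dict[str, int] = {}
    rows = []
    for leaf in leaves:
        if leaf not in matrix:
            raise ValueError(f"taxon {leaf!r} missing from the character matrix")
        row = []
        for ch in matrix[leaf]:
            if ch not in alphabet:
                if len(alphabet) >= 63:
                    raise ValueError("alphabet too large for bitmask Fitch")
                alphabet[ch] = len(alphabet)
            row.append(1 << alphabet[ch])
        rows.append(row)
    return np.asarray(rows, dtype=np.int64)


def _all_binary_topologies(labels: list[str]):
    """Yield every unrooted binary topology over ``labels`` as a nested tuple
    rooted on the first label's edge ((2n-5)!! trees)."""
    if len(labels) < 3:
        yield tuple(labels)
        return

    def grow(subtree, leaf):
        # insert `leaf` on every edge of `subtree`; yields new subtrees
        yield (subtree, leaf)
        if isinstance(subtree, tuple):
            left, right = subtree
            for g in grow(left, leaf):
                yield (g, right)
            for g in grow(right, leaf):
                yield (left, g)

    first, rest = labels[0], labels[1:]
    base = (rest[0], rest[1])
    stack = [base]
    for leaf in rest[2:]:
        stack = [g for s in stack for g in grow(s, leaf)]
    for s in stack:
        yield (first, s)


def _shape_to_ops(shape, leaf_index: dict[str, int]):
    """Postorder (parent, left, right) triples for one nested-tuple shape."""
    ops: list[tuple[int, int, int]] = []
    counter = [len(leaf_index)]

    def walk(s) -> int:
        if not isinstance(s, tuple):
            return leaf_index[s]
        left = walk(s[0])
        right = walk(s[1])
        idx = counter[0]
        counter[0] += 1
        ops.append((idx, left, right))
        return idx

    walk(shape)
    return ops, counter[0]


def exhaustive_tree_search(taxa: list[str]):
    """Parsimony search minimizing over every unrooted binary topology.

    Topology structures for ``taxa`` (<= 9) are precompiled once; the
    returned callable scores a character matrix with vectorized Fitch on
    each topology and returns the minimum total length.
    """
    taxa = sorted(taxa)
    if len(taxa) > 9:
        raise ValueError("exhaustive search limited to 9 taxa")
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    leaf_index = {t: i for i, t in enumerate(taxa)}
    compiled = [
        _shape_to_ops(shape, leaf_index) for shape in _all_binary_topologies(taxa)
    ]

    def search(matrix: dict[str, str]) -> int:
        masks = _matrix_to_masks(matrix, taxa)
        best = None
        for ops, n_nodes in compiled:
            total = int(_fitch_lengths_columns(ops, masks, n_nodes).sum())
            if best is None or total < best:
                best = total
        return best

    search.taxa = taxa  # type: ignore[attr-defined]
    search.n_topologies = len(compiled)  # type: ignore[attr-defined]
    return search


def exhaustive_parsimony_search(matrix: dict[str, str]) -> int:
    """Best Fitch length over every unrooted binary topology (<= 9 taxa)."""
    return exhaustive_tree_search(sorted(matrix))(matrix)


@dataclass
class IldResult:
    statistic: int
    p_value: float
    n_perm: int
    length_a: int
    length_b: int
    length_combined: int


def ild_test(
    partition_a: dict[str, str],
    partition_b: dict[str, str],
    tree_search,
    n_perm: int = 199,
    seed: int = 0,
) -> IldResult:
    """Incongruence-length-difference permutation test.

    Statistic: L(combined) − [L(a) + L(b)] under the supplied parsimony
    search.  Characters are permuted between the two partitions, holding
    the partition sizes fixed; p = (1 + #{permuted >= observed}) /
    (n_perm + 1).
    """
    if set(partition_a) != set(partition_b):
        raise ValueError("partitions must cover the same taxa")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    taxa = sorted(partition_a)
    na = len(partition_a[taxa[0]])
    combined = {t: partition_a[t] + partition_b[t] for t in taxa}
    n_total = len(combined[taxa[0]])

    if hasattr(tree_search, "ops"):
        # fixed-topology search: score all columns once, permute the split
        masks = _matrix_to_masks(combined, tree_search.leaves)
        per_col = _fitch_lengths_columns(tree_search.ops, masks, tree_search.n_nodes)
        l_comb = int(per_col.sum())
        l_a = int(per_col[:na].sum())
        l_b = l_comb - l_a
        observed = l_comb - (l_a + l_b)  # 0 on a fixed topology by additivity
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            pa = int(per_col[perm[:na]].sum())
            stat = l_comb - (pa + (l_comb - pa))
            count += stat >= observed
        return IldResult(observed, (1 + count) / (n_perm + 1), n_perm, l_a, l_b, l_comb)

    l_a = tree_search(partition_a)
    l_b = tree_search(partition_b)
    l_comb = tree_search(combined)
    observed = l_comb - (l_a + l_b)
    rng = np.random.default_rng(seed)
    cols = [{t: combined[t][k] for t in taxa} for k in range(n_total)]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        mat_a = {t: "".join(cols[k][t] for k in perm[:na]) for t in taxa}
        mat_b = {t: "".join(cols[k][t] for k in perm[na:]) for t in taxa}
        stat = l_comb - (tree_search(mat_a) + tree_search(mat_b))
        count += stat >= observed
    return IldResult(observed, (1 + count) / (n_perm + 1), n_perm, l_a, l_b, l_comb)
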
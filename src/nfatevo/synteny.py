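"""Chromosome dispersion and evolutionary-breakpoint (EBP) detection.

Two statistics are computed from gene-location tables:

* the *chromosome ratio* of a gene family in a taxon — family-bearing
  chromosomes over the total chromosome number, aggregated over the
  taxon's species;
* *evolutionary breakpoints* — reference gene-order adjacencies that are
  disrupted in a target species' chromosome.  Gene directionality (strand)
  is parsed but deliberately ignored: adjacencies are unordered pairs, so
  a whole-order reversal produces zero breakpoints.

Orders are compared after restriction to their shared gene set; synteny
blocks are the maximal runs of reference-consecutive genes that remain
contiguous (forward or reversed) in the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .simulate import adjacency_set

LOCATION_COLUMNS = ["species", "taxon", "gene", "family", "chromosome", "position", "strand"]


class UndefinedRatioError(ZeroDivisionError):
    pass


class InsufficientOverlapError(ValueError):
    """Fewer than 2 genes shared between the two orders."""


@dataclass
class LocationTable:
    """Gene locations: one row per (species, gene), plus chromosome totals.

    ``table`` columns: species, taxon, gene, family, chromosome, position
    (0-based ordinal rank along the chromosome), strand (+/-/.).  ``gene``
    holds ortholog-group identifiers so orders are comparable across
    species.  ``total_chromosomes`` maps species -> karyotype size.
    """

    table: pd.DataFrame
    total_chromosomes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in LOCATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"location table missing columns: {missing}")
        dup = self.table.duplicated(subset=["species", "gene"])
        if dup.any():
            bad = self.table.loc[dup, ["species", "gene"]].iloc[0]
            raise ValueError(f"duplicate (species, gene): {tuple(bad)}")
        dup = self.table.duplicated(subset=["species", "chromosome", "position"])
        if dup.any():
            bad = self.table.loc[dup, ["species", "chromosome", "position"]].iloc[0]
            raise ValueError(f"duplicate ordinal position: {tuple(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path, totals_path: str | Path | None = None) -> "LocationTable":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        totals = {}
        if totals_path is not None:
            tt = pd.read_csv(totals_path, sep="\t")
            totals = dict(zip(tt["species"], tt["total_chromosomes"].astype(int)))
        return cls(table=df, total_chromosomes=totals)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        species: str,
        taxon: str = "",
        family: str = "",
        total_chromosomes: int | None = None,
    ) -> "LocationTable":
        """Import one species from BED (0-based half-open; name col 4, strand col 6).

        Ordinal positions are assigned by start coordinate within each
        chromosome.
        """
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        bed = bed.iloc[:, : max(6, bed.shape[1])]
        names = ["chromosome", "start", "end", "gene", "score", "strand"][: bed.shape[1]]
        bed.columns = names
        if "strand" not in bed.columns:
            bed["strand"] = "."
        bed = bed.sort_values(["chromosome", "start"], kind="mergesort")
        bed["position"] = bed.groupby("chromosome").cumcount()
        df = pd.DataFrame(
            {
                "species": species,
                "taxon": taxon,
                "gene": bed["gene"],
                "family": family,
                "chromosome": bed["chromosome"].astype(str),
                "position": bed["position"].astype(int),
                "strand": bed["strand"],
            }
        )
        totals = {species: total_chromosomes} if total_chromosomes else {}
        return cls(table=df.reset_index(drop=True), total_chromosomes=totals)


@dataclass
class GeneOrder:
    """Ordered ortholog-group ids along one chromosome of one species."""

    species: str
    chromosome: str
    genes: list[str]
    strands: list[str] | None = None

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene order contains repeated ids")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class BreakpointReport:
    species: str
    family: str
    broken_adjacencies: set[frozenset]
    synteny_blocks: list[list[str]]
    n_shared: int

    @property
    def ebp_count(self) -> int:
        return len(self.broken_adjacencies)


# ---------------------------------------------------------------------------
# chromosome ratio
# ---------------------------------------------------------------------------

def chromosome_ratio(
    table: LocationTable, taxon: str, family: str, aggregate: str = "mean"
) -> float:
    """Family-bearing chromosomes over total chromosome number in a taxon.

    ``aggregate='mean'``: per-species ratios averaged (unweighted) over the
    taxon's species; ``'pooled'``: summed counts over summed karyotype
    sizes.
    """
    df = table.table
    sub = df[df["taxon"] == taxon]
    if sub.empty:
        raise ValueError(f"taxon {taxon!r} not present in the location table")
    species = sorted(sub["species"].unique())
    counts, totals, ratios = [], [], []
    for sp in species:
        total = table.total_chromosomes.get(sp, 0)
        if total <= 0:
            raise UndefinedRatioError(f"species {sp!r} has no total chromosome count")
        n_chr = sub[(sub["species"] == sp) & (sub["family"] == family)]["chromosome"].nunique()
        counts.append(n_chr)
        totals.append(total)
        ratios.append(n_chr / total)
    if aggregate == "mean":
        return sum(ratios) / len(ratios)
    if aggregate == "pooled":
        return sum(counts) / sum(totals)
    raise ValueError(f"aggregate must be 'mean' or 'pooled', got {aggregate!r}")


# ---------------------------------------------------------------------------
# neighborhoods and breakpoints
# ---------------------------------------------------------------------------

def extract_neighborhood(
    table: LocationTable, species: str, anchor_gene: str, window: int = 5
) -> GeneOrder:
    """The ``window`` genes up- and downstream of the anchor, anchor included.

    Truncated without padding at chromosome ends.  If an ortholog-group id
    occurs more than once in the window, the copy closest to the anchor is
    kept so the resulting order is duplicate-free.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    df = table.table
    hit = df[(df["species"] == species) & (df["gene"] == anchor_gene)]
    if hit.empty:
        raise KeyError(f"anchor gene {anchor_gene!r} not found in species {species!r}")
    row = hit.iloc[0]
    chrom = row["chromosome"]
    chrom_df = (
        df[(df["species"] == species) & (df["chromosome"] == chrom)]
        .sort_values("position", kind="mergesort")
        .reset_index(drop=True)
    )
    idx = int(chrom_df.index[chrom_df["gene"] == anchor_gene][0])
    lo = max(0, idx - window)
    win = chrom_df.iloc[lo : idx + window + 1]
    genes = list(win["gene"])
    strands = list(win["strand"])
    anchor_pos = genes.index(anchor_gene)
    # deduplicate, keeping the copy closest to the anchor
    best: dict[str, int] = {}
    for i, g in enumerate(genes):
        if g not in best or abs(i - anchor_pos) < abs(best[g] - anchor_pos):
            best[g] = i
    keep = sorted(best.values())
    return GeneOrder(
        species=species,
        chromosome=str(chrom),
        genes=[genes[i] for i in keep],
        strands=[strands[i] for i in keep],
    )


def _restrict(order: list[str], shared: set[str]) -> list[str]:
    return [g for g in order if g in shared]


def detect_breakpoints(
    reference: GeneOrder | list[str], target: GeneOrder | list[str], family: str = ""
) -> BreakpointReport:
    """Reference adjacencies (unordered pairs) no longer adjacent in the target.

    Both orders are first restricted to their shared gene set, preserving
    relative order.  Strand is ignored throughout, so reversing the whole
    target yields zero breakpoints.
    """
    ref_genes = reference.genes if isinstance(reference, GeneOrder) else list(reference)
    tgt_genes = target.genes if isinstance(target, GeneOrder) else list(target)
    shared = set(ref_genes) & set(tgt_genes)
    if len(shared) < 2:
        raise InsufficientOverlapError(
            f"only {len(shared)} genes shared between reference and target"
        )
    ref = _restrict(ref_genes, shared)
    tgt = _restrict(tgt_genes, shared)
    broken = adjacency_set(ref) - adjacency_set(tgt)
    # blocks: cut the restricted reference at every broken adjacency
    blocks: list[list[str]] = [[ref[0]]]
    for prev, cur in zip(ref, ref[1:]):
        if frozenset((prev, cur)) in broken:
            blocks.append([cur])
        else:
            blocks[-1].append(cur)
    return BreakpointReport(
        species=target.species if isinstance(target, GeneOrder) else "",
        family=family,
        broken_adjacencies=broken,
        synteny_blocks=blocks,
        n_shared=len(shared),
    )


def synteny_blocks(
    reference: GeneOrder | list[str], target: GeneOrder | list[str]
) -> list[list[str]]:
    """Maximal reference-consecutive runs contiguous (either way) in the target."""
    return detect_breakpoints(reference, target).synteny_blocks


def ebp_survey(
    table: LocationTable,
    reference_species: str,
    families: list[str],
    window: int = 5,
) -> pd.DataFrame:
    """Breakpoint counts per (species, family) against a reference species.

    For each family the anchor is that family's gene in each species (first
    by chromosome/position if several); species or families without an
    anchor in either the reference or the target are skipped.  Rows are
    ordered by (species, family).
    """
    df = table.table
    if reference_species not in set(df["species"]):
        raise ValueError(f"reference species {reference_species!r} not in the table")
    rows = []
    species_list = sorted(df["species"].unique())
    for sp in species_list:
        for fam in families:
            ref_anchor = _family_anchor(df, reference_species, fam)
            tgt_anchor = _family_anchor(df, sp, fam)
            if ref_anchor is None or tgt_anchor is None:
                continue
            ref_order = extract_neighborhood(table, reference_species, ref_anchor, window)
            tgt_order = extract_neighborhood(table, sp, tgt_anchor, window)
            try:
                rep = detect_breakpoints(ref_order, tgt_order, family=fam)
            except InsufficientOverlapError:
                rows.append({"species": sp, "family": fam, "ebp_count": pd.NA,
                             "n_shared": 0, "n_blocks": 0})
                continue
            rows.append(
                {
                    "species": sp,
                    "family": fam,
                    "ebp_count": rep.ebp_count,
                    "n_shared": rep.n_shared,
                    "n_blocks": len(rep.synteny_blocks),
                }
            )
    out = pd.DataFrame(rows, columns=["species", "family", "ebp_count", "n_shared", "n_blocks"])
    return out.sort_values(["species", "family"], kind="mergesort").reset_index(drop=True)


def _family_anchor(df: pd.DataFrame, species: str, family: str) -> str | None:
    sub = df[(df["species"] == species) & (df["family"] == family)]
    if sub.empty:
        return None
    sub = sub.sort_values(["chromosome", "position"], kind="mergesort")
    return sub.iloc[0]["gene"]
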
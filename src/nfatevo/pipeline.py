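"""End-to-end orchestration: demo data, configuration, the full pipeline.

``make_demo`` writes a small, fully synthetic comparative study — a
species tree, gene-family trees with planted duplications, codon pairs
with planted omega per family, gene orders with planted rearrangements,
and an isoform table — together with JSON truth sidecars.  ``run_pipeline``
runs every analysis stage over such a dataset and writes a report bundle
plus a manifest with per-stage checksums, so a rerun with the same config
and inputs is verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from . import phylo, selection, simulate, stats, synteny


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_PATH_KEYS = (
    "gene_trees_dir", "locations", "chromosome_totals", "codon_manifest",
    "isoforms", "divergence_times", "species_taxa",
)


@dataclass
class PipelineConfig:
    """Paths, switches and seeds for one pipeline run.

    Paths are resolved relative to the config file's directory.  Switches
    mirror the analysis options: ``node_total`` (internal|all) for the
    duplication ratio, ``aggregate`` (mean|pooled) for the chromosome
    ratio, ``numerator`` (extra|all) for the splicing ratio, ``combine``
    (fisher|none) for pooling LRT p-values.
    """

    gene_trees_dir: Path
    locations: Path
    chromosome_totals: Path
    codon_manifest: Path
    isoforms: Path
    divergence_times: Path
    species_taxa: Path
    outdir: Path
    reference_species: str = "T01"
    window: int = 5
    node_total: str = "internal"
    aggregate: str = "mean"
    numerator: str = "extra"
    combine: str = "fisher"
    alpha: float = 0.05
    seed: int = 0
    delimiter: str = "|"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Parse a plain key=value config file; kwargs override file values."""
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw: dict[str, str] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = path.parent
        kwargs: dict = {}
        for f in cls.__dataclass_fields__.values():
            if f.name not in raw:
                continue
            v = raw.pop(f.name)
            if f.name in _PATH_KEYS or f.name == "outdir":
                p = Path(v)
                kwargs[f.name] = p if p.is_absolute() else base / p
            elif f.type in ("int", int):
                kwargs[f.name] = int(v)
            elif f.type in ("float", float):
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        if raw:
            raise ConfigError(f"unknown config keys: {sorted(raw)}")
        missing = [k for k in (*_PATH_KEYS, "outdir") if k not in kwargs]
        if missing:
            raise ConfigError(f"config missing required keys: {missing}")
        return cls(**kwargs)

    def validate(self) -> None:
        for key in _PATH_KEYS:
            p = Path(getattr(self, key))
            if not p.exists():
                raise ConfigError(f"input path for {key!r} does not exist: {p}")
        if self.node_total not in ("internal", "all"):
            raise ConfigError(f"node_total must be internal|all, got {self.node_total!r}")
        if self.aggregate not in ("mean", "pooled"):
            raise ConfigError(f"aggregate must be mean|pooled, got {self.aggregate!r}")
        if self.numerator not in ("extra", "all"):
            raise ConfigError(f"numerator must be extra|all, got {self.numerator!r}")
        if self.combine not in ("fisher", "none"):
            raise ConfigError(f"combine must be fisher|none, got {self.combine!r}")
        if self.window < 1:
            raise ConfigError("window must be >= 1")


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

DEMO_TAXA = ["mammal", "bird", "reptile", "amphibian", "fish"]
DEMO_DUP_RATES = {"F1": 0.1, "F2": 0.25, "F3": 0.4, "F4": 0.55, "F5": 0.7}
DEMO_OMEGAS = {"F1": 0.2, "F2": 0.5, "F3": 1.0, "F4": 1.4, "F5": 2.0}
DEMO_INVERSIONS = {"mammal": 0, "bird": 1, "reptile": 1, "amphibian": 2, "fish": 3}
DEMO_EXTRA_CHROMS = {"mammal": 0, "bird": 0, "reptile": 1, "amphibian": 1, "fish": 2}
DEMO_PAIR_LABELS = ["mammal-fish", "mammal-bird", "bird-fish"]
DEMO_N_CODONS = 400
DEMO_T = 0.5
DEMO_KAPPA = 2.0
DEMO_NEIGHBORS = 5  # genes each side of the anchor in the planted order


def make_demo(outdir: str | Path, seed: int = 1) -> Path:
    """Write the bundled synthetic study (15 species, 5 taxa, 5 families).

    Returns the path of the generated config file.  Every random choice
    derives from ``seed``; truth sidecars land in ``truth/``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "gene_trees").mkdir(exist_ok=True)
    (out / "codon_pairs").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    sp = simulate.simulate_species_tree(15, 1.0, seed=seed)
    species = sorted(lf.taxon.label for lf in sp.tree.leaf_node_iter())
    taxon_of = {s: DEMO_TAXA[i // 3] for i, s in enumerate(species)}
    (out / "species_tree.nwk").write_text(sp.newick + "\n")
    pd.DataFrame(
        {"species": species, "taxon": [taxon_of[s] for s in species]}
    ).to_csv(out / "species_taxa.tsv", sep="\t", index=False)

    # divergence time of each taxon: mean pairwise MRCA age of its species
    div_rows = []
    for taxon in DEMO_TAXA:
        members = [s for s in species if taxon_of[s] == taxon]
        ages = [
            sp.divergence_times[frozenset(p)]
            for p in itertools.combinations(members, 2)
        ]
        div_rows.append({"taxon": taxon, "divergence_time": sum(ages) / len(ages)})
    pd.DataFrame(div_rows).to_csv(
        out / "divergence_times.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    # gene families with a planted duplication-rate gradient
    fam_truth = {}
    for i, (fam, rate) in enumerate(sorted(DEMO_DUP_RATES.items())):
        gf = simulate.simulate_gene_family(sp, rate, 0.0, seed=seed * 100 + i)
        (out / "gene_trees" / f"{fam}.nwk").write_text(gf.newick + "\n")
        fam_truth[fam] = {
            "dup_rate": rate,
            "seed": gf.seed,
            "true_duplication_nodes": sorted(gf.true_duplication_nodes),
        }

    # codon pairs with a planted omega per family
    codon_truth = {}
    manifest_rows = []
    for i, (fam, omega) in enumerate(sorted(DEMO_OMEGAS.items())):
        for j, pair in enumerate(DEMO_PAIR_LABELS):
            s = seed * 1000 + i * 10 + j
            sim = simulate.simulate_codon_pair(omega, DEMO_T, DEMO_KAPPA, DEMO_N_CODONS, s)
            rel = f"codon_pairs/{fam}_{pair}.fasta"
            with open(out / rel, "w") as fh:
                fh.write(f">{fam}_{pair}_a\n{sim.seq_a}\n>{fam}_{pair}_b\n{sim.seq_b}\n")
            manifest_rows.append({"family": fam, "pair": pair, "path": rel})
            codon_truth[f"{fam}_{pair}"] = {
                "omega": omega, "t": DEMO_T, "kappa": DEMO_KAPPA, "seed": s,
            }
    pd.DataFrame(manifest_rows).to_csv(out / "codon_manifest.tsv", sep="\t", index=False)

    # gene locations: per family a planted neighborhood order per species,
    # plus extra family-bearing chromosomes in the more rearranged taxa
    rng = np.random.default_rng(seed + 777)
    loc_rows = []
    order_truth = {}
    families = sorted(DEMO_DUP_RATES)
    n_genes = 2 * DEMO_NEIGHBORS + 1
    for fi, fam in enumerate(families):
        ref_order = (
            [f"{fam}nb{k:02d}" for k in range(1, DEMO_NEIGHBORS + 1)]
            + [fam]
            + [f"{fam}nb{k:02d}" for k in range(DEMO_NEIGHBORS + 1, 2 * DEMO_NEIGHBORS + 1)]
        )
        chrom = f"c{fi + 1:02d}"
        for si, spc in enumerate(species):
            taxon = taxon_of[spc]
            k_inv = DEMO_INVERSIONS[taxon]
            if spc == species[0] or k_inv == 0:
                order = list(ref_order)
                planted: set = set()
            else:
                ops = simulate.random_inversion_ops(n_genes, k_inv, rng)
                sim = simulate.simulate_gene_orders(
                    n_genes, {spc: ops}, seed=seed, gene_prefix="_tmp"
                )
                perm = [int(g[4:]) - 1 for g in sim.target_orders[spc]]
                order = [ref_order[p] for p in perm]
                planted = {
                    frozenset((ref_order[int(a[4:]) - 1], ref_order[int(b[4:]) - 1]))
                    for a, b in (tuple(fs) for fs in sim.planted_breakpoints[spc])
                }
            order_truth[f"{spc}:{fam}"] = {
                "n_breakpoints": len(planted),
                "broken": sorted(sorted(p) for p in planted),
            }
            for pos, gid in enumerate(order):
                loc_rows.append({
                    "species": spc, "taxon": taxon, "gene": gid,
                    "family": fam if gid == fam else "",
                    "chromosome": chrom, "position": pos,
                    "strand": "+" if rng.random() < 0.5 else "-",
                })
            for x in range(DEMO_EXTRA_CHROMS[taxon]):
                loc_rows.append({
                    "species": spc, "taxon": taxon, "gene": f"{fam}x{x + 1}@{spc}",
                    "family": fam, "chromosome": f"c{6 + (fi + x) % 5:02d}",
                    "position": fi * 10 + x, "strand": "+",
                })
    pd.DataFrame(loc_rows).to_csv(out / "locations.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"species": species, "total_chromosomes": [10] * len(species)}
    ).to_csv(out / "chromosome_totals.tsv", sep="\t", index=False)

    # isoform table: splicing propensity rises along the taxon order
    iso_rows = []
    for si, spc in enumerate(species):
        taxon = taxon_of[spc]
        ti = DEMO_TAXA.index(taxon)
        for fam in families:
            gene = f"{fam}@{spc}"
            k = 1 + rng.poisson(0.25 + 0.35 * ti)
            for iso in range(1, k + 1):
                iso_rows.append({
                    "species": spc, "taxon": taxon, "family": fam,
                    "gene": gene, "isoform_id": f"{gene}.i{iso}",
                })
    pd.DataFrame(iso_rows).to_csv(out / "isoforms.tsv", sep="\t", index=False)

    with open(out / "truth" / "truth.json", "w") as fh:
        json.dump(
            {"seed": seed, "gene_families": fam_truth,
             "codon_pairs": codon_truth, "gene_orders": order_truth},
            fh, indent=1, sort_keys=True,
        )

    cfg = out / "demo.cfg"
    cfg.write_text(
        "# synthetic demo study configuration\n"
        "gene_trees_dir=gene_trees\n"
        "locations=locations.tsv\n"
        "chromosome_totals=chromosome_totals.tsv\n"
        "codon_manifest=codon_manifest.tsv\n"
        "isoforms=isoforms.tsv\n"
        "divergence_times=divergence_times.tsv\n"
        "species_taxa=species_taxa.tsv\n"
        f"reference_species={species[0]}\n"
        "outdir=results\n"
        "window=5\n"
        "node_total=internal\n"
        "aggregate=mean\n"
        "numerator=extra\n"
        "combine=fisher\n"
        "alpha=0.05\n"
        f"seed={seed}\n"
    )
    return cfg


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _induced_subtree(tree: dendropy.Tree, labels: set[str]) -> dendropy.Tree | None:
    keep = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon.label in labels]
    if len(keep) < 2:
        return None
    return tree.extract_tree_with_taxa_labels(labels=keep)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage over the configured inputs; returns the manifest.

    Stages: duplication ratios from the gene trees; chromosome ratios and
    the breakpoint survey from the location table; pairwise ML omega with
    LRT from the codon manifest; splicing ratios from the isoform table;
    and the correlation layer over the assembled ratio table.  A failure
    inside one family/taxon is recorded as a warning, not fatal; a failed
    stage is recorded in the manifest and the remaining stages still run.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "stages": {},
        "warnings": [],
    }
    warn = manifest["warnings"].append

    taxa_map = pd.read_csv(config.species_taxa, sep="\t")
    taxon_of = dict(zip(taxa_map["species"], taxa_map["taxon"]))
    taxa = sorted(set(taxon_of.values()))

    # ---- stage: duplication ratios ------------------------------------
    t0 = time.perf_counter()
    dup_rows = []
    try:
        tree_files = sorted(Path(config.gene_trees_dir).glob("*.nwk"))
        if not tree_files:
            raise StageError(f"no .nwk files in {config.gene_trees_dir}")
        for tf in tree_files:
            fam = tf.stem
            tree = phylo.read_newick(tf.read_text())
            ann = phylo.species_overlap_labels(tree, delimiter=config.delimiter)
            dup_rows.append({
                "family": fam, "taxon": "all",
                "n_leaves": sum(1 for _ in tree.leaf_node_iter()),
                "n_duplications": ann.duplication_count,
                "duplication_ratio": phylo.duplication_ratio(ann, config.node_total),
            })
            for taxon in taxa:
                members = {s for s, t in taxon_of.items() if t == taxon}
                labels = {
                    lf.taxon.label for lf in tree.leaf_node_iter()
                    if lf.taxon.label.split(config.delimiter, 1)[0] in members
                }
                sub = _induced_subtree(tree, labels)
                if sub is None:
                    warn(f"dupratio: {fam}/{taxon}: fewer than 2 genes, skipped")
                    continue
                sann = phylo.species_overlap_labels(sub, delimiter=config.delimiter)
                try:
                    ratio = phylo.duplication_ratio(sann, config.node_total)
                except phylo.UndefinedRatioError:
                    warn(f"dupratio: {fam}/{taxon}: no internal nodes, skipped")
                    continue
                dup_rows.append({
                    "family": fam, "taxon": taxon, "n_leaves": len(labels),
                    "n_duplications": sann.duplication_count,
                    "duplication_ratio": ratio,
                })
        dup_df = pd.DataFrame(dup_rows)
        _write_tsv(dup_df, out / "duplication_ratios.tsv")
        manifest["stages"]["duplication"] = _stage_ok(t0, [out / "duplication_ratios.tsv"])
    except Exception as exc:
        dup_df = pd.DataFrame(
            columns=["family", "taxon", "n_leaves", "n_duplications", "duplication_ratio"]
        )
        manifest["stages"]["duplication"] = _stage_fail(t0, exc)

    # ---- stage: chromosome ratios + breakpoint survey ------------------
    t0 = time.perf_counter()
    try:
        loc = synteny.LocationTable.from_tsv(config.locations, config.chromosome_totals)
        loc.table["family"] = loc.table["family"].fillna("")
        families = sorted(f for f in loc.table["family"].unique() if f)
        chrom_rows = []
        for taxon in taxa:
            for fam in families:
                try:
                    r = synteny.chromosome_ratio(loc, taxon, fam, config.aggregate)
                except (ValueError, ZeroDivisionError) as exc:
                    warn(f"chromosome_ratio: {taxon}/{fam}: {exc}")
                    continue
                chrom_rows.append({"taxon": taxon, "family": fam, "chromosome_ratio": r})
        chrom_df = pd.DataFrame(chrom_rows)
        ebp_df = synteny.ebp_survey(loc, config.reference_species, families, config.window)
        _write_tsv(chrom_df, out / "chromosome_ratios.tsv")
        _write_tsv(ebp_df, out / "ebp_survey.tsv")
        manifest["stages"]["synteny"] = _stage_ok(
            t0, [out / "chromosome_ratios.tsv", out / "ebp_survey.tsv"]
        )
    except Exception as exc:
        chrom_df = pd.DataFrame(columns=["taxon", "family", "chromosome_ratio"])
        ebp_df = pd.DataFrame()
        manifest["stages"]["synteny"] = _stage_fail(t0, exc)

    # ---- stage: selection ----------------------------------------------
    t0 = time.perf_counter()
    try:
        man = pd.read_csv(config.codon_manifest, sep="\t")
        base = Path(config.codon_manifest).parent
        per_family: dict[str, list[selection.OmegaEstimate]] = {}
        pair_rows = []
        for _, row in man.iterrows():
            fpath = base / row["path"]
            try:
                aln = selection.read_fasta_pair(fpath)
                est = selection.ml_pairwise_omega(aln)
            except Exception as exc:
                warn(f"selection: {row['family']}/{row['pair']}: {exc}")
                continue
            per_family.setdefault(row["family"], []).append(est)
            pair_rows.append({
                "family": row["family"], "pair": row["pair"],
                "w": est.w, "t": est.t, "kappa": est.kappa,
                "dN": est.dN, "dS": est.dS,
                "lnL_alt": est.lnL_alt, "lnL_null": est.lnL_null,
                "p_value": est.p_value, "flags": ";".join(est.flags),
            })
        summary = selection.taxonpair_omega_summary(per_family, combine=config.combine)
        summary["classification"] = [
            selection.classify_selection(
                None if pd.isna(r.mean_w) else r.mean_w,
                1.0 if pd.isna(r.p_combined) else r.p_combined,
                config.alpha,
            ).label
            for r in summary.itertuples()
        ]
        _write_tsv(pd.DataFrame(pair_rows), out / "omega_pairs.tsv")
        _write_tsv(summary, out / "omega_summary.tsv")
        manifest["stages"]["selection"] = _stage_ok(
            t0, [out / "omega_pairs.tsv", out / "omega_summary.tsv"]
        )
    except Exception as exc:
        summary = pd.DataFrame(columns=["family", "mean_w", "sem_w", "p_combined"])
        manifest["stages"]["selection"] = _stage_fail(t0, exc)

    # ---- stage: splicing -----------------------------------------------
    t0 = time.perf_counter()
    try:
        iso = pd.read_csv(config.isoforms, sep="\t")
        by_taxon = stats.splicing_ratio(iso, by="taxon", numerator=config.numerator)
        _write_tsv(by_taxon.reset_index(), out / "splicing_by_taxon.tsv")
        if "family" in iso.columns:
            by_tf = stats.splicing_ratio(iso, by=["taxon", "family"],
                                         numerator=config.numerator)
            splice_df = by_tf.reset_index()
        else:
            splice_df = by_taxon.reset_index().assign(family="")
        _write_tsv(splice_df, out / "splicing_ratios.tsv")
        manifest["stages"]["splicing"] = _stage_ok(
            t0, [out / "splicing_by_taxon.tsv", out / "splicing_ratios.tsv"]
        )
    except Exception as exc:
        splice_df = pd.DataFrame(columns=["taxon", "family", "splicing_ratio"])
        manifest["stages"]["splicing"] = _stage_fail(t0, exc)

    # ---- stage: correlation layer ---------------------------------------
    t0 = time.perf_counter()
    try:
        div = pd.read_csv(config.divergence_times, sep="\t")
        ratio_table = _assemble_ratio_table(dup_df, chrom_df, splice_df, div, summary)
        _write_tsv(ratio_table, out / "ratio_table.tsv")
        report = stats.correlation_report(ratio_table)
        with open(out / "correlations.json", "w") as fh:
            json.dump(
                {k: (vars(v) if v is not None else None) for k, v in report.items()}, fh, indent=1, sort_keys=True
            )
        manifest["stages"]["correlation"] = _stage_ok(
            t0, [out / "ratio_table.tsv", out / "correlations.json"]
        )
    except Exception as exc:
        manifest["stages"]["correlation"] = _stage_fail(t0, exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _assemble_ratio_table(dup_df, chrom_df, splice_df, div, summary) -> pd.DataFrame:
    rows = dup_df[dup_df["taxon"] != "all"][["taxon", "family", "duplication_ratio"]]
    merged = rows.merge(chrom_df, on=["taxon", "family"], how="outer")
    if not splice_df.empty and "family" in splice_df.columns:
        merged = merged.merge(
            splice_df[["taxon", "family", "splicing_ratio"]],
            on=["taxon", "family"], how="left",
        )
    else:
        merged["splicing_ratio"] = np.nan
    merged = merged.merge(div, on="taxon", how="left")
    mw = summary[["family", "mean_w"]] if "family" in summary.columns else None
    if mw is not None and not mw.empty:
        merged = merged.merge(mw, on="family", how="left")
    else:
        merged["mean_w"] = np.nan
    return merged.sort_values(["taxon", "family"], kind="mergesort").reset_index(drop=True)


def _stage_ok(t0: float, outputs: list[Path]) -> dict:
    return {
        "status": "ok",
        "seconds": round(time.perf_counter() - t0, 3),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }


def _stage_fail(t0: float, exc: Exception) -> dict:
    return {
        "status": "failed",
        "seconds": round(time.perf_counter() - t0, 3),
        "error": f"{type(exc).__name__}: {exc}",
    }
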
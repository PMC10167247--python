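"""Pairwise dN/dS (omega) estimation, LRT against neutrality, classification.

Two estimators of omega = dN/dS for a pair of in-frame coding sequences:

* :func:`ng86_omega` — the Nei–Gojobori counting method: synonymous and
  nonsynonymous sites per codon, pathway-averaged difference counts for
  multi-hit codons, and a Jukes–Cantor multiple-hit correction;
* :func:`ml_pairwise_omega` — maximum likelihood under a GY94-style codon
  model (single-nucleotide exchanges; transition bias kappa; selection
  parameter omega; stop codons inaccessible), with a likelihood-ratio
  test of the neutral null omega = 1 against chi-square(1).

omega > 1 indicates positive selection, < 1 purifying selection, and = 1
neutral evolution; :func:`classify_selection` applies those calls at a
significance threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2
from Bio import SeqIO
from Bio.Data import CodonTable


class InvalidSequenceError(ValueError):
    pass


class PathwayDegenerateError(ValueError):
    """Every substitution pathway between two codons passes through a stop."""


_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _TABLE.forward_table if len(c) == 3 and set(c) <= set("ACGT"))
)
STOP_CODONS = frozenset(_TABLE.stop_codons)
N_CODONS = len(CODONS)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO = {c: _TABLE.forward_table[c] for c in CODONS}
_NUCS = "ACGT"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _exchange_masks():
    """Boolean 61x61 masks splitting single-nucleotide exchanges by
    transition/transversion x synonymous/nonsynonymous."""
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    ts = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, a in enumerate(CODONS):
        for j, b in enumerate(CODONS):
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = frozenset(diffs[0]) in _TRANSITIONS
            nonsyn[i, j] = AMINO[a] != AMINO[b]
    return (
        single & ~ts & ~nonsyn,
        single & ts & ~nonsyn,
        single & ~ts & nonsyn,
        single & ts & nonsyn,
    )


_TV_SYN, _TS_SYN, _TV_NON, _TS_NON = _exchange_masks()


# ---------------------------------------------------------------------------
# alignment validation
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Two equal-length, in-frame, gap- and stop-free coding sequences."""

    seq_a: str
    seq_b: str
    code: int = 1
    n_dropped: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        a, b = self.seq_a, self.seq_b
        for k in range(0, len(a), 3):
            yield a[k : k + 3], b[k : k + 3]


def validate_codon_alignment(a: str, b: str, code: int = 1) -> CodonAlignment:
    """Validate and clean a pairwise codon alignment.

    Codon columns where either sequence carries a gap or ambiguity
    character are dropped whole; an in-frame stop codon in the remainder
    is an error (reported with its codon index in the original frame).
    """
    if code != 1:
        raise ValueError("only the standard nuclear code (id 1) is supported")
    a, b = a.upper().replace("U", "T"), b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise ValueError(f"alignment length {len(a)} is not a multiple of 3")
    keep_a, keep_b = [], []
    dropped = 0
    for k in range(0, len(a), 3):
        ca, cb = a[k : k + 3], b[k : k + 3]
        if set(ca) <= set(_NUCS) and set(cb) <= set(_NUCS):
            if ca in STOP_CODONS or cb in STOP_CODONS:
                raise InvalidSequenceError(
                    f"in-frame stop codon at codon {k // 3 + 1}: {ca}/{cb}"
                )
            keep_a.append(ca)
            keep_b.append(cb)
        else:
            dropped += 1
    return CodonAlignment("".join(keep_a), "".join(keep_b), code=code, n_dropped=dropped)


def read_fasta_pair(path: str | Path, code: int = 1) -> CodonAlignment:
    """Load a two-record FASTA alignment as a :class:`CodonAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 FASTA records, found {len(records)}")
    return validate_codon_alignment(str(records[0].seq), str(records[1].seq), code=code)


# ---------------------------------------------------------------------------
# NG86 counting estimator
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the synonymous fraction is the share of non-stop
    single-nucleotide changes that preserve the amino acid; fractions sum
    across the three positions, so syn + nonsyn = 3.
    """
    if codon not in CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    for pos in range(3):
        n_valid = n_syn = 0
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            n_syn += AMINO[alt] == AMINO[codon]
        syn += n_syn / n_valid
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    For k differing positions, every ordering of the k changes defines a
    pathway; pathways visiting a stop codon are excluded and the
    synonymous/nonsynonymous step counts are averaged over the rest.
    """
    for c in (codon_a, codon_b):
        if c not in CODON_INDEX:
            raise ValueError(f"not a sense codon: {c!r}")
    positions = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not positions:
        return 0.0, 0.0
    syn_total = non_total = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = codon_a
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AMINO[cur] == AMINO[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_total += syn
            non_total += non
            n_paths += 1
    if n_paths == 0:
        raise PathwayDegenerateError(
            f"all pathways between {codon_a} and {codon_b} pass through stops"
        )
    return syn_total / n_paths, non_total / n_paths


@dataclass
class OmegaEstimate:
    """dN/dS for one sequence pair, by counting (NG86) or ML (GY94)."""

    method: str
    S_sites: float
    N_sites: float
    S_diffs: float
    N_diffs: float
    dS: float
    dN: float
    w: float | None
    t: float | None = None
    kappa: float | None = None
    lnL_alt: float | None = None
    lnL_null: float | None = None
    p_value: float | None = None
    flags: tuple[str, ...] = ()


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86_omega(aln: CodonAlignment) -> OmegaEstimate:
    """Nei–Gojobori counting estimate of dN, dS and omega.

    Site counts are averaged over the two sequences; proportions are
    Jukes–Cantor corrected; omega is flagged undefined when dS = 0 and the
    correction is flagged saturated when a proportion reaches 3/4.
    """
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    S = N = Sd = Nd = 0.0
    flags: list[str] = []
    for ca, cb in aln.codon_pairs():
        sa = ng86_sites(ca)
        sb = ng86_sites(cb)
        S += (sa[0] + sb[0]) / 2.0
        N += (sa[1] + sb[1]) / 2.0
        try:
            ds, dn = ng86_differences(ca, cb)
        except PathwayDegenerateError:
            if "pathway_degenerate" not in flags:
                flags.append("pathway_degenerate")
            continue
        Sd += ds
        Nd += dn
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, satS = _jc_correct(pS)
    dN, satN = _jc_correct(pN)
    if satS or satN:
        flags.append("saturated")
    w: float | None
    if not math.isnan(dS) and dS > 0 and not math.isnan(dN):
        w = dN / dS
    else:
        w = None
        if dS == 0:
            flags.append("undefined_w")
    return OmegaEstimate(
        method="NG86", S_sites=S, N_sites=N, S_diffs=Sd, N_diffs=Nd,
        dS=dS, dN=dN, w=w, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# GY94-style pairwise maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class CodonModelParams:
    """Parameters of the pairwise codon substitution model."""

    t: float
    omega: float
    kappa: float
    codon_frequencies: np.ndarray | str = "uniform"

    def frequencies(self) -> np.ndarray:
        if isinstance(self.codon_frequencies, str):
            if self.codon_frequencies != "uniform":
                raise ValueError(
                    "frequencies must be an array, or the string 'uniform'"
                )
            return np.full(N_CODONS, 1.0 / N_CODONS)
        pi = np.asarray(self.codon_frequencies, dtype=float)
        if pi.shape != (N_CODONS,) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be 61 values summing to 1")
        return pi


def empirical_codon_frequencies(aln: CodonAlignment, kind: str = "F3x4") -> np.ndarray:
    """F1x4 / F3x4 codon frequencies estimated from the alignment."""
    seqs = aln.seq_a + aln.seq_b
    if kind == "F1x4":
        counts = np.array([seqs.count(n) for n in _NUCS], dtype=float) + 1.0
        f = counts / counts.sum()
        fpos = [f, f, f]
    elif kind == "F3x4":
        fpos = []
        for pos in range(3):
            sub = seqs[pos::3]
            counts = np.array([sub.count(n) for n in _NUCS], dtype=float) + 1.0
            fpos.append(counts / counts.sum())
    else:
        raise ValueError(f"kind must be 'F1x4' or 'F3x4', got {kind!r}")
    pi = np.array(
        [
            fpos[0][_NUCS.index(c[0])]
            * fpos[1][_NUCS.index(c[1])]
            * fpos[2][_NUCS.index(c[2])]
            for c in CODONS
        ]
    )
    return pi / pi.sum()


def _rate_matrix(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """Normalized GY94 generator: q_ij = pi_j * kappa^ts * omega^nonsyn."""
    R = (
        _TV_SYN * 1.0
        + _TS_SYN * kappa
        + _TV_NON * omega
        + _TS_NON * (kappa * omega)
    )
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu > 0:
        Q /= mu
    return Q


def _transition_probs(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetrization (the model is time reversible)."""
    sqrt_pi = np.sqrt(pi)
    A = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    A = (A + A.T) / 2.0  # enforce exact symmetry
    lam, V = np.linalg.eigh(A)
    expd = np.exp(lam * t)
    P = (V * expd[None, :]) @ V.T
    P = P * (sqrt_pi[None, :] / sqrt_pi[:, None])
    return np.clip(P, 1e-300, None)


def pair_count_matrix(aln: CodonAlignment) -> np.ndarray:
    """61x61 matrix of observed codon-pair counts."""
    N = np.zeros((N_CODONS, N_CODONS))
    for ca, cb in aln.codon_pairs():
        N[CODON_INDEX[ca], CODON_INDEX[cb]] += 1.0
    return N


def gy94_loglik(aln: CodonAlignment, params: CodonModelParams) -> float:
    """Log-likelihood of the pair under the codon model.

    lnL = sum over codon columns of log[pi(a) P(a -> b; t)].  Time
    reversibility makes the value symmetric in the order of the two
    sequences.
    """
    pi = params.frequencies()
    N = pair_count_matrix(aln)
    return _loglik_from_counts(N, params.t, params.omega, params.kappa, pi)


def _loglik_from_counts(
    N: np.ndarray, t: float, omega: float, kappa: float, pi: np.ndarray
) -> float:
    Q = _rate_matrix(omega, kappa, pi)
    P = _transition_probs(Q, pi, t)
    i, j = np.nonzero(N)
    return float((N[i, j] * np.log(pi[i] * P[i, j])).sum())


_T_BOUNDS = (1e-6, 50.0)
_W_BOUNDS = (1e-4, 99.0)
_K_BOUNDS = (0.01, 100.0)
_STARTS = [(0.1, 0.3), (0.1, 3.0), (1.0, 0.3), (1.0, 3.0)]  # (t, omega)
_KAPPA_START = 2.0


def ml_pairwise_omega(
    aln: CodonAlignment,
    kappa: float | None = None,
    frequencies: str = "uniform",
    min_variable_codons: int = 10,
) -> OmegaEstimate:
    """Maximum-likelihood (t, omega[, kappa]) for one codon pair.

    Bounded L-BFGS-B in log-parameter space from a fixed grid of starts
    (t in {0.1, 1.0} x omega in {0.3, 3.0}; kappa starts at 2 when
    estimated).  ``kappa=None`` (default) estimates kappa jointly; a float
    fixes it.  The null log-likelihood re-optimizes the same nuisance
    parameters with omega pinned at 1, so the LRT has one degree of
    freedom.
    """
    if aln.n_codons == 0:
        raise ValueError("empty alignment")
    pi = (
        np.full(N_CODONS, 1.0 / N_CODONS)
        if frequencies == "uniform"
        else empirical_codon_frequencies(aln, frequencies)
    )
    Ncounts = pair_count_matrix(aln)
    n_var = sum(ca != cb for ca, cb in aln.codon_pairs())
    flags: list[str] = []
    if n_var == 0:
        sites = _ml_site_totals(aln)
        return OmegaEstimate(
            method="ML", S_sites=sites[0], N_sites=sites[1],
            S_diffs=0.0, N_diffs=0.0, dS=0.0, dN=0.0, w=None,
            t=_T_BOUNDS[0], kappa=kappa, flags=("unidentifiable",),
        )
    if n_var < min_variable_codons:
        flags.append("few_variable_codons")

    fit_kappa = kappa is None

    def unpack(x):
        t = math.exp(x[0])
        w = math.exp(x[1])
        k = math.exp(x[2]) if fit_kappa else kappa
        return t, w, k

    def neg_loglik(x):
        t, w, k = unpack(x)
        return -_loglik_from_counts(Ncounts, t, w, k, pi)

    bounds = [np.log(_T_BOUNDS), np.log(_W_BOUNDS)]
    if fit_kappa:
        bounds.append(np.log(_K_BOUNDS))
    best = None
    any_success = False
    for t0, w0 in _STARTS:
        x0 = [math.log(t0), math.log(w0)]
        if fit_kappa:
            x0.append(math.log(_KAPPA_START))
        res = optimize.minimize(
            neg_loglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        flags.append("estimation_failure")
    t_hat, w_hat, k_hat = unpack(best.x)
    lnl_alt = -best.fun

    # null: omega fixed at 1, same nuisance parameters free
    def neg_loglik_null(x):
        t = math.exp(x[0])
        k = math.exp(x[1]) if fit_kappa else kappa
        return -_loglik_from_counts(Ncounts, t, 1.0, k, pi)

    nbounds = [np.log(_T_BOUNDS)] + ([np.log(_K_BOUNDS)] if fit_kappa else [])
    nbest = None
    for t0 in (0.1, 1.0):
        x0 = [math.log(t0)] + ([math.log(_KAPPA_START)] if fit_kappa else [])
        res = optimize.minimize(
            neg_loglik_null, x0, method="L-BFGS-B", bounds=nbounds,
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        if nbest is None or res.fun < nbest.fun:
            nbest = res
    lnl_null = -nbest.fun

    # model-based decomposition: synonymous share of the substitution flux
    # at the MLE, and of the mutational opportunity (omega = 1), give the
    # per-site rates dS, dN and the site counts (codeml's convention).
    fS_hat = _syn_flux_fraction(w_hat, k_hat, pi)
    fS_neutral = _syn_flux_fraction(1.0, k_hat, pi)
    s_sites_codon = 3.0 * fS_neutral
    n_sites_codon = 3.0 - s_sites_codon
    dS = t_hat * fS_hat / s_sites_codon
    dN = t_hat * (1.0 - fS_hat) / n_sites_codon
    est = OmegaEstimate(
        method="ML",
        S_sites=s_sites_codon * aln.n_codons,
        N_sites=n_sites_codon * aln.n_codons,
        S_diffs=t_hat * fS_hat * aln.n_codons,
        N_diffs=t_hat * (1.0 - fS_hat) * aln.n_codons,
        dS=dS, dN=dN,
        w=w_hat, t=t_hat, kappa=k_hat if fit_kappa else kappa,
        lnL_alt=lnl_alt, lnL_null=lnl_null, flags=tuple(flags),
    )
    est.p_value = lrt_omega(est)
    return est


_SYN_MASK = _TV_SYN | _TS_SYN


def _syn_flux_fraction(omega: float, kappa: float, pi: np.ndarray) -> float:
    """Share of the total substitution flux that is synonymous."""
    Q = _rate_matrix(omega, kappa, pi)
    off = Q * pi[:, None]
    np.fill_diagonal(off, 0.0)
    total = off.sum()
    return float(off[_SYN_MASK].sum() / total)


def _ml_site_totals(aln: CodonAlignment) -> tuple[float, float]:
    S = N = 0.0
    for ca, cb in aln.codon_pairs():
        sa, sb = ng86_sites(ca), ng86_sites(cb)
        S += (sa[0] + sb[0]) / 2.0
        N += (sa[1] + sb[1]) / 2.0
    return S, N


def lrt_omega(est: OmegaEstimate) -> float:
    """LRT p-value of omega = 1: 2 dlnL (clipped at 0) vs chi-square(1)."""
    if est.method != "ML" or est.lnL_alt is None or est.lnL_null is None:
        raise ValueError("LRT needs an ML estimate with both log-likelihoods")
    stat = max(0.0, 2.0 * (est.lnL_alt - est.lnL_null))
    return float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# classification and the per-family summary
# ---------------------------------------------------------------------------

@dataclass
class SelectionCall:
    label: str  # positive | purifying | neutral | inconclusive
    w: float | None
    p_value: float
    alpha: float


def classify_selection(w: float | None, p: float, alpha: float = 0.05) -> SelectionCall:
    """Call the selection regime from (omega, LRT p-value).

    Neutrality not rejected (p >= alpha) -> neutral; otherwise omega > 1 is
    positive and omega < 1 purifying selection; an undefined omega is
    inconclusive.
    """
    if w is None or (isinstance(w, float) and math.isnan(w)):
        label = "inconclusive"
    elif p >= alpha:
        label = "neutral"
    elif w > 1.0:
        label = "positive"
    elif w < 1.0:
        label = "purifying"
    else:
        label = "neutral"
    return SelectionCall(label=label, w=w, p_value=p, alpha=alpha)


def fisher_combined_p(p_values: list[float]) -> tuple[float, float]:
    """Fisher's method: statistic -2 sum(ln p) against chi-square(2k)."""
    ps = [max(min(p, 1.0), 1e-300) for p in p_values]
    stat = -2.0 * sum(math.log(p) for p in ps)
    return stat, float(chi2.sf(stat, df=2 * len(ps)))


def taxonpair_omega_summary(
    estimates: dict[str, list[OmegaEstimate]], combine: str = "fisher"
) -> pd.DataFrame:
    """Per-family mean omega, SEM and combined LRT p over taxon pairs.

    Flagged (undefined-omega) estimates are excluded from the mean/SEM; a
    family whose estimates are all flagged still gets a row, flagged.
    ``combine='fisher'`` pools pairwise LRT p-values by Fisher's method;
    ``'none'`` leaves the combined p empty.
    """
    rows = []
    for family in sorted(estimates):
        ests = estimates[family]
        if len(ests) < 2:
            raise ValueError(f"family {family!r} needs >= 2 estimates")
        ws = [e.w for e in ests if e.w is not None and not math.isnan(e.w)]
        ps = [e.p_value for e in ests if e.p_value is not None]
        row = {"family": family, "n_pairs": len(ests), "n_defined": len(ws)}
        if ws:
            arr = np.asarray(ws)
            row["mean_w"] = float(arr.mean())
            row["sem_w"] = (
                float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
            )
            row["flags"] = ""
        else:
            row["mean_w"] = math.nan
            row["sem_w"] = math.nan
            row["flags"] = "all_flagged"
        if combine == "fisher" and ps:
            row["p_combined"] = fisher_combined_p(ps)[1]
        elif combine == "none" or not ps:
            row["p_combined"] = math.nan
        else:
            raise ValueError(f"combine must be 'fisher' or 'none', got {combine!r}")
        rows.append(row)
    return pd.DataFrame(rows)
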
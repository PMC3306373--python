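"""Genome-wide admixture-scan statistics.

Two statistics are computed at every marker:

* the *locus-genome* statistic — in cases only, the likelihood of the local
  ancestry data under a multiplicative risk model psi (odds per
  European-origin allele) relative to the null, averaged over a
  pre-specified grid of risk models and reported as a log10 LOD score; and
* the *case-control* statistic Z — the standardized case-vs-control
  difference in the locus-specific deviation of posterior mean local
  European ancestry from each individual's genome-wide average.

The per-case likelihood ratio reweights the unmodified HMM posterior
gamma_i by psi^e and normalises by the same reweighting of the individual's
stationary prior pi_i = Binomial(2, M_i):

    LR(psi) = prod_i [ sum_e gamma_i(e) psi^e / sum_e pi_i(e) psi^e ].

LOD = log10 of the mean LR over the risk-model grid; the genome-wide score
is log10 of the mean (over loci) of the per-locus psi-averaged LR.
Thresholds: LOD >= 5 genome-wide significant, >= 4 suggestive; genome-wide
score >= 2 significant, >= 1 suggestive; |Z| >= 4.06 significant
(two-sided normal tail 5e-5, i.e. 0.05 after a 1,000-hypothesis
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .hmm import stationary_prior

PSI_GRID = (0.7, 0.8, 0.9, 1.1, 1.2, 1.3)

LOD_SIGNIFICANT = 5.0
LOD_SUGGESTIVE = 4.0
GENOME_SCORE_SIGNIFICANT = 2.0
GENOME_SCORE_SUGGESTIVE = 1.0
Z_SIGNIFICANT = 4.06


def z_threshold_pvalue(z: float = Z_SIGNIFICANT) -> float:
    """Two-sided standard-normal tail probability of |Z| >= z."""
    return float(2.0 * stats.norm.sf(z))


def locus_log10_lr(gammas: np.ndarray, priors: np.ndarray, psi: float) -> float:
    """log10 likelihood ratio at one locus for one risk model psi.

    ``gammas`` and ``priors`` are (n_cases, 3) probability vectors over the
    European allele count e; an empty case set gives log10 LR = 0.
    """
    if psi <= 0:
        raise ValueError("risk model psi must be > 0")
    gammas = np.atleast_2d(np.asarray(gammas, dtype=float))
    priors = np.atleast_2d(np.asarray(priors, dtype=float))
    if gammas.size == 0:
        return 0.0
    if gammas.shape != priors.shape or gammas.shape[1] != 3:
        raise ValueError("gammas and priors must both be (n_cases, 3)")
    if psi == 1.0:
        return 0.0  # analytically exact for probability vectors
    w = psi ** np.arange(3)
    num = gammas @ w
    den = priors @ w
    return float(np.sum(np.log10(num) - np.log10(den)))


def locus_likelihood_ratio(gammas: np.ndarray, priors: np.ndarray, psi: float) -> float:
    """Likelihood ratio at one locus (may be astronomically large; see locus_log10_lr)."""
    return float(10.0 ** locus_log10_lr(gammas, priors, psi))


def locus_genome_lod(log10_lr_by_psi) -> float:
    """LOD = log10 of the mean likelihood ratio over the risk-model grid.

    Accepts a mapping {psi: log10 LR} or a sequence aligned to PSI_GRID;
    all six grid models are required. Averaging is done in log space.
    """
    if isinstance(log10_lr_by_psi, dict):
        missing = [p for p in PSI_GRID if p not in log10_lr_by_psi]
        if missing:
            raise ValueError(f"missing risk models: {missing}")
        vals = np.array([log10_lr_by_psi[p] for p in PSI_GRID], dtype=float)
    else:
        vals = np.asarray(log10_lr_by_psi, dtype=float)
        if vals.shape[-1] != len(PSI_GRID):
            raise ValueError(f"expected {len(PSI_GRID)} risk models, got {vals.shape[-1]}")
    ln10 = np.log(10.0)
    return float((logsumexp(vals * ln10, axis=-1) - np.log(len(PSI_GRID))) / ln10)


def genome_wide_score(locus_lods: np.ndarray) -> float:
    """log10 of the genome-averaged likelihood ratio.

    ``locus_lods`` are per-locus LOD values (log10 of the psi-averaged LR);
    the score is log10(mean_l 10^lod_l), computed stably.
    """
    lods = np.asarray(locus_lods, dtype=float)
    if lods.size == 0:
        raise ValueError("need at least one locus")
    ln10 = np.log(10.0)
    return float((logsumexp(lods * ln10) - np.log(lods.size)) / ln10)


def case_control_z(
    local_european_mean: np.ndarray,
    M_hat: np.ndarray,
    case_labels: np.ndarray,
) -> np.ndarray:
    """Case-control ancestry-deviation Z at every locus.

    ``local_european_mean`` is (n_individuals, n_loci) posterior mean local
    European ancestry, ``M_hat`` the per-individual genome-wide European
    proportion. Positive Z means cases carry MORE European ancestry at the
    locus than controls. Uses a Welch two-sample standard error; loci where
    either group has fewer than two members are NaN.
    """
    local = np.atleast_2d(np.asarray(local_european_mean, dtype=float))
    labels = np.asarray(case_labels, dtype=bool)
    delta = local - np.asarray(M_hat, dtype=float)[:, None]
    dc, dn = delta[labels], delta[~labels]
    if dc.shape[0] < 2 or dn.shape[0] < 2:
        return np.full(local.shape[1], np.nan)
    se = np.sqrt(
        dc.var(axis=0, ddof=1) / dc.shape[0] + dn.var(axis=0, ddof=1) / dn.shape[0]
    )
    diff = dc.mean(axis=0) - dn.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / se
    # Degenerate loci with no within-group variation and no difference: z = 0.
    z[(se == 0) & (diff == 0)] = 0.0
    return z


def classify_lod(lod: np.ndarray) -> np.ndarray:
    """Per-locus call from the LOD score: none / suggestive / significant."""
    lod = np.asarray(lod, dtype=float)
    calls = np.where(
        lod >= LOD_SIGNIFICANT, "significant", np.where(lod >= LOD_SUGGESTIVE, "suggestive", "none")
    )
    return calls.astype(object)


def classify_genome_score(score: float) -> str:
    if score >= GENOME_SCORE_SIGNIFICANT:
        return "significant"
    if score >= GENOME_SCORE_SUGGESTIVE:
        return "suggestive"
    return "none"


def classify_z(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    calls = np.where(np.abs(z) >= Z_SIGNIFICANT, "significant", "none")
    calls = calls.astype(object)
    calls[np.isnan(z)] = "undefined"
    return calls


@dataclass
class ScanResult:
    """Genome-scan output: per-locus table plus scan-level summaries."""

    table: pd.DataFrame  # chromosome, genetic_pos, physical_pos, lod, lr_psi_*, z, calls
    genome_score: float
    genome_call: str


def run_scan(
    local_european_mean: np.ndarray,
    gammas: np.ndarray,
    M_hat: np.ndarray,
    case_labels: np.ndarray,
    panel: pd.DataFrame,
    psi_grid=PSI_GRID,
) -> ScanResult:
    """Full two-statistic scan at every marker.

    ``gammas`` is (n_individuals, n_loci, 3) posterior probabilities from
    the HMM under the unmodified prior; the LOD uses cases only, the Z uses
    everyone.
    """
    gammas = np.asarray(gammas, dtype=float)
    labels = np.asarray(case_labels, dtype=bool)
    M_hat = np.asarray(M_hat, dtype=float)
    priors = stationary_prior(M_hat)  # (N, 3)
    case_g = gammas[labels]
    case_p = priors[labels]
    n_loci = gammas.shape[1]

    powers = np.array([[p**e for e in range(3)] for p in psi_grid])  # (npsi, 3)
    num = np.einsum("nle,pe->pnl", case_g, powers)
    den = np.einsum("ne,pe->pn", case_p, powers)
    log10_lr = np.log10(num).sum(axis=1) - np.log10(den).sum(axis=1)[:, None]  # (npsi, L)

    lods = np.array([locus_genome_lod(log10_lr[:, l]) for l in range(n_loci)])
    z = case_control_z(local_european_mean, M_hat, labels)
    score = genome_wide_score(lods)

    table = panel[["marker_id", "chromosome", "genetic_pos", "physical_pos"]].copy()
    table["lod"] = lods
    for i, p in enumerate(psi_grid):
        table[f"log10_lr_psi_{p}"] = log10_lr[i]
    table["z"] = z
    table["lod_call"] = classify_lod(lods)
    table["z_call"] = classify_z(z)
    return ScanResult(table=table, genome_score=score, genome_call=classify_genome_score(score))


def scan_intervals_bed(table: pd.DataFrame, level: str = "suggestive") -> pd.DataFrame:
    """Contiguous called marker runs as 0-based half-open BED intervals."""
    want = {"suggestive": ("suggestive", "significant"), "significant": ("significant",)}[level]
    rows = []
    for chrom, sub in table.groupby("chromosome", sort=True):
        mask = sub["lod_call"].isin(want).to_numpy()
        pos = sub["physical_pos"].to_numpy()
        start = None
        for i, flag in enumerate(mask):
            if flag and start is None:
                start = i
            if start is not None and (not flag or i == len(mask) - 1):
                end = i if not flag else i + 1
                rows.append(
                    {"chrom": f"chr{chrom}", "start": int(pos[start] - 1), "end": int(pos[end - 1])}
                )
                start = None
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class PowerResult:
    power: float
    se: float
    reps: int
    detections: int
    threshold: float


def power_simulation(
    n_cases: int,
    psi_true: float,
    reps: int = 500,
    threshold: float = LOD_SIGNIFICANT,
    beta_a: float | None = None,
    beta_b: float | None = None,
    mean_european: float = 0.16,
    rng: np.random.Generator | int | None = None,
    psi_grid=PSI_GRID,
) -> PowerResult:
    """Monte-Carlo power of the case-only locus-genome scan at one locus.

    Each replicate draws ``n_cases`` individuals with European proportion
    M_i (Beta(beta_a, beta_b) when given, else fixed at ``mean_european``)
    and a true local European allele count e_i from the psi_true-weighted
    prior P(e | case) proportional to pi_i(e) * psi_true^e — i.e. ancestry
    at the locus is fully informative and perfectly inferred. The locus LOD
    is computed over ``psi_grid`` and detection declared when it exceeds
    ``threshold``.
    """
    if psi_true <= 0:
        raise ValueError("psi_true must be > 0")
    if reps < 50:
        raise ValueError("need at least 50 replicates for a stable power estimate")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    if beta_a is not None and beta_b is not None:
        M = rng.beta(beta_a, beta_b, size=(reps, n_cases))
    else:
        M = np.full((reps, n_cases), float(mean_european))
    pi = stationary_prior(M)  # (reps, n, 3)
    w_true = psi_true ** np.arange(3)
    p_case = pi * w_true
    p_case /= p_case.sum(axis=-1, keepdims=True)
    u = rng.uniform(size=(reps, n_cases, 1))
    e = (u > np.cumsum(p_case, axis=-1)[..., :2]).sum(axis=-1)  # (reps, n) in {0,1,2}

    log10_lr = np.empty((reps, len(psi_grid)))
    for k, psi in enumerate(psi_grid):
        w = psi ** np.arange(3)
        log10_lr[:, k] = (e * np.log10(psi)).sum(axis=1) - np.log10(pi @ w).sum(axis=1)
    lods = np.array([locus_genome_lod(row) for row in log10_lr])
    detections = int((lods > threshold).sum())
    power = detections / reps
    se = float(np.sqrt(power * (1 - power) / reps))
    return PowerResult(power=power, se=se, reps=reps, detections=detections, threshold=threshold)
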
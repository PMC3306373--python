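"""Diploid hidden Markov model for local and global ancestry inference.

The hidden state at each marker is e in {0, 1, 2}, the number of
European-origin alleles. Each haplotype follows a two-state Markov chain
along the genetic map: over a distance d Morgans it keeps its ancestry with
probability exp(-lambda*d) and otherwise redraws it (European with
probability M, the individual's genome-wide European proportion). The two
haplotypes are independent, so the diploid transition matrix is the tensor
square of the haploid one collapsed onto allele counts, and the stationary
prior at any locus is Binomial(2, M):
    pi(e) = ((1-M)^2, 2M(1-M), M^2).

Emissions: each European-origin allele carries the counted variant with
probability pE, each African-origin allele with probability pA; the
genotype is the unphased allele sum. A missing genotype is uninformative
(emission 1 for every state).

Global ancestry is estimated per individual by maximising the HMM
log-likelihood over a grid of (M, lambda); African ancestry is 1 - M_hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, EstimationError

FREQ_CLAMP = 1e-4  # guard against impossible-data zeros from genotyping error

DEFAULT_M_GRID = np.round(np.arange(0.005, 0.9951, 0.005), 6)
DEFAULT_LAMBDA_GRID = (2.0, 4.0, 6.0, 8.0, 10.0)

# Unordered diploid state e = h1 + h2 with haploid coding 0=African, 1=European.
_HAPLOID_PAIRS = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
_PAIR_TO_E = np.array([0, 1, 1, 2])


def haploid_transition(d: float, lambda_gen: float, M: float) -> np.ndarray:
    """2x2 haploid transition over d Morgans; state order (African, European)."""
    if d < 0:
        raise ValueError("genetic distance must be non-negative")
    stay = np.exp(-lambda_gen * d)
    redraw = np.array([[1.0 - M, M], [1.0 - M, M]])
    return stay * np.eye(2) + (1.0 - stay) * redraw


def transition_matrix(d: float, lambda_gen: float, M: float) -> np.ndarray:
    """3x3 diploid transition over e in {0, 1, 2} European alleles."""
    H = haploid_transition(d, lambda_gen, M)
    T = np.zeros((3, 3))
    for i, (a1, a2) in enumerate(_HAPLOID_PAIRS):
        for j, (b1, b2) in enumerate(_HAPLOID_PAIRS):
            # From e=1 the ordered representative (0,1) is used; exchangeability
            # of the haplotypes makes the collapsed matrix well defined.
            if (a1, a2) == (1, 0):
                continue
            T[_PAIR_TO_E[i], _PAIR_TO_E[j]] += H[a1, b1] * H[a2, b2]
    return T


def stationary_prior(M: float | np.ndarray) -> np.ndarray:
    """Binomial(2, M) prior over the diploid European allele count."""
    M = np.asarray(M, dtype=float)
    return np.stack([(1 - M) ** 2, 2 * M * (1 - M), M**2], axis=-1)


def emission_prob(g, e: int, pE: float, pA: float) -> float:
    """P(genotype g | e European-origin alleles) for one marker.

    ``g`` may be NaN/None for missing (probability 1 for every state).
    """
    if g is None or (isinstance(g, float) and np.isnan(g)):
        return 1.0
    if g not in (0, 1, 2):
        raise ValueError(f"invalid genotype code {g!r}")
    if not (0 <= pE <= 1 and 0 <= pA <= 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    pE = float(np.clip(pE, FREQ_CLAMP, 1 - FREQ_CLAMP))
    pA = float(np.clip(pA, FREQ_CLAMP, 1 - FREQ_CLAMP))
    g = int(g)
    if e == 0:
        probs = [(1 - pA) ** 2, 2 * pA * (1 - pA), pA**2]
    elif e == 2:
        probs = [(1 - pE) ** 2, 2 * pE * (1 - pE), pE**2]
    elif e == 1:
        probs = [
            (1 - pE) * (1 - pA),
            pE * (1 - pA) + (1 - pE) * pA,
            pE * pA,
        ]
    else:
        raise ValueError(f"invalid ancestry state {e!r}")
    return probs[g]


def emission_matrix(genotypes: np.ndarray, panel: pd.DataFrame) -> np.ndarray:
    """(n_markers, 3) emission probabilities for one individual; missing rows = 1."""
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] != len(panel):
        raise AlignmentError(f"genotypes length {g.shape[0]} != panel size {len(panel)}")
    bad = ~(np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0)))
    if bad.any():
        raise ValueError(f"invalid genotype code {g[bad][0]!r} at marker index {np.where(bad)[0][0]}")
    pE = np.clip(panel["pE"].to_numpy(), FREQ_CLAMP, 1 - FREQ_CLAMP)
    pA = np.clip(panel["pA"].to_numpy(), FREQ_CLAMP, 1 - FREQ_CLAMP)

    def binom2(p):  # P(g | two alleles at freq p), columns g=0,1,2
        return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)

    by_e = np.stack(
        [
            binom2(pA),
            np.stack(
                [(1 - pE) * (1 - pA), pE * (1 - pA) + (1 - pE) * pA, pE * pA], axis=1
            ),
            binom2(pE),
        ],
        axis=1,
    )  # (L, 3 states, 3 genotypes)
    em = np.ones((len(panel), 3))
    obs = ~np.isnan(g)
    em[obs] = by_e[obs, :, g[obs].astype(int)]
    return em


@dataclass
class AncestryPosterior:
    """Per-individual HMM output.

    ``gamma[l, e]`` is the posterior probability of carrying ``e``
    European-origin alleles at marker ``l``; ``local_european_mean`` is the
    posterior mean local European ancestry (sum_e e*gamma_e)/2.
    """

    M_hat: float  # European proportion at the likelihood optimum
    lambda_hat: float
    log_likelihood: float
    gamma: np.ndarray  # (n_markers, 3)
    local_european_mean: np.ndarray = field(init=False)

    def __post_init__(self):
        self.local_european_mean = (self.gamma[:, 1] + 2.0 * self.gamma[:, 2]) / 2.0

    @property
    def african_ancestry(self) -> float:
        return 1.0 - self.M_hat

    @property
    def genome_mean_european(self) -> float:
        return float(self.local_european_mean.mean())


def _chromosome_blocks(panel: pd.DataFrame):
    """Yield (index array, genetic distances) per chromosome, panel order."""
    for _chrom, idx in panel.groupby("chromosome", sort=True).indices.items():
        pos = panel["genetic_pos"].to_numpy()[idx]
        yield idx, np.diff(pos)


def forward_backward(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    M: float,
    lambda_gen: float,
) -> AncestryPosterior:
    """Exact smoothed posteriors and total log-likelihood for one individual.

    Chromosomes are independent; each restarts from the stationary prior.
    Scaled recursions keep the computation stable over thousands of markers.
    """
    em = emission_matrix(genotypes, panel)
    pi = stationary_prior(M)
    gamma = np.empty((len(panel), 3))
    loglik = 0.0
    for idx, dists in _chromosome_blocks(panel):
        e = em[idx]
        L = len(idx)
        trans = [transition_matrix(d, lambda_gen, M) for d in dists]
        alpha = np.empty((L, 3))
        scale = np.empty(L)
        a = pi * e[0]
        scale[0] = a.sum()
        if scale[0] <= 0:
            raise EstimationError(f"zero-probability model at marker index {idx[0]}")
        alpha[0] = a / scale[0]
        for t in range(1, L):
            a = (alpha[t - 1] @ trans[t - 1]) * e[t]
            scale[t] = a.sum()
            if scale[t] <= 0:
                raise EstimationError(f"zero-probability model at marker index {idx[t]}")
            alpha[t] = a / scale[t]
        beta = np.empty((L, 3))
        beta[-1] = 1.0
        for t in range(L - 2, -1, -1):
            beta[t] = (trans[t] @ (e[t + 1] * beta[t + 1])) / scale[t + 1]
        g = alpha * beta
        gamma[idx] = g / g.sum(axis=1, keepdims=True)
        loglik += float(np.log(scale).sum())
    return AncestryPosterior(float(M), float(lambda_gen), loglik, gamma)


def log_likelihood_backward(
    genotypes: np.ndarray, panel: pd.DataFrame, M: float, lambda_gen: float
) -> float:
    """Total log-likelihood via the backward recursion (numerical cross-check)."""
    em = emission_matrix(genotypes, panel)
    pi = stationary_prior(M)
    loglik = 0.0
    for idx, dists in _chromosome_blocks(panel):
        e = em[idx]
        L = len(idx)
        trans = [transition_matrix(d, lambda_gen, M) for d in dists]
        b = np.ones(3)
        logz = 0.0
        for t in range(L - 2, -1, -1):
            b = trans[t] @ (e[t + 1] * b)
            s = b.sum()
            logz += np.log(s)
            b = b / s
        total = float(pi @ (e[0] * b))
        loglik += logz + np.log(total)
    return loglik


def _grid_transitions(panel: pd.DataFrame, m_grid: np.ndarray, lam: float):
    """Per-chromosome stacks of (n_steps, n_M, 3, 3) diploid transitions."""
    out = []
    for idx, dists in _chromosome_blocks(panel):
        stay = np.exp(-lam * dists)[:, None]  # (steps, 1)
        m = m_grid[None, :]
        # Haploid entries as functions of (stay s, M):
        # P(A->A)=s+(1-s)(1-M), P(A->E)=(1-s)M, P(E->A)=(1-s)(1-M), P(E->E)=s+(1-s)M
        shape = (len(dists), len(m_grid))
        h = np.empty(shape + (2, 2))
        h[..., 0, 0] = stay + (1 - stay) * (1 - m)
        h[..., 0, 1] = (1 - stay) * m
        h[..., 1, 0] = (1 - stay) * (1 - m)
        h[..., 1, 1] = stay + (1 - stay) * m
        T = np.zeros(shape + (3, 3))
        reps = [(0, 0), (0, 1), (1, 1)]  # ordered representative per e
        for i, (a1, a2) in enumerate(reps):
            for j, (b1, b2) in enumerate(_HAPLOID_PAIRS):
                T[..., i, _PAIR_TO_E[j]] += h[..., a1, b1] * h[..., a2, b2]
        out.append((idx, T))
    return out


def _grid_loglik(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    m_grid: np.ndarray,
    lambda_grid,
) -> np.ndarray:
    """Forward log-likelihood on the (M, lambda) grid, batched over individuals.

    Returns (n_individuals, n_M, n_lambda).
    """
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    N = G.shape[0]
    ems = np.stack([emission_matrix(G[i], panel) for i in range(N)])  # (N, L, 3)
    pi = stationary_prior(m_grid)  # (nM, 3)
    nM = len(m_grid)
    out = np.empty((N, nM, len(lambda_grid)))
    for k, lam in enumerate(lambda_grid):
        loglik = np.zeros((N, nM))
        for idx, T in _grid_transitions(panel, m_grid, lam):
            e = ems[:, idx, :]  # (N, Lc, 3)
            a = pi[None, :, :] * e[:, 0, None, :]  # (N, nM, 3)
            s = a.sum(axis=2)
            loglik += np.log(s)
            a /= s[..., None]
            for t in range(1, len(idx)):
                a = np.einsum("nmi,mij->nmj", a, T[t - 1]) * e[:, t, None, :]
                s = a.sum(axis=2)
                loglik += np.log(s)
                a /= s[..., None]
        out[:, :, k] = loglik
    return out


def estimate_global_ancestry(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    m_grid: np.ndarray | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    min_informative: int = 50,
    informative_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-individual maximum-likelihood (M_hat, lambda_hat) on a grid.

    Ties in the likelihood are broken toward smaller lambda (ascending grid
    order, strict-improvement argmax). Returns a DataFrame with columns
    M_hat (European), african_ancestry, lambda_hat, log_likelihood.
    """
    if m_grid is None:
        m_grid = DEFAULT_M_GRID
    m_grid = np.asarray(m_grid, dtype=float)
    lambda_grid = tuple(sorted(lambda_grid))
    div = np.abs(panel["pE"].to_numpy() - panel["pA"].to_numpy())
    n_informative = int((div > informative_threshold).sum())
    if n_informative == 0:
        raise EstimationError(
            "no ancestry-informative markers (pE == pA everywhere): "
            "global ancestry is unidentifiable"
        )
    if n_informative < min_informative:
        warnings.warn(
            f"only {n_informative} informative markers (< {min_informative}); "
            "global ancestry estimates will be noisy",
            stacklevel=2,
        )
    ll = _grid_loglik(genotypes, panel, m_grid, lambda_grid)  # (N, nM, nLam)
    if np.ptp(ll) < 1e-6:
        warnings.warn(
            "likelihood is flat over the (M, lambda) grid; estimates are arbitrary",
            stacklevel=2,
        )
    N = ll.shape[0]
    flat = ll.reshape(N, -1)
    # Column-major order over (M, lambda) with lambda fastest would favour
    # small lambda only within one M; take argmax over M for each lambda then
    # first (= smallest) lambda among ties.
    best_per_lam = ll.max(axis=1)  # (N, nLam)
    best_lam_idx = np.argmax(best_per_lam, axis=1)  # first max -> smallest lambda
    rows = []
    for i in range(N):
        k = best_lam_idx[i]
        j = int(np.argmax(ll[i, :, k]))
        rows.append(
            {
                "M_hat": float(m_grid[j]),
                "african_ancestry": float(1.0 - m_grid[j]),
                "lambda_hat": float(lambda_grid[k]),
                "log_likelihood": float(ll[i, j, k]),
            }
        )
    del flat
    return pd.DataFrame(rows)


def infer_cohort(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    m_grid: np.ndarray | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
) -> tuple[pd.DataFrame, list[AncestryPosterior]]:
    """Global-ancestry table plus smoothed local posteriors at the per-individual MLE."""
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    table = estimate_global_ancestry(G, panel, m_grid=m_grid, lambda_grid=lambda_grid)
    posteriors = [
        forward_backward(G[i], panel, row.M_hat, row.lambda_hat)
        for i, row in enumerate(table.itertuples())
    ]
    return table, posteriors
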
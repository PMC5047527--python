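"""Per-sample allelic-imbalance (ASE) estimation and testing.

At every heterozygous SNP with enough coverage in a sample, the imbalance
between reference and alternate reads is summarized by

    beta = log(rho / (1 - rho)),

the log-odds of the reference allele's expression share, where rho is the
reference fraction corrected for the base-miscall rate eps estimated during
genotyping. Positive beta means the reference allele is the more expressed
one. A Wald test (z = beta / se) gives per-site p-values, and Storey
q-values control the FDR within each sample. The (beta, se) pair is exactly
what the downstream conditional-ASE contrast consumes, so the same estimator
drives both tests.

Overdispersion relative to the binomial is absorbed by a beta-binomial
concentration M (M -> infinity recovers the binomial), estimated once per
dataset from the null-dominant bulk of het sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import betabinom, norm

from microase.stats import storey_qvalues

logger = logging.getLogger(__name__)

ASE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "sample",
    "n_ref", "n_alt", "beta", "se", "p", "q", "clamped",
]


@dataclass(frozen=True)
class AseModelParams:
    """Fixed inputs of the ASE estimator.

    epsilon : global base-miscall rate from joint genotyping.
    M : beta-binomial concentration; ``math.inf`` means pure binomial.
    coverage_min : minimum ref+alt reads for a site to be testable.
    """

    epsilon: float = 0.0
    M: float = math.inf
    coverage_min: int = 20

    def __post_init__(self):
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must lie in [0, 0.5)")
        if not self.M > 0:
            raise ValueError("M must be positive (or inf for binomial)")
        if self.coverage_min < 1:
            raise ValueError("coverage_min must be >= 1")


# ---------------------------------------------------------------------------
# Overdispersion
# ---------------------------------------------------------------------------

def estimate_overdispersion(
    counts: list[tuple[int, int]] | np.ndarray,
    coverage_min: int = 20,
    min_sites: int = 50,
    log_m_bounds: tuple[float, float] = (0.0, math.log(1e6)),
) -> tuple[float, bool]:
    """Estimate the beta-binomial concentration M at mean 0.5.

    Most het sites carry no allelic imbalance, so the dispersion of the
    reference fraction around 0.5 across sites identifies M (the
    null-dominant assumption). Maximizes the beta-binomial likelihood with
    both shapes M/2 by a bounded one-dimensional search on log M.

    Returns ``(M_hat, ok)``; with fewer than ``min_sites`` usable sites,
    falls back to the binomial (``M = inf``) with ``ok = False``.

    The likelihood is nearly flat in M once the data look binomial, so the
    estimate collapses to the binomial limit unless finite M improves the
    fit significantly (likelihood ratio above the chi-square(1) 5% point);
    this keeps truly binomial data from drawing an arbitrary large M off
    the plateau.
    """
    arr = np.asarray(counts, dtype=float).reshape(-1, 2)
    tot = arr.sum(axis=1)
    arr = arr[tot >= coverage_min]
    if len(arr) < min_sites:
        logger.warning(
            "estimate_overdispersion: only %d sites with coverage >= %d; "
            "falling back to binomial", len(arr), coverage_min,
        )
        return math.inf, False
    k = arr[:, 0]
    n = arr.sum(axis=1)

    def nll(log_m: float) -> float:
        m = math.exp(log_m)
        return -float(betabinom.logpmf(k, n, m / 2.0, m / 2.0).sum())

    res = minimize_scalar(nll, bounds=log_m_bounds, method="bounded",
                          options={"xatol": 1e-6})
    m_hat = float(math.exp(res.x))
    if res.x >= log_m_bounds[1] - 1e-3:
        return math.inf, True
    from scipy.stats import binom as _binom

    nll_binom = -float(_binom.logpmf(k, n, 0.5).sum())
    if 2.0 * (nll_binom - res.fun) < 3.841:
        return math.inf, True
    return m_hat, True


# ---------------------------------------------------------------------------
# Per-site estimator and test
# ---------------------------------------------------------------------------

def fit_ase(n_ref: int, n_alt: int, params: AseModelParams) -> tuple[float, float, bool]:
    """Estimate (beta, se) for one site in one sample.

    The raw reference fraction r = n_ref / (n_ref + n_alt) is corrected for
    symmetric miscalls, rho = (r - eps) / (1 - 2 eps), then clamped to the
    interior by half a read's worth of proportion, delta = 1 / (2 n), so
    that beta and its standard error stay finite at monoallelic sites. The
    standard error comes from the observed Fisher information of the
    binomial in the beta parameterization, inflated by
    sqrt((M + n) / (M + 1)) for finite beta-binomial concentration M.

    Returns ``(beta, se, clamped)``.
    """
    n = n_ref + n_alt
    if n < params.coverage_min:
        raise ValueError(
            f"coverage {n} below minimum {params.coverage_min}; site should be skipped"
        )
    eps = params.epsilon
    r = n_ref / n
    rho_raw = (r - eps) / (1.0 - 2.0 * eps)
    delta = 1.0 / (2.0 * n)
    rho = min(max(rho_raw, delta), 1.0 - delta)
    clamped = rho != rho_raw
    beta = math.log(rho / (1.0 - rho))
    se = 1.0 / math.sqrt(n * rho * (1.0 - rho))
    if math.isfinite(params.M):
        se *= math.sqrt((params.M + n) / (params.M + 1.0))
    return beta, se, clamped


def ase_test(beta: float, se: float) -> float:
    """Two-sided Wald p-value for beta != 0."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = beta / se
    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Sample-level runner
# ---------------------------------------------------------------------------

def run_ase(
    counts: pd.DataFrame,
    het_sites: pd.DataFrame,
    params: AseModelParams,
    lam: float = 0.5,
) -> pd.DataFrame:
    """ASE table over all (het site, sample) pairs with sufficient coverage.

    ``counts`` is the per-sample SNP count table; ``het_sites`` the
    heterozygote calls from genotyping (joined on chrom/pos/ref/alt). Sites
    below ``params.coverage_min`` ref+alt reads in a sample are skipped.
    q-values are computed within each sample, since samples differ in depth
    and testable-site count.
    """
    het_keys = het_sites[["chrom", "pos", "ref", "alt"]]
    sub = counts.merge(het_keys, on=["chrom", "pos", "ref", "alt"], how="inner")
    sub = sub[(sub["n_ref"] + sub["n_alt"]) >= params.coverage_min].copy()
    n_skipped = len(counts.merge(het_keys, on=["chrom", "pos", "ref", "alt"])) - len(sub)
    if n_skipped:
        logger.info("run_ase: %d (site, sample) pairs below coverage %d",
                    n_skipped, params.coverage_min)
    if sub.empty:
        return pd.DataFrame(columns=ASE_COLUMNS)

    betas = np.empty(len(sub))
    ses = np.empty(len(sub))
    clamped = np.zeros(len(sub), dtype=bool)
    for i, (nr, na) in enumerate(zip(sub["n_ref"].to_numpy(), sub["n_alt"].to_numpy())):
        betas[i], ses[i], clamped[i] = fit_ase(int(nr), int(na), params)
    sub["beta"] = betas
    sub["se"] = ses
    sub["clamped"] = clamped
    sub["p"] = 2.0 * norm.sf(np.abs(betas / ses))
    sub["q"] = np.nan
    for _, idx in sub.groupby("sample", sort=False).groups.items():
        sub.loc[idx, "q"] = storey_qvalues(sub.loc[idx, "p"].to_numpy(), lam=lam)
    return sub[ASE_COLUMNS].reset_index(drop=True)


def significant_ase(ase: pd.DataFrame, q_cut: float = 0.10) -> pd.DataFrame:
    """ASE events at Storey FDR < q_cut (per sample)."""
    return ase[ase["q"] < q_cut].reset_index(drop=True)
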
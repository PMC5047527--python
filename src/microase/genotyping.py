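"""Joint genotyping of SNPs from pooled allele-specific read counts.

RNA-seq reads from every sample of the same cell line are pooled per SNP and
a three-genotype Bayesian caller assigns each site a posterior over
{hom-ref (RR), het (RA), hom-alt (AA)}:

- prior: Hardy–Weinberg at the site's population minor-allele frequency;
- likelihood: Binomial(n_ref; n_ref + n_alt, p_g) with p_RR = 1 - eps,
  p_RA = 0.5, p_AA = eps, where eps is a global base-miscall rate;
- eps is estimated by EM across all sites. Reads matching neither allele
  (n_other) inform eps through an independent Binomial(n_total, eps) factor
  but never enter the genotype likelihood, which keeps the three-genotype
  model binomial and well identified.

Heterozygous sites (the only ones informative for allelic imbalance) are
then selected at a posterior cutoff; the per-sample coverage filter is
applied downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "maf"]
COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "n_ref", "n_alt", "n_other"]

GENOTYPES = ("RR", "RA", "AA")

_EPS_MIN, _EPS_MAX = 1e-6, 0.49


@dataclass(frozen=True)
class JointGenotypeResult:
    """EM output: the per-site call table and the estimated error rate."""

    calls: pd.DataFrame
    epsilon: float
    loglik_trace: tuple[float, ...]
    converged: bool


# ---------------------------------------------------------------------------
# Panel I/O and filtering
# ---------------------------------------------------------------------------

def read_panel(path) -> pd.DataFrame:
    """Read a SNP panel (tab-separated: chrom pos ref alt maf; 1-based pos)."""
    panel = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    return validate_panel(panel)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    if (panel["pos"] < 1).any():
        raise ValueError("panel positions must be >= 1 (1-based)")
    if (panel["ref"] == panel["alt"]).any():
        raise ValueError("panel contains sites with ref == alt")
    if ((panel["maf"] < 0) | (panel["maf"] > 0.5)).any():
        raise ValueError("panel MAF must lie in [0, 0.5] (folded)")
    return panel


def read_bed_intervals(path) -> pd.DataFrame:
    """Read exclusion regions from BED (0-based, half-open)."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str}, comment="#",
    )
    if (bed["start"] < 0).any() or (bed["end"] < 0).any():
        raise ValueError("negative BED coordinates")
    return bed


def filter_panel(
    panel: pd.DataFrame,
    maf_min: float = 0.05,
    excluded_regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the SNP-panel filters: drop MAF < maf_min and blacklisted sites.

    ``excluded_regions`` is a BED-convention table (chrom, start, end;
    0-based half-open). Panel positions are 1-based, so position ``pos`` is
    excluded iff some interval satisfies ``start <= pos - 1 < end``. This is
    the single place the two coordinate conventions meet.

    The MAF boundary is kept: removal applies to MAF strictly below
    ``maf_min``.
    """
    keep = panel["maf"] >= maf_min
    if excluded_regions is not None and len(excluded_regions):
        if (excluded_regions["start"] < 0).any():
            raise ValueError("negative BED coordinates")
        pos0 = panel["pos"].to_numpy() - 1  # to 0-based
        excluded = np.zeros(len(panel), dtype=bool)
        for chrom, chunk in excluded_regions.groupby("chrom", sort=False):
            mask = (panel["chrom"] == chrom).to_numpy()
            if not mask.any():
                continue
            starts = chunk["start"].to_numpy()
            ends = chunk["end"].to_numpy()
            p = pos0[mask]
            hit = ((starts[None, :] <= p[:, None]) & (p[:, None] < ends[None, :])).any(axis=1)
            excluded[np.flatnonzero(mask)] |= hit
        keep &= ~excluded
    out = panel[keep].reset_index(drop=True)
    logger.info("filter_panel: %d of %d sites retained", len(out), len(panel))
    return out


# ---------------------------------------------------------------------------
# Pileup parsing
# ---------------------------------------------------------------------------

class PileupParseError(ValueError):
    pass


def _count_bases(bases: str, quals: str, ref: str, alt: str,
                 min_base_quality: int, lineno: int) -> tuple[int, int, int]:
    """Count ref/alt/other base calls in one samtools-pileup base string."""
    n_ref = n_alt = n_other = 0
    ref, alt = ref.upper(), alt.upper()
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":  # read start: next char is mapping quality
            if i + 1 >= n:
                raise PileupParseError(f"line {lineno}: dangling '^'")
            i += 2
            continue
        if c == "$":  # read end marker
            i += 1
            continue
        if c in "+-":  # indel: +NNseq / -NNseq, not a base call
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"line {lineno}: indel without length")
            length = int(bases[i + 1:j])
            i = j + length
            if i > n:
                raise PileupParseError(f"line {lineno}: truncated indel run")
            continue
        # every remaining symbol consumes one quality character
        if qi >= len(quals):
            raise PileupParseError(f"line {lineno}: quality string too short")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in "*#><":  # deletion placeholder / reference skip
            continue
        if q < min_base_quality:
            continue
        if c in ".,":
            n_ref += 1
        else:
            b = c.upper()
            if b == ref:
                n_ref += 1
            elif b == alt:
                n_alt += 1
            else:
                n_other += 1
    return n_ref, n_alt, n_other


def parse_pileup(
    lines,
    panel: pd.DataFrame,
    min_base_quality: int = 13,
    sample_names: list[str] | None = None,
) -> pd.DataFrame:
    """Build a SNP count table from samtools-mpileup text.

    Each pileup line is ``chrom pos refbase`` followed by one
    ``(depth, bases, quals)`` column triplet per sample. Sites absent from
    the panel are skipped (counted in the log); bases below
    ``min_base_quality`` are discarded; indel runs, read start/end markers
    and deletion placeholders are consumed without being counted.

    Returns a dense count table (one row per panel site x sample; sites with
    no pileup line get zero counts).
    """
    site_index = {
        (c, p): i
        for i, (c, p) in enumerate(zip(panel["chrom"], panel["pos"]))
    }
    refs = panel["ref"].to_numpy()
    alts = panel["alt"].to_numpy()

    rows: dict[tuple[int, int], tuple[int, int, int]] = {}
    n_samples = None
    skipped = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6 or (len(fields) - 3) % 3 != 0:
            raise PileupParseError(f"line {lineno}: expected 3 + 3k fields, got {len(fields)}")
        chrom, pos_s = fields[0], fields[1]
        try:
            pos = int(pos_s)
        except ValueError:
            raise PileupParseError(f"line {lineno}: non-integer position {pos_s!r}") from None
        k = (len(fields) - 3) // 3
        if n_samples is None:
            n_samples = k
        elif k != n_samples:
            raise PileupParseError(f"line {lineno}: inconsistent sample count")
        idx = site_index.get((chrom, pos))
        if idx is None:
            skipped += 1
            continue
        for s in range(k):
            depth_s, bases, quals = fields[3 + 3 * s: 6 + 3 * s]
            if depth_s == "0" or bases == "*":
                continue
            rows[(idx, s)] = _count_bases(
                bases, quals, refs[idx], alts[idx], min_base_quality, lineno
            )
    if skipped:
        logger.info("parse_pileup: skipped %d lines not in panel", skipped)
    if n_samples is None:
        n_samples = 1
    if sample_names is None:
        sample_names = [f"S{i + 1}" for i in range(n_samples)]
    elif len(sample_names) != n_samples:
        raise ValueError("sample_names length does not match pileup columns")

    records = []
    for i in range(len(panel)):
        for s, name in enumerate(sample_names):
            nr, na, no = rows.get((i, s), (0, 0, 0))
            records.append(
                (panel["chrom"].iat[i], panel["pos"].iat[i], refs[i], alts[i],
                 name, nr, na, no)
            )
    return pd.DataFrame(records, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# Joint genotyping (EM over the global error rate)
# ---------------------------------------------------------------------------

def pool_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum counts across samples per site (joint-genotyping substrate)."""
    pooled = (
        counts.groupby(["chrom", "pos", "ref", "alt"], sort=False, as_index=False)[
            ["n_ref", "n_alt", "n_other"]
        ].sum()
    )
    return pooled


def _hw_log_prior(maf: np.ndarray) -> np.ndarray:
    """Hardy–Weinberg genotype log-prior; maf is the ALT (minor) frequency."""
    f = np.clip(maf, 1e-12, 1 - 1e-12)
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2], axis=1)
    return np.log(prior)


def _log_lik(n_ref: np.ndarray, n_tot: np.ndarray, eps: float) -> np.ndarray:
    """Per-site log-likelihood of (RR, RA, AA); n_tot = n_ref + n_alt."""
    p = np.array([1.0 - eps, 0.5, eps])
    return binom.logpmf(n_ref[:, None], n_tot[:, None], p[None, :])


def genotype_posterior(n_ref: int, n_alt: int, maf: float, eps: float) -> np.ndarray:
    """Posterior over (RR, RA, AA) for one site at a known error rate.

    Hardy–Weinberg prior at alt-allele frequency ``maf``; binomial
    likelihood on ref reads out of ref+alt. The EM-free building block of
    ``joint_genotype``.
    """
    log_joint = (
        _hw_log_prior(np.array([maf]))
        + _log_lik(np.array([float(n_ref)]), np.array([float(n_ref + n_alt)]), eps)
    )
    return np.exp(log_joint - logsumexp(log_joint))[0]


def joint_genotype(
    counts: pd.DataFrame,
    panel: pd.DataFrame,
    eps_init: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> JointGenotypeResult:
    """Call genotypes per site from counts pooled across all samples.

    Runs EM for the global miscall rate eps: the E-step computes genotype
    posteriors from the Hardy–Weinberg prior and binomial likelihoods; the
    M-step re-estimates eps from the expected number of miscalled reads
    (alt reads under RR, ref reads under AA, plus all non-ref/alt reads)
    over the corresponding read totals. The observed-data log-likelihood is
    non-decreasing across iterations.

    Sites with zero pooled ref+alt coverage keep the prior as posterior and
    are flagged uncallable, as are exact posterior ties.
    """
    if not _EPS_MIN <= eps_init <= _EPS_MAX:
        raise ValueError(f"eps_init must lie in [{_EPS_MIN}, {_EPS_MAX}]")
    pooled = pool_counts(counts)
    merged = pooled.merge(panel[PANEL_COLUMNS], on=["chrom", "pos", "ref", "alt"], how="left")
    if merged["maf"].isna().any():
        missing = merged["maf"].isna().sum()
        raise ValueError(f"{missing} count sites missing from the panel")

    n_ref = merged["n_ref"].to_numpy(dtype=float)
    n_alt = merged["n_alt"].to_numpy(dtype=float)
    n_other = merged["n_other"].to_numpy(dtype=float)
    n_tot = n_ref + n_alt
    n_all = n_tot + n_other
    log_prior = _hw_log_prior(merged["maf"].to_numpy(dtype=float))

    covered = n_tot > 0
    eps = float(eps_init)
    trace: list[float] = []
    converged = False
    post = np.exp(log_prior - logsumexp(log_prior, axis=1, keepdims=True))
    for _ in range(max_iter):
        log_joint = log_prior + _log_lik(n_ref, n_tot, eps)
        log_marg = logsumexp(log_joint, axis=1)
        # the n_other factor Binomial(n_all, eps) is genotype-independent
        other_ll = n_other * np.log(eps) + (n_all - n_other) * np.log1p(-eps)
        ll = float(np.sum(log_marg + other_ll))
        post = np.exp(log_joint - log_marg[:, None])
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M-step: expected miscalls over their read totals
        num = np.sum(post[:, 0] * n_alt + post[:, 2] * n_ref) + n_other.sum()
        den = np.sum((post[:, 0] + post[:, 2]) * n_tot) + n_all.sum()
        eps = float(np.clip(num / den if den > 0 else eps, _EPS_MIN, _EPS_MAX))

    # ensure posteriors match the final eps
    log_joint = log_prior + _log_lik(n_ref, n_tot, eps)
    post = np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])
    post[~covered] = np.exp(
        log_prior[~covered] - logsumexp(log_prior[~covered], axis=1, keepdims=True)
    )

    best = np.argmax(post, axis=1)
    sorted_post = np.sort(post, axis=1)
    tied = sorted_post[:, -1] == sorted_post[:, -2]
    callable_mask = covered & ~tied

    calls = merged[["chrom", "pos", "ref", "alt", "n_ref", "n_alt", "n_other", "maf"]].copy()
    for g, name in enumerate(GENOTYPES):
        calls[f"post_{name}"] = post[:, g]
    calls["genotype"] = np.where(callable_mask, np.array(GENOTYPES)[best], "NA")
    calls["callable"] = callable_mask
    calls["epsilon"] = eps
    return JointGenotypeResult(
        calls=calls, epsilon=eps, loglik_trace=tuple(trace), converged=converged
    )


def call_heterozygotes(calls: pd.DataFrame, posterior_min: float = 0.99) -> pd.DataFrame:
    """Select callable sites with het posterior >= posterior_min.

    The per-sample minimum-coverage rule for ASE testing is applied
    downstream; this selection uses pooled evidence only.
    """
    mask = calls["callable"] & (calls["post_RA"] >= posterior_min)
    return calls[mask].reset_index(drop=True)
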
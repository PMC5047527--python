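"""Conditional ASE: gene-by-microbiota interaction at heterozygous SNPs.

A genotype-by-environment interaction shows up as allelic imbalance whose
magnitude differs between a microbiota-exposed sample and its time-matched
control. For each SNP covered in both members of a (treatment, control)
pair, the contrast statistic is

    Z_delta = (beta_T - beta_C) / sqrt(se_T^2 + se_C^2).

Z_delta is only asymptotically standard normal; the deviation is corrected
empirically by dividing all scores by the spread of the Z_delta values from
a control-versus-control pair, where no interaction can exist. Two-sided
normal p-values of the normalized scores are then compared tail-for-tail
with the control-versus-control p-values to estimate an empirical FDR, and
sites are called significant below an FDR cutoff (default 0.12).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

CASE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "treatment", "control", "is_null",
    "beta_T", "se_T", "beta_C", "se_C", "z_delta", "z_norm", "p_delta",
    "efdr", "significant",
]


@dataclass(frozen=True)
class ContrastPair:
    """A (treatment, control) sample pairing; ``is_null`` marks the
    control-versus-control contrast that supplies the empirical null."""

    treatment: str
    control: str
    is_null: bool = False

    def __post_init__(self):
        if self.treatment == self.control:
            raise ValueError("treatment and control must differ")


def read_pairs(path) -> list[ContrastPair]:
    """Read a pairs design from TSV with columns treatment, control, is_null."""
    df = pd.read_csv(path, sep="\t")
    required = {"treatment", "control", "is_null"}
    if not required <= set(df.columns):
        raise ValueError(f"pairs file needs columns {sorted(required)}")
    return [
        ContrastPair(str(r.treatment), str(r.control), bool(r.is_null))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Statistic and normalization
# ---------------------------------------------------------------------------

def z_delta(beta_t: float, se_t: float, beta_c: float, se_c: float) -> float:
    """Differential z-score contrasting treatment and control imbalance."""
    if se_t <= 0 or se_c <= 0:
        raise ValueError("standard errors must be positive")
    return (beta_t - beta_c) / np.sqrt(se_t**2 + se_c**2)


def normalize_z(
    z_test: np.ndarray,
    z_null: np.ndarray,
    center: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scale all scores by the null-contrast spread.

    The null contrast has expectation zero by symmetry, so the scale
    estimate defaults to the about-zero standard deviation
    ``sqrt(mean(z_null^2))``; ``center=True`` switches to the mean-centered
    sample SD.

    Returns ``(z_norm_test, z_norm_null, s_null)``.
    """
    z_null = np.asarray(z_null, dtype=float)
    z_null = z_null[np.isfinite(z_null)]
    if z_null.size < 2:
        raise ValueError(
            "need >= 2 finite null contrasts to estimate the normalization "
            "scale; enlarge coverage of the control-versus-control pair"
        )
    if center:
        s_null = float(np.std(z_null, ddof=1))
    else:
        s_null = float(np.sqrt(np.mean(z_null**2)))
    if s_null <= 0:
        raise ValueError("null-contrast scores are all zero; cannot normalize")
    return np.asarray(z_test, dtype=float) / s_null, z_null / s_null, s_null


def p_delta(z_norm) -> np.ndarray | float:
    """Two-sided standard-normal tail probability of a normalized score."""
    return 2.0 * norm.sf(np.abs(z_norm))


# ---------------------------------------------------------------------------
# Empirical FDR
# ---------------------------------------------------------------------------

def empirical_fdr(p_test: np.ndarray, p_null: np.ndarray) -> np.ndarray:
    """Tail-ratio empirical FDR at each observed test p-value.

    At threshold t, the estimate is the null tail fraction over the test
    tail fraction,

        efdr_raw(t) = (#{p_null <= t} / |null|) / (#{p_test <= t} / |test|),

    monotonized by a running minimum from the largest threshold downward
    (so a smaller p-value never carries a larger FDR) and capped at 1.
    Tied p-values share a single value by construction.
    """
    p_test = np.asarray(p_test, dtype=float)
    p_null = np.asarray(p_null, dtype=float)
    if p_test.size == 0 or p_null.size == 0:
        raise ValueError("both p-value vectors must be nonempty")
    order = np.argsort(p_test, kind="mergesort")
    sorted_p = p_test[order]
    # tail counts at each observed threshold
    n_test_le = np.searchsorted(sorted_p, sorted_p, side="right")
    n_null_le = np.searchsorted(np.sort(p_null), sorted_p, side="right")
    raw = (n_null_le / p_null.size) / (n_test_le / p_test.size)
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    mono = np.minimum(mono, 1.0)
    out = np.empty_like(mono)
    out[order] = mono
    return out


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_case(
    ase: pd.DataFrame,
    pairs: list[ContrastPair],
    efdr_cut: float = 0.12,
    center: bool = False,
    min_null_pool: int = 100,
    per_pair_efdr: bool = False,
) -> pd.DataFrame:
    """Conditional-ASE scan over all contrast pairs.

    ``ase`` is the per-sample ASE table (already restricted to sites with
    sufficient coverage in each sample, so requiring a site to appear for
    both members of a pair enforces the both-sides coverage rule). The null
    pair(s) contribute the z pool used for normalization and the empirical
    FDR; null-pair rows carry ``efdr = NaN`` and are never significant.
    Sites eligible in several treatment pairs are tested in each pair
    independently.
    """
    if not any(p.is_null for p in pairs):
        raise ValueError("at least one control-versus-control (is_null) pair is required")
    samples = set(ase["sample"].unique())
    for p in pairs:
        if p.treatment not in samples or p.control not in samples:
            raise ValueError(
                f"pair ({p.treatment}, {p.control}) references samples absent "
                f"from the ASE table (have: {sorted(samples)})"
            )

    key = ["chrom", "pos", "ref", "alt"]
    per_sample = {s: g.set_index(key) for s, g in ase.groupby("sample", sort=False)}
    frames = []
    for pair in pairs:
        t = per_sample[pair.treatment][["beta", "se"]]
        c = per_sample[pair.control][["beta", "se"]]
        j = t.join(c, how="inner", lsuffix="_T", rsuffix="_C")
        if j.empty:
            logger.warning("pair (%s, %s): no sites covered in both members",
                           pair.treatment, pair.control)
            continue
        j["treatment"] = pair.treatment
        j["control"] = pair.control
        j["is_null"] = pair.is_null
        j["z_delta"] = (j["beta_T"] - j["beta_C"]) / np.sqrt(j["se_T"]**2 + j["se_C"]**2)
        frames.append(j.reset_index())
    if not frames:
        return pd.DataFrame(columns=CASE_COLUMNS)
    table = pd.concat(frames, ignore_index=True)

    null_mask = table["is_null"].to_numpy()
    z_null = table.loc[null_mask, "z_delta"].to_numpy()
    z_test = table.loc[~null_mask, "z_delta"].to_numpy()
    if z_null.size < min_null_pool:
        logger.warning("null pool has only %d contrasts (< %d); normalization "
                       "proceeds but the scale estimate is noisy",
                       z_null.size, min_null_pool)
    if np.all(z_null == 0):
        # degenerate null (e.g. identical imbalance everywhere): leave the
        # scores unscaled; zero contrasts still yield p = 1 and no calls
        logger.warning("all null contrasts are exactly zero; skipping "
                       "normalization (scale fixed at 1)")
        zt_norm, zn_norm, s_null = np.asarray(z_test, float), z_null, 1.0
    else:
        zt_norm, zn_norm, s_null = normalize_z(z_test, z_null, center=center)
    table.loc[~null_mask, "z_norm"] = zt_norm
    table.loc[null_mask, "z_norm"] = zn_norm
    table["p_delta"] = p_delta(table["z_norm"].to_numpy())

    table["efdr"] = np.nan
    p_null_pool = table.loc[null_mask, "p_delta"].to_numpy()
    if (~null_mask).any():
        if per_pair_efdr:
            for _, idx in table[~null_mask].groupby(
                ["treatment", "control"], sort=False
            ).groups.items():
                table.loc[idx, "efdr"] = empirical_fdr(
                    table.loc[idx, "p_delta"].to_numpy(), p_null_pool
                )
        else:
            table.loc[~null_mask, "efdr"] = empirical_fdr(
                table.loc[~null_mask, "p_delta"].to_numpy(), p_null_pool
            )
    table["significant"] = table["efdr"] < efdr_cut
    table.attrs["s_null"] = s_null
    return table[CASE_COLUMNS]
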
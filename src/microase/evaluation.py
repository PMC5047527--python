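"""Calibration and parameter-recovery studies on synthetic data.

These routines run the estimators on generator output with known truth and
summarize operating characteristics: null calibration of the ASE test,
recovery of planted imbalance, het-calling accuracy of the joint
genotyper, and sensitivity/false-discovery of the conditional-ASE scan.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from microase import ase as ase_mod
from microase import genotyping, pipeline, simulate


def simulate_null_ase_pvalues(
    n_sites: int = 2000,
    coverage_mean: float = 80.0,
    coverage_dispersion: float = 10.0,
    epsilon: float = 0.005,
    coverage_min: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Wald p-values at balanced (beta = 0) binomial het sites.

    Coverage is negative-binomial around ``coverage_mean``; sites below
    ``coverage_min`` are discarded before testing, as in the pipeline.
    """
    rng = np.random.default_rng(seed)
    params = ase_mod.AseModelParams(epsilon=epsilon, M=math.inf,
                                    coverage_min=coverage_min)
    ps: list[float] = []
    while len(ps) < n_sites:
        draw = rng.negative_binomial(
            coverage_dispersion,
            coverage_dispersion / (coverage_dispersion + coverage_mean),
            size=2 * n_sites,
        )
        draw = draw[draw >= coverage_min]
        k = rng.binomial(draw, 0.5)
        for ni, ki in zip(draw, k):
            beta, se, _ = ase_mod.fit_ase(int(ki), int(ni - ki), params)
            ps.append(ase_mod.ase_test(beta, se))
            if len(ps) == n_sites:
                break
    return np.asarray(ps)


def recover_beta(
    true_beta: float = 1.0,
    coverage: int = 100,
    n_sites: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Estimated beta at ``n_sites`` binomial het sites of fixed coverage."""
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + math.exp(-true_beta))
    k = rng.binomial(coverage, p, size=n_sites)
    params = ase_mod.AseModelParams(epsilon=0.0, M=math.inf, coverage_min=20)
    return np.array([
        ase_mod.fit_ase(int(ki), int(coverage - ki), params)[0] for ki in k
    ])


def case_operating_characteristics(
    seed: int,
    case_fraction: float,
    n_sites: int = 2000,
    coverage_mean: float = 100.0,
    case_effect_size: float = 1.5,
    efdr_cut: float = 0.12,
) -> dict:
    """Run the count path once and score cASE calls against planted truth.

    Returns the fraction of test contrasts called significant, and — when
    interactions are planted — sensitivity (significant among truly
    interacting contrasts) and the realized false-discovery proportion.
    """
    cfg = simulate.SimConfig(
        n_sites=n_sites, coverage_mean=coverage_mean,
        case_fraction=case_fraction, case_effect_size=case_effect_size,
        seed=seed,
    )
    thr = pipeline.Thresholds(efdr_cut=efdr_cut)
    run = pipeline.run_count_path(cfg, thr)
    table = run["case"]
    tests = table[~table["is_null"]]
    idx = tests["pos"].to_numpy() // 1000 - 1
    truth = run["truth"]
    true_case = np.array([
        truth.case_sites[f"{t}|{c}"][i]
        for t, c, i in zip(tests["treatment"], tests["control"], idx)
    ])
    sig = tests["significant"].to_numpy()
    out = {
        "n_tests": int(len(tests)),
        "sig_fraction": float(sig.mean()) if len(tests) else 0.0,
        "n_true": int(true_case.sum()),
    }
    if true_case.any():
        out["sensitivity"] = float(sig[true_case].mean())
    if sig.any():
        out["fdp"] = float((sig & ~true_case).sum() / sig.sum())
    elif case_fraction > 0:
        out["fdp"] = 0.0
    return out


def genotyper_accuracy(
    seed: int = 0,
    n_sites: int = 2000,
    error_rate: float = 0.01,
    posterior_min: float = 0.99,
    pooled_coverage_min: int = 20,
) -> dict:
    """Het recall/precision of the joint caller against simulated truth.

    Evaluated on sites with pooled ref+alt coverage at or above
    ``pooled_coverage_min``; also reports whether the EM log-likelihood
    trace was non-decreasing.
    """
    cfg = simulate.SimConfig(n_sites=n_sites, error_rate=error_rate, seed=seed)
    panel, counts, truth = simulate.simulate_allele_counts(cfg)
    res = genotyping.joint_genotype(counts, panel)
    calls = res.calls
    pooled_cov = (calls["n_ref"] + calls["n_alt"]).to_numpy()
    eligible = pooled_cov >= pooled_coverage_min
    idx = calls["pos"].to_numpy() // 1000 - 1
    true_het = (truth.genotype[idx] == "RA") & eligible
    called_het = (
        calls["callable"].to_numpy()
        & (calls["post_RA"].to_numpy() >= posterior_min)
        & eligible
    )
    tp = int((called_het & true_het).sum())
    ll = np.array(res.loglik_trace)
    return {
        "recall": tp / max(1, int(true_het.sum())),
        "precision": tp / max(1, int(called_het.sum())),
        "n_true_het": int(true_het.sum()),
        "loglik_monotone": bool(np.all(np.diff(ll) >= -1e-9)),
        "epsilon_hat": res.epsilon,
    }
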
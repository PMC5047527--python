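"""Synthetic inputs for the full pipeline, with known ground truth.

The generator reproduces the statistical structure the analysis assumes:

- a SNP panel with population minor-allele frequencies and Hardy–Weinberg
  genotypes in a single (cell-line) individual;
- per-sample allele read counts at each SNP: total coverage from a negative
  binomial, non-ref/non-alt base calls from a symmetric miscall rate, and
  a (beta-)binomial split of the remaining reads whose mean folds the
  planted allelic imbalance together with the miscall rate;
- planted ASE effects (shared across conditions) and condition-specific
  cASE effects (added in treatment conditions only) at a configurable
  fraction of heterozygous sites;
- a transcript-level differential-expression table with planted DE genes,
  per-condition membership, directions, and direction-inconsistent or
  mixed-direction genes to exercise the strict set rules;
- a GWAS-catalog-style trait table with one trait planted to overlap the
  DE truth at a chosen odds ratio, and per-gene association p-values that
  strengthen inside the overlap so threshold scans have a signal.

The default design mirrors a coculture study with three treatments paired
to two time-matched controls: T1, T2 vs C4; T3 vs C6; and the (C6, C4)
control pair supplying the empirical null. One sample per condition
(experimental replicates are pooled at the count level upstream).

Every output is deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from microase.case import ContrastPair
from microase.genotyping import COUNT_COLUMNS

_BASES = np.array(list("ACGT"))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the allele-count simulator.

    coverage_mean / coverage_dispersion parameterize a negative binomial
    (variance = mu + mu^2 / dispersion). ``maf_range`` is the uniform law
    of panel minor-allele frequencies. ``overdispersion_m`` is the
    beta-binomial concentration (inf = binomial). ``ase_fraction`` and
    ``case_fraction`` are the fractions of het sites carrying a planted
    shared-imbalance effect and a treatment-specific effect, respectively.
    """

    n_sites: int = 2000
    conditions: tuple[str, ...] = ("T1", "T2", "T3", "C4", "C6")
    pairs: tuple[tuple[str, str], ...] = (("T1", "C4"), ("T2", "C4"), ("T3", "C6"))
    null_pair: tuple[str, str] = ("C6", "C4")
    n_samples_per_condition: int = 1
    coverage_mean: float = 80.0
    coverage_dispersion: float = 10.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    error_rate: float = 0.005
    overdispersion_m: float = 300.0
    ase_fraction: float = 0.05
    ase_effect_sd: float = 0.5
    ase_effect_min: float = 0.25
    case_fraction: float = 0.05
    case_effect_size: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in ("error_rate", "ase_fraction", "case_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage mean must be positive")
        if not self.overdispersion_m > 0:
            raise ValueError("overdispersion M must be positive (inf = binomial)")
        if self.maf_range[1] <= 0:
            raise ValueError("maf_range degenerate at 0: no het-capable sites")
        if not (0 <= self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        treatments = {t for t, _ in self.pairs}
        controls = {c for _, c in self.pairs}
        if not self.pairs:
            raise ValueError("need at least one (treatment, control) pair")
        missing = (treatments | controls | set(self.null_pair)) - set(self.conditions)
        if missing:
            raise ValueError(f"pair conditions not in conditions: {sorted(missing)}")
        if self.null_pair[0] == self.null_pair[1]:
            raise ValueError("null pair must contrast two distinct controls")

    def contrast_pairs(self) -> list[ContrastPair]:
        out = [ContrastPair(t, c, is_null=False) for t, c in self.pairs]
        out.append(ContrastPair(*self.null_pair, is_null=True))
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``beta`` has one row per site and one column per condition; hom sites
    carry no imbalance (all-zero rows, genotype != RA). ``case_sites`` maps
    each (treatment, control) pair name to the boolean planted-cASE
    indicator per site (true iff the true beta differs within the pair).
    """

    genotype: np.ndarray
    beta: pd.DataFrame
    is_ase: np.ndarray
    case_sites: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "genotype": self.genotype.tolist(),
            "beta": {c: self.beta[c].tolist() for c in self.beta.columns},
            "is_ase": self.is_ase.astype(bool).tolist(),
            "case_sites": {k: v.astype(bool).tolist() for k, v in self.case_sites.items()},
        }
        return json.dumps(payload)


def _draw_coverage(rng, mean, dispersion, size):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_panel(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic SNP panel: evenly spaced sites with uniform folded MAF."""
    n = config.n_sites
    pos = np.arange(1, n + 1) * 1000
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    maf = rng.uniform(*config.maf_range, size=n)
    return pd.DataFrame({
        "chrom": "chr1", "pos": pos,
        "ref": _BASES[ref_idx], "alt": _BASES[alt_idx],
        "maf": maf,
    })


def simulate_allele_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (panel, count table, truth) for one dataset.

    Per site: genotype from Hardy–Weinberg at its MAF. Per sample: total
    coverage ~ NB(mean, dispersion); "other" reads ~ Binomial(coverage,
    error_rate); the remaining reads split ref/alt with mean
    p = logistic(beta) (1 - eps) + (1 - logistic(beta)) eps at het sites
    (1 - eps at RR, eps at AA), beta-binomially overdispersed at finite M.
    """
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    n = config.n_sites
    eps = config.error_rate
    m = config.overdispersion_m

    maf = panel["maf"].to_numpy()
    u = rng.random(n)
    hw = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2], axis=1)
    cdf = np.cumsum(hw, axis=1)
    gt_idx = (u[:, None] > cdf).sum(axis=1)  # 0=RR 1=RA 2=AA
    genotype = np.array(["RR", "RA", "AA"])[gt_idx]
    het = gt_idx == 1

    # planted effects at het sites
    is_ase = np.zeros(n, dtype=bool)
    is_case = np.zeros(n, dtype=bool)
    het_idx = np.flatnonzero(het)
    is_ase[het_idx] = rng.random(het_idx.size) < config.ase_fraction
    is_case[het_idx] = rng.random(het_idx.size) < config.case_fraction

    base_beta = np.zeros(n)
    if is_ase.any():
        k = int(is_ase.sum())
        mag = np.abs(rng.normal(0.0, config.ase_effect_sd, size=3 * k))
        mag = mag[mag >= config.ase_effect_min]
        while mag.size < k:  # top up the truncated draw
            extra = np.abs(rng.normal(0.0, config.ase_effect_sd, size=3 * k))
            mag = np.concatenate([mag, extra[extra >= config.ase_effect_min]])
        base_beta[is_ase] = mag[:k] * rng.choice([-1.0, 1.0], size=k)

    delta = np.zeros(n)
    if is_case.any():
        k = int(is_case.sum())
        delta[is_case] = config.case_effect_size * rng.choice([-1.0, 1.0], size=k)

    treatments = {t for t, _ in config.pairs}
    beta = pd.DataFrame(
        {c: base_beta + (delta if c in treatments else 0.0) for c in config.conditions}
    )
    beta[genotype != "RA"] = 0.0

    records = []
    sample_names = []
    for cond in config.conditions:
        reps = config.n_samples_per_condition
        names = [cond] if reps == 1 else [f"{cond}_r{i+1}" for i in range(reps)]
        for name in names:
            sample_names.append((cond, name))

    chrom = panel["chrom"].to_numpy()
    pos = panel["pos"].to_numpy()
    ref = panel["ref"].to_numpy()
    alt = panel["alt"].to_numpy()
    for cond, name in sample_names:
        cov = _draw_coverage(rng, config.coverage_mean, config.coverage_dispersion, n)
        n_other = rng.binomial(cov, eps)
        n_ra = cov - n_other
        p_ref = np.where(
            gt_idx == 0, 1.0 - eps,
            np.where(gt_idx == 2, eps,
                     _logistic(beta[cond].to_numpy()) * (1 - eps)
                     + (1 - _logistic(beta[cond].to_numpy())) * eps),
        )
        if math.isfinite(m):
            a = np.clip(p_ref * m, 1e-9, None)
            b = np.clip((1 - p_ref) * m, 1e-9, None)
            p_draw = rng.beta(a, b)
            n_ref = rng.binomial(n_ra, p_draw)
        else:
            n_ref = rng.binomial(n_ra, p_ref)
        n_alt = n_ra - n_ref
        records.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "sample": name, "n_ref": n_ref, "n_alt": n_alt, "n_other": n_other,
        }))
    counts = pd.concat(records, ignore_index=True)[COUNT_COLUMNS]

    case_sites = {}
    for t, c in config.pairs:
        case_sites[f"{t}|{c}"] = (beta[t].to_numpy() != beta[c].to_numpy())
    truth = SimTruth(genotype=genotype, beta=beta, is_ase=is_ase, case_sites=case_sites)
    return panel, counts, truth


# ---------------------------------------------------------------------------
# Differential-expression table
# ---------------------------------------------------------------------------

@dataclass
class DeTruth:
    """Planted DE structure: per-condition gene sets, directions, and the
    direction-consistent set."""

    sets: dict[str, set]
    directions: dict[str, dict[str, str]]
    all_consistent: set
    universe: set

    def to_json(self) -> str:
        return json.dumps({
            "sets": {c: sorted(s) for c, s in self.sets.items()},
            "directions": self.directions,
            "all_consistent": sorted(self.all_consistent),
            "universe_size": len(self.universe),
        })


def simulate_de_table(
    n_genes: int = 3000,
    transcripts_per_gene: tuple[int, int] = (1, 4),
    de_fraction: float = 0.1,
    conditions: tuple[str, ...] = ("T1", "T2", "T3"),
    flip_fraction: float = 0.1,
    mixed_fraction: float = 0.05,
    n_boundary: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, DeTruth]:
    """Transcript-level DE table with exactly recoverable planted truth.

    Planted DE transcripts have |log2fc| in (0.3, 2.5) and p <= 1e-4 so
    they always clear the strict calling thresholds after BH; null
    transcripts have |log2fc| < 0.2 and p >= 0.2 so they never do. Each DE
    gene is DE in a random nonempty subset of conditions; ``flip_fraction``
    of the genes DE everywhere get one condition's direction inverted, and
    ``mixed_fraction`` get a second, opposite-direction DE transcript in
    one condition — both are thereby excluded from the direction-consistent
    truth set. ``n_boundary`` extra transcripts sit exactly at
    |log2fc| = 0.25 (with small p) and are planted non-DE.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_tx = rng.integers(transcripts_per_gene[0], transcripts_per_gene[1] + 1, size=n_genes)
    de_genes = set(np.array(genes)[rng.random(n_genes) < de_fraction])

    rows = []
    truth_sets: dict[str, set] = {c: set() for c in conditions}
    truth_dirs: dict[str, dict[str, str]] = {c: {} for c in conditions}
    for gi, gene in enumerate(genes):
        k = int(n_tx[gi])
        if gene in de_genes:
            # random nonempty condition subset, one shared base direction
            member = rng.random(len(conditions)) < 0.8
            if not member.any():
                member[rng.integers(len(conditions))] = True
            sign = float(rng.choice([-1.0, 1.0]))
            signs = {c: (sign if m else 0.0) for c, m in zip(conditions, member)}
            flipped = False
            if all(member) and rng.random() < flip_fraction:
                flip_c = conditions[rng.integers(len(conditions))]
                signs[flip_c] = -sign
                flipped = True
            mixed_c = None  # mutually exclusive with flipping, else the
            # opposite-direction transcript could match the flipped sign
            if all(member) and not flipped and rng.random() < mixed_fraction:
                mixed_c = conditions[rng.integers(len(conditions))]
            n_de_tx = int(rng.integers(1, k + 1))
            de_tx = set(rng.choice(k, size=n_de_tx, replace=False))
            for t in range(k):
                tx = f"{gene}.t{t+1}"
                for c in conditions:
                    if t in de_tx and signs[c] != 0.0:
                        lfc = signs[c] * rng.uniform(0.3, 2.5)
                        p = 10.0 ** rng.uniform(-10, -4)
                    else:
                        lfc = rng.uniform(-0.2, 0.2)
                        p = rng.uniform(0.2, 1.0)
                    rows.append((tx, gene, c, lfc, p))
            if mixed_c is not None:
                tx = f"{gene}.tmix"
                for c in conditions:
                    if c == mixed_c:
                        rows.append((tx, gene, c, -sign * rng.uniform(0.3, 2.5),
                                     10.0 ** rng.uniform(-10, -4)))
                    else:
                        rows.append((tx, gene, c, rng.uniform(-0.2, 0.2),
                                     rng.uniform(0.2, 1.0)))
            for c in conditions:
                if signs[c] != 0.0:
                    truth_sets[c].add(gene)
                    if c == mixed_c:
                        truth_dirs[c][gene] = "mixed"
                    else:
                        truth_dirs[c][gene] = "+" if signs[c] > 0 else "-"
        else:
            for t in range(k):
                tx = f"{gene}.t{t+1}"
                for c in conditions:
                    rows.append((tx, gene, c, rng.uniform(-0.2, 0.2), rng.uniform(0.2, 1.0)))

    for b in range(n_boundary):
        gene = f"GB{b:03d}"
        sign = float(rng.choice([-1.0, 1.0]))
        for c in conditions:
            rows.append((f"{gene}.t1", gene, c, sign * 0.25, 10.0 ** rng.uniform(-10, -4)))
        genes.append(gene)

    table = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "condition",
                                        "log2fc", "pvalue"])
    universe = set(genes)
    all_consistent = set()
    for gene in set.intersection(*truth_sets.values()) if truth_sets else set():
        dirs = {truth_dirs[c][gene] for c in conditions}
        if len(dirs) == 1 and "mixed" not in dirs:
            all_consistent.add(gene)
    truth = DeTruth(sets=truth_sets, directions=truth_dirs,
                    all_consistent=all_consistent, universe=universe)
    return table, truth


# ---------------------------------------------------------------------------
# GWAS-catalog-style trait table
# ---------------------------------------------------------------------------

def simulate_gwas_catalog(
    genes,
    de_truth: set,
    traits: tuple[str, ...] = ("TraitA", "TraitB", "TraitC", "TraitD",
                               "TraitE", "TraitF", "TraitG", "TraitH"),
    enriched_trait: str = "TraitA",
    enrichment_odds: float = 3.0,
    base_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Trait catalog with one trait planted to overlap the DE truth.

    Each gene joins each trait independently at ``base_rate``; for the
    enriched trait, membership odds for genes in ``de_truth`` are
    multiplied by ``enrichment_odds``. Per-entry association p-values are
    log-uniform on the GWAS-significance scale, and entries in the
    enriched-trait/DE overlap are drawn from a stronger range so fold
    enrichment rises with cutoff stringency.
    """
    if enrichment_odds < 1:
        raise ValueError("enrichment_odds must be >= 1")
    if enriched_trait not in traits:
        raise ValueError("enriched_trait must be one of traits")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    de_mask = np.array([g in de_truth for g in genes])
    odds0 = base_rate / (1 - base_rate)
    p_enriched = (enrichment_odds * odds0) / (1 + enrichment_odds * odds0)
    rows = []
    for trait in traits:
        if trait == enriched_trait:
            prob = np.where(de_mask, p_enriched, base_rate)
        else:
            prob = np.full(len(genes), base_rate)
        member = rng.random(len(genes)) < prob
        for i in np.flatnonzero(member):
            if trait == enriched_trait and de_mask[i]:
                logp = rng.uniform(6.0, 25.0)
            else:
                logp = rng.uniform(5.0, 12.0)
            rows.append((genes[i], trait, 10.0 ** (-logp)))
    return pd.DataFrame(rows, columns=["gene", "trait", "pvalue"])
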
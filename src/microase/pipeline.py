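"""End-to-end orchestration: simulate → genotype → ASE → cASE → DE sets →
enrichment, from one YAML-able configuration.

Stages hand data off through plain tab-separated files so every stage can
be re-run and inspected from its on-disk inputs alone; a JSON manifest
records each output with a content hash, so reruns with the same seed can
be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from microase import __version__, ase as ase_mod, case as case_mod
from microase import de_sets, enrichment, genotyping, simulate

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Every calling threshold of the pipeline, with its default."""

    coverage_min: int = 20
    ase_q_cut: float = 0.10
    efdr_cut: float = 0.12
    lfc_min: float = 0.25
    de_alpha: float = 0.1
    het_posterior_min: float = 0.99
    maf_min: float = 0.05


@dataclass
class RunConfig:
    """Full pipeline configuration (simulation block + thresholds + seed)."""

    seed: int = 0
    outdir: str = "run_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: dict = field(default_factory=dict)
    de_simulation: dict = field(default_factory=dict)
    catalog_simulation: dict = field(default_factory=dict)
    categories_file: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of human-readable issues; empty means runnable."""
    issues = []
    t = config.thresholds
    if t.coverage_min < 1:
        issues.append("thresholds.coverage_min: must be >= 1")
    for name, lo, hi in [
        ("ase_q_cut", 0, 1), ("efdr_cut", 0, 1), ("de_alpha", 0, 1),
        ("het_posterior_min", 0, 1), ("maf_min", 0, 0.5),
    ]:
        v = getattr(t, name)
        if not lo < v <= hi:
            issues.append(f"thresholds.{name}: {v} outside ({lo}, {hi}]")
    if t.lfc_min < 0:
        issues.append("thresholds.lfc_min: must be >= 0")
    try:
        sim = simulate.SimConfig(seed=config.seed, **config.simulation)
    except (TypeError, ValueError) as exc:
        issues.append(f"simulation: {exc}")
        return issues
    known = {c for c in sim.conditions}
    for t_, c_ in list(sim.pairs) + [sim.null_pair]:
        if t_ not in known or c_ not in known:
            issues.append(f"pairs: unknown condition in ({t_}, {c_})")
    if config.categories_file and not Path(config.categories_file).exists():
        issues.append(f"categories_file: {config.categories_file} does not exist")
    return issues


def run_count_path(
    sim_cfg: simulate.SimConfig,
    thresholds: Thresholds | None = None,
) -> dict:
    """Run the allele-count arm in memory: simulate → genotype → ASE → cASE.

    Returns a dict with the simulation truth and every intermediate table;
    used for calibration studies where no files need to be written.
    """
    thr = thresholds or Thresholds()
    panel, counts, truth = simulate.simulate_allele_counts(sim_cfg)
    panel_f = genotyping.filter_panel(panel, maf_min=thr.maf_min)
    counts_f = counts.merge(
        panel_f[["chrom", "pos", "ref", "alt"]], on=["chrom", "pos", "ref", "alt"]
    )
    geno = genotyping.joint_genotype(counts_f, panel_f)
    het = genotyping.call_heterozygotes(geno.calls, thr.het_posterior_min)
    het_counts = counts_f.merge(
        het[["chrom", "pos", "ref", "alt"]], on=["chrom", "pos", "ref", "alt"]
    )
    m_hat, _ = ase_mod.estimate_overdispersion(
        het_counts[["n_ref", "n_alt"]].to_numpy(), coverage_min=thr.coverage_min
    )
    params = ase_mod.AseModelParams(
        epsilon=geno.epsilon, M=m_hat, coverage_min=thr.coverage_min
    )
    ase_table = ase_mod.run_ase(counts_f, het, params)
    case_table = case_mod.run_case(
        ase_table, sim_cfg.contrast_pairs(), efdr_cut=thr.efdr_cut
    )
    return {
        "panel": panel_f, "counts": counts_f, "truth": truth, "geno": geno,
        "het": het, "m_hat": m_hat, "ase": ase_table, "case": case_table,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Any stage failure raises with the stage name attached so the pointer to
    the failing step is explicit.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    outputs: dict[str, Path] = {}
    counts_log: dict[str, int] = {}
    stage = "simulate"
    try:
        sim_cfg = simulate.SimConfig(seed=config.seed, **config.simulation)
        panel, counts, truth = simulate.simulate_allele_counts(sim_cfg)
        de_table, de_truth = simulate.simulate_de_table(
            seed=config.seed + 1,
            conditions=tuple(t for t, _ in sim_cfg.pairs),
            **config.de_simulation,
        )
        catalog = simulate.simulate_gwas_catalog(
            genes=sorted(de_truth.universe),
            de_truth=de_truth.all_consistent,
            seed=config.seed + 2,
            **config.catalog_simulation,
        )
        _write = lambda df, name: (df.to_csv(outdir / name, sep="\t", index=False),
                                   outputs.__setitem__(name, outdir / name))
        _write(panel, "panel.tsv")
        _write(counts, "counts.tsv")
        _write(de_table, "de_table.tsv")
        _write(catalog, "catalog.tsv")
        (outdir / "truth.json").write_text(truth.to_json())
        outputs["truth.json"] = outdir / "truth.json"
        (outdir / "de_truth.json").write_text(de_truth.to_json())
        outputs["de_truth.json"] = outdir / "de_truth.json"
        pairs = sim_cfg.contrast_pairs()
        pairs_df = pd.DataFrame(
            [(p.treatment, p.control, p.is_null) for p in pairs],
            columns=["treatment", "control", "is_null"],
        )
        _write(pairs_df, "pairs.tsv")
        counts_log["panel_sites"] = len(panel)

        stage = "genotype"
        panel_f = genotyping.filter_panel(panel, maf_min=thr.maf_min)
        counts_f = counts.merge(
            panel_f[["chrom", "pos", "ref", "alt"]], on=["chrom", "pos", "ref", "alt"]
        )
        geno = genotyping.joint_genotype(counts_f, panel_f)
        _write(geno.calls, "genotypes.tsv")
        counts_log["filtered_panel_sites"] = len(panel_f)

        stage = "ase"
        het = genotyping.call_heterozygotes(geno.calls, thr.het_posterior_min)
        counts_log["het_sites"] = len(het)
        het_counts = counts_f.merge(
            het[["chrom", "pos", "ref", "alt"]], on=["chrom", "pos", "ref", "alt"]
        )
        per_site = het_counts[["n_ref", "n_alt"]].to_numpy()
        m_hat, _ = ase_mod.estimate_overdispersion(per_site, coverage_min=thr.coverage_min)
        params = ase_mod.AseModelParams(
            epsilon=geno.epsilon, M=m_hat, coverage_min=thr.coverage_min
        )
        ase_table = ase_mod.run_ase(counts_f, het, params)
        _write(ase_table, "ase.tsv")
        counts_log["ase_tests"] = len(ase_table)
        counts_log["ase_events"] = int((ase_table["q"] < thr.ase_q_cut).sum())

        stage = "case"
        case_table = case_mod.run_case(ase_table, pairs, efdr_cut=thr.efdr_cut)
        _write(case_table, "case.tsv")
        counts_log["case_tests"] = int((~case_table["is_null"]).sum())
        counts_log["case_significant"] = int(case_table["significant"].sum())

        stage = "desets"
        bundle = de_sets.build_gene_sets(de_table, lfc_min=thr.lfc_min, alpha=thr.de_alpha)
        sets_payload = {
            "per_condition": {c: sorted(s) for c, s in bundle.sets.items()},
            "all_consistent": sorted(bundle.all_set),
            "venn": de_sets.venn_counts(bundle),
            "universe_size": len(bundle.universe),
        }
        (outdir / "gene_sets.json").write_text(json.dumps(sets_payload, indent=1))
        outputs["gene_sets.json"] = outdir / "gene_sets.json"
        counts_log["de_genes_union"] = len(set.union(*bundle.sets.values()))
        counts_log["de_genes_all_consistent"] = len(bundle.all_set)

        stage = "enrich"
        enriched_trait = config.catalog_simulation.get("enriched_trait", "TraitA")
        res = enrichment.gwas_trait_enrichment(
            bundle.all_set, bundle.universe, catalog, enriched_trait
        )
        scan = enrichment.threshold_scan(
            bundle.all_set, bundle.universe, catalog, enriched_trait
        )
        _write(scan, "threshold_scan.tsv")
        enrich_payload = {
            "trait": enriched_trait,
            "table": dataclasses.asdict(res.table),
            "odds_ratio": res.odds_ratio,
            "p": res.p,
            "fold": res.fold,
            "max_fold_cutoff": scan.attrs.get("max_fold_cutoff"),
            "any_significant_cutoff": scan.attrs.get("any_significant"),
        }
        if config.categories_file:
            cats = enrichment.read_categories(config.categories_file)
            rep = enrichment.set_representation(bundle.all_set, cats, bundle.universe)
            _write(rep, "category_representation.tsv")
        (outdir / "enrichment.json").write_text(json.dumps(enrich_payload, indent=1))
        outputs["enrichment.json"] = outdir / "enrichment.json"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(thr),
        "epsilon_hat": geno.epsilon,
        "overdispersion_m_hat": None if m_hat != m_hat or m_hat == float("inf") else m_hat,
        "counts": counts_log,
        "files": {
            name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(outputs.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
    return manifest
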
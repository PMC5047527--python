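"""Gene-set construction from transcript-level differential expression.

Consumes a DESeq2-style results table (one row per transcript per
treatment-versus-control contrast) and applies the calling rules:

- a transcript is DE when |log2 fold change| > 0.25 and its BH-adjusted
  p-value is < 0.1 (both inequalities strict; boundary values excluded);
- a gene is DE in a condition when at least one of its transcripts is;
- a gene's per-condition direction is "+" ("-") only when every DE
  transcript of that gene in that condition goes up (down), else "mixed";
- the ALL set contains genes DE in every condition with the same non-mixed
  direction throughout.

BH adjustment is applied per condition (each contrast separately) when the
table carries raw p-values without an adjusted column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from microase.stats import bh_adjust

DE_COLUMNS = ["transcript_id", "gene_id", "condition", "log2fc", "pvalue"]


@dataclass
class GeneSetBundle:
    """Per-condition DE gene sets with directions, plus derived sets.

    ``directions[cond][gene]`` is "+", "-" or "mixed". ``universe`` is every
    gene in the input table (the expressed-gene background).
    """

    sets: dict[str, set[str]]
    directions: dict[str, dict[str, str]]
    universe: set[str]
    all_set: set[str] = field(default_factory=set)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    return df


def call_de_transcripts(
    records: pd.DataFrame,
    lfc_min: float = 0.25,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Flag DE transcripts: |log2fc| > lfc_min AND padj < alpha (strict).

    Computes a per-condition BH-adjusted column when ``padj`` is absent.
    """
    df = records.copy()
    if "padj" not in df.columns:
        if "pvalue" not in df.columns:
            raise ValueError("table needs a padj or pvalue column")
        df["padj"] = float("nan")
        for _, idx in df.groupby("condition", sort=False).groups.items():
            df.loc[idx, "padj"] = bh_adjust(df.loc[idx, "pvalue"].to_numpy())
    df["de"] = (df["log2fc"].abs() > lfc_min) & (df["padj"] < alpha)
    return df


def genes_from_transcripts(flagged: pd.DataFrame) -> GeneSetBundle:
    """Aggregate flagged transcripts to per-condition gene sets.

    A gene enters a condition's set when it has at least one DE transcript
    there; its direction is the common sign of its DE transcripts or
    "mixed" when they disagree.
    """
    universe = set(flagged["gene_id"].unique())
    sets: dict[str, set[str]] = {}
    directions: dict[str, dict[str, str]] = {}
    for cond, grp in flagged.groupby("condition", sort=False):
        de = grp[grp["de"]]
        sets[cond] = set(de["gene_id"].unique())
        dirs = {}
        for gene, g in de.groupby("gene_id", sort=False):
            signs = set("+" if x > 0 else "-" for x in g["log2fc"])
            dirs[gene] = signs.pop() if len(signs) == 1 else "mixed"
        directions[cond] = dirs
    bundle = GeneSetBundle(sets=sets, directions=directions, universe=universe)
    bundle.all_set = consistent_direction_genes(bundle)
    return bundle


def consistent_direction_genes(bundle: GeneSetBundle) -> set[str]:
    """Genes DE with the same non-mixed direction in every condition."""
    conds = list(bundle.sets)
    if len(conds) < 2:
        raise ValueError("need at least two conditions for the consistent set")
    common = set.intersection(*(bundle.sets[c] for c in conds))
    out = set()
    for gene in common:
        dirs = {bundle.directions[c][gene] for c in conds}
        if len(dirs) == 1 and "mixed" not in dirs:
            out.add(gene)
    return out


def venn_counts(bundle: GeneSetBundle) -> dict[str, int]:
    """Exact region counts of the condition Venn diagram.

    For 2-3 conditions, every region (keys like "A&B-C") is reported; for
    more, only pairwise overlaps and the full intersection. Region counts
    sum to the union size.
    """
    conds = list(bundle.sets)
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    if len(conds) <= 3:
        out = {}
        for r in range(1, len(conds) + 1):
            for inc in combinations(conds, r):
                exc = [c for c in conds if c not in inc]
                region = set.intersection(*(bundle.sets[c] for c in inc))
                for c in exc:
                    region -= bundle.sets[c]
                key = "&".join(inc) + ("-" + "-".join(exc) if exc else "")
                out[key] = len(region)
        return out
    out = {
        f"{a}&{b}": len(bundle.sets[a] & bundle.sets[b])
        for a, b in combinations(conds, 2)
    }
    out["&".join(conds)] = len(set.intersection(*bundle.sets.values()))
    return out


def build_gene_sets(
    records: pd.DataFrame,
    lfc_min: float = 0.25,
    alpha: float = 0.1,
) -> GeneSetBundle:
    """End-to-end: thresholding, gene aggregation, direction-consistent set."""
    return genes_from_transcripts(call_de_transcripts(records, lfc_min, alpha))
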
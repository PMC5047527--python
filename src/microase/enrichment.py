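"""Gene-set enrichment statistics.

Three designs, all built on a two-by-two contingency table within an
explicit gene universe:

- ``fisher_overlap``: overlap of two gene sets (Fisher exact test, odds
  ratio, observed/expected fold enrichment);
- ``gwas_trait_enrichment``: DE genes versus a GWAS-catalog trait, with the
  universe restricted to expressed genes present in the catalog and columns
  TRAIT versus OTHER-GWAS;
- ``threshold_scan``: fold enrichment of a DE set among trait-associated
  genes at progressively stringent association p-value cutoffs, reporting
  the point of maximum enrichment;
- ``set_representation``: category (GO-style) over/under-representation
  against an expressed-gene background, with the expected-count band filter
  used to keep interpretable categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from microase.stats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a,b,c,d: rows = set membership, columns = trait membership;
    a = in-set AND in-trait."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher-test summary of one two-by-two design.

    ``odds_ratio`` is the cross-product ratio a*d / (b*c) (inf when b*c = 0
    and a*d > 0; nan when degenerate); ``fold`` is observed/expected
    overlap, a / (row1 * col1 / N).
    """

    table: ContingencyTable
    odds_ratio: float
    p: float
    fold: float


def _fisher_result(table: ContingencyTable) -> EnrichmentResult:
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty contingency table")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    expected = (a + b) * (a + c) / n
    fold = a / expected if expected > 0 else (0.0 if a == 0 else math.nan)
    p = float(fisher_exact(table.as_array(), alternative="two-sided")[1])
    return EnrichmentResult(table=table, odds_ratio=odds, p=p, fold=fold)


def fisher_overlap(set_a: set, set_b: set, universe: set) -> EnrichmentResult:
    """Two-sided Fisher exact test of the overlap of two gene sets.

    Elements outside the universe are dropped (logged). The two-sided
    p-value follows the probability-mass convention: the total probability
    of fixed-margin tables no more likely than the observed one.
    """
    if not universe:
        raise ValueError("empty universe")
    dropped = len(set_a - universe) + len(set_b - universe)
    if dropped:
        logger.info("fisher_overlap: dropped %d elements outside universe", dropped)
    set_a = set_a & universe
    set_b = set_b & universe
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    return _fisher_result(ContingencyTable(a, b, c, d))


# ---------------------------------------------------------------------------
# GWAS-catalog designs
# ---------------------------------------------------------------------------

def read_trait_catalog(path) -> pd.DataFrame:
    """Read a trait catalog (tab-separated: gene, trait, optional pvalue)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "trait"} <= set(df.columns):
        raise ValueError("catalog needs columns gene, trait")
    return df


def gwas_trait_enrichment(
    all_set: set,
    universe: set,
    catalog: pd.DataFrame,
    trait: str,
) -> EnrichmentResult:
    """Trait-versus-other-GWAS enrichment of the direction-consistent DE set.

    The universe is restricted to expressed genes appearing in the catalog
    under any trait. Rows split that restricted universe into the DE set
    ("ALL") versus the rest; columns into genes associated with the focal
    trait ("TRAIT") versus genes associated only with other traits ("OTHER
    GWAS"). A gene carrying both the focal and other traits counts as
    TRAIT (focal membership wins, since catalog membership is per-trait).
    """
    traits = set(catalog["trait"].unique())
    if trait not in traits:
        raise ValueError(f"trait {trait!r} not in catalog; available: {sorted(traits)}")
    catalog_genes = set(catalog["gene"].unique())
    restricted = universe & catalog_genes
    trait_genes = set(catalog.loc[catalog["trait"] == trait, "gene"]) & restricted
    de = all_set & restricted
    a = len(de & trait_genes)
    b = len(de - trait_genes)
    c = len(trait_genes - de)
    d = len(restricted) - a - b - c
    return _fisher_result(ContingencyTable(a, b, c, d))


def gene_min_association_p(associations: pd.DataFrame, trait: str) -> pd.Series:
    """Per-gene minimum association p-value for one trait."""
    sub = associations[associations["trait"] == trait]
    return sub.groupby("gene")["pvalue"].min()


def default_grid() -> np.ndarray:
    """GWAS-scale -log10(p) cutoffs: 5 to 12 in steps of 0.25."""
    return np.arange(5.0, 12.0 + 1e-9, 0.25)


def threshold_scan(
    de_set: set,
    universe: set,
    associations: pd.DataFrame,
    trait: str,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fold-enrichment scan over association p-value cutoffs.

    At each cutoff c, the trait set is the universe's genes whose minimum
    association p-value for the trait is <= 10^-c; fold = observed overlap
    with ``de_set`` over the overlap expected under independence; a Fisher
    p-value accompanies each cutoff. Cutoffs where the trait set is empty
    are excluded. Result attrs carry the argmax-fold cutoff and whether any
    cutoff reached p < 0.05.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    gene_p = gene_min_association_p(associations, trait)
    gene_p = gene_p[gene_p.index.isin(universe)]
    de = de_set & universe
    n_u = len(universe)
    rows = []
    for c in grid:
        trait_set = set(gene_p.index[gene_p.to_numpy() <= 10.0 ** (-c)])
        if not trait_set:
            continue
        obs = len(trait_set & de)
        expected = len(trait_set) * len(de) / n_u
        fold = obs / expected if expected > 0 else 0.0
        a = obs
        b = len(de) - obs
        cc = len(trait_set) - obs
        d = n_u - a - b - cc
        p = float(fisher_exact([[a, b], [cc, d]])[1])
        rows.append((c, len(trait_set), obs, expected, fold, p))
    scan = pd.DataFrame(
        rows, columns=["cutoff", "set_size", "observed", "expected", "fold", "p"]
    )
    if len(scan):
        scan.attrs["max_fold_cutoff"] = float(scan.loc[scan["fold"].idxmax(), "cutoff"])
        scan.attrs["any_significant"] = bool((scan["p"] < 0.05).any())
    return scan


# ---------------------------------------------------------------------------
# Category (GO-style) representation
# ---------------------------------------------------------------------------

def read_categories(path) -> dict[str, set]:
    """Read category membership from long-format TSV (category, gene)."""
    df = pd.read_csv(path, sep="\t")
    if not {"category", "gene"} <= set(df.columns):
        raise ValueError("categories file needs columns category, gene")
    return {c: set(g["gene"]) for c, g in df.groupby("category", sort=False)}


def set_representation(
    query: set,
    categories: dict[str, set],
    background: set,
    expected_band: tuple[float, float] = (10.0, 500.0),
) -> pd.DataFrame:
    """Over/under-representation of a query set in each category.

    Per category (intersected with the background; empty ones dropped with
    a log entry): hypergeometric one-sided over- and under-representation
    p-values, combined two-sided as min(1, 2 * min(p_over, p_under)); BH
    adjustment across categories; enrichment = observed / expected count;
    ``in_band`` flags expected counts inside the closed ``expected_band``
    (the interval that keeps categories large enough to test and small
    enough to interpret).
    """
    if not query <= background:
        query = query & background
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for name, genes in categories.items():
        genes = genes & background
        if not genes:
            logger.info("set_representation: category %s outside background, dropped", name)
            continue
        k = len(genes & query)
        m = len(genes)
        expected = m * n_q / n_bg
        p_over = float(hypergeom.sf(k - 1, n_bg, m, n_q))
        p_under = float(hypergeom.cdf(k, n_bg, m, n_q))
        p_two = min(1.0, 2.0 * min(p_over, p_under))
        enr = k / expected if expected > 0 else math.nan
        rows.append((name, m, k, expected, enr, p_over, p_under, p_two))
    out = pd.DataFrame(
        rows,
        columns=["category", "size", "observed", "expected", "enrichment",
                 "p_over", "p_under", "p"],
    )
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["padj"] < 0.05
        lo, hi = expected_band
        out["in_band"] = (out["expected"] >= lo) & (out["expected"] <= hi)
    return out
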
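"""Pileup parsing, panel filtering, and the joint genotype caller."""

import io

import numpy as np
import pandas as pd
import pytest

from microase import genotyping as gt
from microase.simulate import SimConfig, simulate_allele_counts


def make_panel(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"])


PANEL = make_panel([
    ("chr1", 1000, "C", "A", 0.2),
    ("chr1", 2000, "T", "G", 0.3),
])


class TestParsePileup:
    def parse_one(self, bases, quals, ref="C", alt="A", minq=0):
        panel = make_panel([("chr1", 1000, ref, alt, 0.2)])
        line = f"chr1\t1000\tN\t{len(quals)}\t{bases}\t{quals}"
        out = gt.parse_pileup([line], panel, min_base_quality=minq)
        row = out.iloc[0]
        return row["n_ref"], row["n_alt"], row["n_other"]

    def test_all_reference(self):
        assert self.parse_one("....,", "IIIII") == (5, 0, 0)

    def test_mixed_bases(self):
        # hand-parsed: 2 ref symbols, A/a match alt, G is neither allele
        assert self.parse_one(".,AaG", "IIIII") == (2, 2, 1)

    def test_insertion_ignored(self):
        assert self.parse_one(".+2AG..", "III") == (3, 0, 0)

    def test_deletion_and_read_markers_ignored(self):
        # ^F starts a read (mapping-quality char consumed), $ ends one,
        # * is a deletion placeholder occupying a quality slot
        assert self.parse_one("^F.$.*,", "IIII") == (3, 0, 0)

    def test_quality_filter(self):
        # '!' is phred 0, 'I' is phred 40
        assert self.parse_one(".,A", "!I!", minq=13) == (1, 0, 0)

    def test_site_not_in_panel_skipped_and_dense_output(self):
        lines = ["chr9\t5\tN\t2\t..\tII"]
        out = gt.parse_pileup(lines, PANEL)
        assert len(out) == 2  # dense: every panel site present with zeros
        assert (out[["n_ref", "n_alt", "n_other"]] == 0).all().all()

    def test_multi_sample_columns(self):
        line = "chr1\t1000\tN\t2\t..\tII\t3\tAAa\tIII"
        out = gt.parse_pileup([line], PANEL, sample_names=["s1", "s2"])
        s1 = out[(out["sample"] == "s1") & (out["pos"] == 1000)].iloc[0]
        s2 = out[(out["sample"] == "s2") & (out["pos"] == 1000)].iloc[0]
        assert (s1["n_ref"], s1["n_alt"]) == (2, 0)
        assert (s2["n_ref"], s2["n_alt"]) == (0, 3)

    @pytest.mark.parametrize("bad", [
        "chr1\t1000\tN\t1\t.",             # wrong field count
        "chr1\tXX\tN\t1\t.\tI",            # non-integer position
        "chr1\t1000\tN\t1\t.+A\tI",        # indel without length
        "chr1\t1000\tN\t2\t..\tI",         # quality string too short
    ])
    def test_malformed_line_names_line_number(self, bad):
        with pytest.raises(gt.PileupParseError, match="line 1"):
            gt.parse_pileup([bad], PANEL)


class TestFilterPanel:
    def test_maf_boundary(self):
        panel = make_panel([
            ("chr1", 10, "A", "C", 0.04),
            ("chr1", 20, "A", "C", 0.05),
        ])
        out = gt.filter_panel(panel, maf_min=0.05)
        # removal rule is strictly-below: 0.04 removed, 0.05 exactly kept
        assert list(out["pos"]) == [20]

    def test_bed_exclusion_is_zero_based_half_open(self):
        panel = make_panel([
            ("chr1", 1000, "A", "C", 0.3),
            ("chr1", 1001, "A", "C", 0.3),
            ("chr2", 1000, "A", "C", 0.3),
        ])
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [999], "end": [1000]})
        out = gt.filter_panel(panel, excluded_regions=bed)
        # interval [999, 1000) covers 0-based 999 == 1-based 1000, chr1 only
        assert list(zip(out["chrom"], out["pos"])) == [("chr1", 1001), ("chr2", 1000)]

    def test_empty_exclusions_only_maf_rule(self):
        out = gt.filter_panel(PANEL, excluded_regions=pd.DataFrame(
            columns=["chrom", "start", "end"]))
        assert len(out) == len(PANEL)

    def test_negative_coordinates_rejected(self):
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [-5], "end": [10]})
        with pytest.raises(ValueError):
            gt.filter_panel(PANEL, excluded_regions=bed)


class TestGenotypePosterior:
    def test_hom_ref_overwhelming(self):
        post = gt.genotype_posterior(50, 0, maf=0.2, eps=0.001)
        assert post[0] > 0.999
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_het_overwhelming(self):
        post = gt.genotype_posterior(25, 25, maf=0.2, eps=0.001)
        assert post[1] > 0.999

    def test_allele_swap_symmetry(self):
        """Swapping ref/alt labels (and hence the allele frequency) swaps
        the homozygous posteriors and preserves the het posterior."""
        a = gt.genotype_posterior(30, 5, maf=0.3, eps=0.01)
        b = gt.genotype_posterior(5, 30, maf=0.7, eps=0.01)
        assert np.allclose(a, b[::-1], atol=1e-12)


def _counts_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample", "n_ref", "n_alt", "n_other"]
    )


class TestJointGenotype:
    def test_zero_coverage_prior_posterior_uncallable(self):
        panel = make_panel([("chr1", 1000, "C", "A", 0.2)])
        counts = _counts_df([("chr1", 1000, "C", "A", "s1", 0, 0, 0)])
        res = gt.joint_genotype(counts, panel)
        row = res.calls.iloc[0]
        hw = np.array([0.64, 0.32, 0.04])
        assert np.allclose(row[["post_RR", "post_RA", "post_AA"]].astype(float), hw)
        assert not row["callable"]

    def test_pools_across_samples(self):
        panel = make_panel([("chr1", 1000, "C", "A", 0.2)])
        counts = _counts_df([
            ("chr1", 1000, "C", "A", "s1", 12, 11, 0),
            ("chr1", 1000, "C", "A", "s2", 13, 14, 0),
        ])
        res = gt.joint_genotype(counts, panel)
        assert res.calls.iloc[0]["genotype"] == "RA"
        assert res.calls.iloc[0][["n_ref", "n_alt"]].tolist() == [25, 25]

    def test_em_loglik_monotone_and_eps_recovery(self):
        cfg = SimConfig(n_sites=1500, error_rate=0.008, ase_fraction=0.0,
                        case_fraction=0.0, seed=5)
        _, counts, _ = simulate_allele_counts(cfg)
        res = gt.joint_genotype(counts, gt.validate_panel(
            simulate_panel_of(cfg)))
        ll = np.array(res.loglik_trace)
        assert np.all(np.diff(ll) >= -1e-9)
        assert res.epsilon == pytest.approx(0.008, rel=0.35)
        sums = res.calls[["post_RR", "post_RA", "post_AA"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_het_recall_precision(self, small_run):
        """Pooled coverage ~400x at eps=0.005: het discovery is near perfect."""
        truth = small_run["truth"]
        calls = small_run["geno"].calls
        het_called = set(small_run["het"]["pos"] // 1000 - 1)
        true_het = set(np.flatnonzero(truth.genotype == "RA"))
        covered = set((calls.loc[(calls["n_ref"] + calls["n_alt"]) >= 20, "pos"] // 1000 - 1))
        true_het &= covered
        tp = len(het_called & true_het)
        assert tp / max(1, len(het_called)) >= 0.99   # precision
        assert tp / max(1, len(true_het)) >= 0.99     # recall


def simulate_panel_of(cfg):
    """Regenerate the panel drawn inside simulate_allele_counts (same seed)."""
    from microase.simulate import simulate_panel
    return simulate_panel(cfg, np.random.default_rng(cfg.seed))


class TestCallHeterozygotes:
    def test_threshold_and_empty(self):
        calls = pd.DataFrame({
            "post_RA": [0.995, 0.5, 0.99],
            "callable": [True, True, True],
        })
        out = gt.call_heterozygotes(calls, posterior_min=0.99)
        assert list(out["post_RA"]) == [0.995, 0.99]
        assert len(gt.call_heterozygotes(calls.iloc[:0], 0.99)) == 0
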
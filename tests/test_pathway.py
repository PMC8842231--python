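"""Pathway quantification: filtering, cell estimates, balance statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tripscar import (
    PathwayRules,
    PipelineParams,
    classify_nhej_by_inhibitor,
    classify_pathways,
    estimate_cells,
    filter_not_clear,
    normalize_replicates,
    summarize_pool,
)
from tripscar.pathway import not_clear_fraction
from conftest import exact_ranksum_p_less


def table(rows):
    df = pd.DataFrame(rows, columns=["barcode", "call", "indel_size", "reads"])
    df["indel_size"] = df["indel_size"].astype("Int64")
    return df


class TestNotClear:
    def test_rows_removed_and_fraction_known(self):
        t = table([
            ("b1", "wt", 0, 40), ("b1", "not_clear", None, 6),
            ("b2", "not_clear", None, 4),
        ])
        assert not_clear_fraction(t) == pytest.approx(10 / 50)
        out = filter_not_clear(t)
        assert "not_clear" not in set(out["call"])
        assert out["reads"].sum() == 40

    def test_identity_without_not_clear(self):
        t = table([("b1", "wt", 0, 40)])
        assert filter_not_clear(t).equals(t)

    def test_simulated_fraction_recovered(self, spec, params):
        """~20% of reads programmed unreadable shows up as ~20% not_clear."""
        from tripscar import call_reads, extract_reads
        from tripscar.simulate import SimulationConfig, simulate_indel_reads

        cfg = SimulationConfig(
            seed=31, n_integrations=10, depth_per_barcode=200,
            indel_spectrum={"wt": 0.5, 1: 0.3, 60: 0.2},
        )  # +60 insertion pushes every spacer and the window out of the read
        reads, truth, idx = simulate_indel_reads(spec, cfg)
        results, _ = extract_reads(reads, spec, params, index_table=idx)
        counts, _ = call_reads(results, spec)
        frac = not_clear_fraction(counts)
        assert frac == pytest.approx(0.2, abs=0.03)


class TestEstimateCells:
    def test_single_barcode_gets_full_pool(self, params):
        t = table([("b1", "wt", 0, 1234)])
        est = estimate_cells(t, params)
        assert est["estimated_cells"].iloc[0] == pytest.approx(600_000)
        assert bool(est["kept"].iloc[0])

    def test_linearity(self, params):
        t = table([("b1", "wt", 0, 50), ("b2", "wt", 0, 50)])
        est = estimate_cells(t, params).set_index("barcode")
        assert est.loc["b1", "estimated_cells"] == pytest.approx(300_000)

    def test_low_abundance_barcode_dropped(self, params):
        t = table([("b1", "wt", 0, 99995), ("b2", "wt", 0, 5)])
        est = estimate_cells(t, params).set_index("barcode")
        # b2 fraction 5e-5 -> 30 cells < 50
        assert est.loc["b2", "estimated_cells"] == pytest.approx(30)
        assert not bool(est.loc["b2", "kept"])

    def test_estimates_conserve_pool_size(self, params):
        rng = np.random.default_rng(0)
        t = table([(f"b{i}", "wt", 0, int(rng.integers(1, 1000))) for i in range(50)])
        est = estimate_cells(t, params)
        assert est["estimated_cells"].sum() == pytest.approx(600_000)

    def test_empty_table_is_an_error(self, params):
        with pytest.raises(ValueError):
            estimate_cells(table([]), params)


class TestNormalizeReplicates:
    def test_single_replicate_matches_raw_fractions(self):
        t = table([("b1", "wt", 0, 60), ("b1", "del", -7, 40)])
        out = normalize_replicates([t]).set_index("call")
        assert out.loc["wt", "proportion"] == pytest.approx(0.6)
        assert out.loc["del", "proportion"] == pytest.approx(0.4)

    def test_depth_invariance(self):
        t1 = table([("b1", "wt", 0, 60), ("b1", "del", -7, 40)])
        t2 = table([("b1", "wt", 0, 600), ("b1", "del", -7, 400)])
        out = normalize_replicates([t1, t2]).set_index("call")
        assert out.loc["wt", "proportion"] == pytest.approx(0.6)

    def test_multinomial_replicates_recover_truth(self):
        rng = np.random.default_rng(1)
        p = np.array([0.5, 0.15, 0.35])
        reps = []
        for _ in range(3):
            n = rng.multinomial(5000, p)
            reps.append(table([
                ("b1", "wt", 0, int(n[0])),
                ("b1", "del", -7, int(n[1])),
                ("b1", "ins", 1, int(n[2])),
            ]))
        out = normalize_replicates(reps).set_index("call")
        se = np.sqrt(p * (1 - p) / (3 * 5000))
        assert abs(out.loc["wt", "proportion"] - 0.5) < 4 * se[0]
        assert abs(out.loc["del", "proportion"] - 0.15) < 4 * se[1]

    def test_zero_total_replicate_excluded(self):
        good = table([("b1", "wt", 0, 10)])
        empty = table([])
        out = normalize_replicates([good, empty])
        assert out["proportion"].iloc[0] == pytest.approx(1.0)


class TestClassifyPathways:
    def test_balance_from_signature_counts(self):
        t = table([("b1", "del", -7, 30), ("b1", "ins", 1, 70), ("b1", "wt", 0, 900)])
        out = classify_pathways(t).set_index("barcode")
        assert out.loc["b1", "mmej_fraction"] == pytest.approx(0.30)
        assert out.loc["b1", "mmej_count"] == 30
        assert out.loc["b1", "nhej_count"] == 70

    def test_nhej_only_gives_zero_fraction(self):
        t = table([("b1", "ins", 1, 50)])
        out = classify_pathways(t)
        assert out["mmej_fraction"].iloc[0] == pytest.approx(0.0)

    def test_no_signature_reads_gives_nan(self):
        t = table([("b1", "del", -3, 50), ("b1", "wt", 0, 100)])
        out = classify_pathways(t)
        assert np.isnan(out["mmej_fraction"].iloc[0])
        assert out["other_count"].iloc[0] == 50

    def test_wt_excluded_from_denominators(self):
        with_wt = table([("b1", "del", -7, 10), ("b1", "ins", 1, 10), ("b1", "wt", 0, 1000)])
        without = table([("b1", "del", -7, 10), ("b1", "ins", 1, 10)])
        assert classify_pathways(with_wt)["mmej_fraction"].iloc[0] == \
            classify_pathways(without)["mmej_fraction"].iloc[0]

    def test_depth_scaling_invariance(self):
        t = table([("b1", "del", -7, 3), ("b1", "ins", 1, 7), ("b1", "del", -2, 5)])
        t10 = t.copy()
        t10["reads"] *= 10
        assert classify_pathways(t)["mmej_fraction"].iloc[0] == \
            classify_pathways(t10)["mmej_fraction"].iloc[0]

    def test_detail_mode_routes_mh0_deletion_to_other(self):
        """A -7 deletion without flanking microhomology is not MMEJ."""
        t = table([("b1", "del", -7, 20), ("b1", "ins", 1, 20),
                   ("b2", "del", -7, 20), ("b2", "ins", 1, 20)])
        details = pd.DataFrame({
            "barcode": ["b1"] * 4 + ["b2"] * 4,
            "indel_size": [-7] * 8,
            "microhomology_len": [3, 3, 3, 3, 0, 0, 0, 1],
        })
        out = classify_pathways(t, details=details).set_index("barcode")
        assert out.loc["b1", "mmej_count"] == 20
        assert out.loc["b2", "mmej_count"] == 0
        assert out.loc["b2", "other_count"] == 20


class TestInhibitorClassification:
    @staticmethod
    def _ratios(rng, n, p, depth=2000):
        return rng.binomial(depth, p, size=n) / depth

    def test_suppressed_insertion_labeled_nhej(self, params):
        """+1 dropping 10-fold under DNA-PK inhibition across 50 barcodes."""
        rng = np.random.default_rng(5)
        dmso = pd.DataFrame({
            "indel": ["+1"] * 50 + ["-7"] * 50,
            "ratio": np.r_[self._ratios(rng, 50, 0.30), self._ratios(rng, 50, 0.15)],
        })
        inhib = pd.DataFrame({
            "indel": ["+1"] * 50 + ["-7"] * 50,
            "ratio": np.r_[self._ratios(rng, 50, 0.03), self._ratios(rng, 50, 0.16)],
        })
        out = classify_nhej_by_inhibitor(dmso, inhib, params).set_index("indel")
        assert bool(out.loc["+1", "nhej"])
        assert not bool(out.loc["-7", "nhej"])

    def test_low_dmso_ratio_never_tested(self, params):
        rng = np.random.default_rng(6)
        dmso = pd.DataFrame({"indel": ["x"] * 10, "ratio": self._ratios(rng, 10, 0.005)})
        inhib = pd.DataFrame({"indel": ["x"] * 10, "ratio": self._ratios(rng, 10, 0.0005)})
        out = classify_nhej_by_inhibitor(dmso, inhib, params)
        assert not bool(out["tested"].iloc[0])
        assert not bool(out["nhej"].iloc[0])

    def test_too_few_observations_reported_untested(self, params):
        dmso = pd.DataFrame({"indel": ["x", "x"], "ratio": [0.3, 0.31]})
        inhib = pd.DataFrame({"indel": ["x", "x"], "ratio": [0.05, 0.06]})
        out = classify_nhej_by_inhibitor(dmso, inhib, params)
        assert not bool(out["tested"].iloc[0])

    def test_wilcoxon_matches_exact_enumeration(self):
        """Rank-sum p-values agree with full enumeration for n, m <= 8."""
        rng = np.random.default_rng(7)
        for n, m in [(3, 3), (4, 6), (5, 5), (8, 7), (8, 8)]:
            for _ in range(5):
                x = rng.permutation(np.arange(1000))[:n].astype(float)
                y = rng.permutation(np.arange(1000, 2000))[:m].astype(float)
                rng.shuffle(y)
                got = sps.mannwhitneyu(x, y, alternative="less").pvalue
                want = exact_ranksum_p_less(x, y)
                assert got == pytest.approx(want, rel=1e-12), (n, m)


class TestSummarizePool:
    def _calls(self, barcodes, status="pass"):
        return pd.DataFrame({
            "barcode": barcodes, "chrom": "chr1",
            "pos": range(len(barcodes)), "strand": "+",
            "status": status, "reasons": "",
        })

    def test_inner_join_logs_unmatched(self):
        pathway = classify_pathways(table(
            [(f"b{i}", "ins", 1, 10) for i in range(8)]
        ))
        joined = summarize_pool(pathway, self._calls([f"b{i}" for i in range(10)]))
        assert len(joined) == 8

    def test_failed_integrations_excluded(self):
        pathway = classify_pathways(table([("b0", "ins", 1, 10)]))
        joined = summarize_pool(pathway, self._calls(["b0"], status="fail"))
        assert joined.empty

    def test_empty_scar_table_gives_empty_join(self):
        pathway = classify_pathways(table([]))
        joined = summarize_pool(pathway, self._calls(["b0"]))
        assert joined.empty
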
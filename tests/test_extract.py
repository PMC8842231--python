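"""Barcode extraction: three-step strategy, demultiplexing, read-through."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tripscar import (
    ConfigError,
    demultiplex_index,
    extract_barcode,
    extract_ipcr_pair,
    extract_reads,
    trim_readthrough,
)
from tripscar._seq import hamming, revcomp
from tripscar.simulate import SimulationConfig, make_index_table, simulate_indel_reads, simulate_ipcr

BC16 = "ACGTTGCAAGGTCCAT"


def build_read(spec, barcode=BC16, prefix="", scar=None):
    scar = spec.wt_amplicon if scar is None else scar
    return prefix + spec.adapter_5p + barcode + spec.adapter_3p + scar


class TestThreeStepStrategy:
    def test_error_free_read_is_full(self, spec, params):
        res = extract_barcode(build_read(spec), spec, params)
        assert res.step == "full"
        assert res.barcode == BC16
        assert res.remainder == spec.wt_amplicon

    @pytest.mark.parametrize("blen", [15, 16, 17])
    def test_tolerated_barcode_lengths_via_full(self, spec, params, blen):
        bc = ("ACGT" * 5)[:blen]
        res = extract_barcode(build_read(spec, barcode=bc), spec, params)
        assert res.step == "full"
        assert res.barcode == bc

    def test_corrupt_3p_arm_falls_back_to_five_prime(self, spec, params):
        read = spec.adapter_5p + BC16 + "GGGGG" + spec.wt_amplicon
        res = extract_barcode(read, spec, params)
        assert res.step == "five_prime"
        assert res.barcode == BC16

    def test_two_subs_in_5p_arm_fall_back_to_three_prime(self, spec, params):
        """With tolerance 1, a doubly-substituted 5' arm cannot match.

        Exhaustively place two substitutions and confirm the 3' route always
        recovers the barcode.
        """
        arm = spec.adapter_5p
        # verify by exhaustive mismatch placement that 2 subs defeat tolerance 1
        for i in range(0, len(arm), 7):
            for j in range(i + 1, len(arm), 5):
                corrupted = list(arm)
                corrupted[i] = "A" if arm[i] != "A" else "C"
                corrupted[j] = "A" if arm[j] != "A" else "C"
                corrupted = "".join(corrupted)
                assert hamming(corrupted, arm) == 2
                read = corrupted + BC16 + spec.adapter_3p + spec.wt_amplicon
                res = extract_barcode(read, spec, params)
                assert res.step == "three_prime"
                assert res.barcode == BC16

    def test_unextractable_read_fails_without_raising(self, spec, params):
        res = extract_barcode("ACGT" * 40, spec, params)
        assert res.step == "failed"
        assert res.barcode is None

    def test_short_read_counts_as_failed(self, spec, params):
        res = extract_barcode("ACGTAC", spec, params)
        assert res.step == "failed"

    @settings(max_examples=50, deadline=None)
    @given(prefix=st.text(alphabet="ACGT", max_size=30))
    def test_position_independence(self, prefix):
        """Prepending unrelated sequence never changes the extracted barcode.

        "Unrelated" means the prefix does not itself create an earlier
        adapter match (a prefix containing the adapter is a different read).
        """
        from hypothesis import assume

        from tripscar import PipelineParams
        from tripscar._seq import find_approx
        from tripscar.simulate import make_reporter

        spec = make_reporter(7)
        params = PipelineParams()
        junction = prefix + spec.adapter_5p[: len(spec.adapter_5p) - 1]
        assume(find_approx(junction, spec.adapter_5p, params.adapter_max_mismatches) == -1)
        base = extract_barcode(build_read(spec), spec, params)
        shifted = extract_barcode(build_read(spec, prefix=prefix), spec, params)
        assert shifted.barcode == base.barcode
        assert shifted.step == "full"


class TestDemultiplex:
    def test_exact_index_assigned_and_stripped(self):
        table = {"AAAAACCCCC": "s1", "GGGGGTTTTT": "s2"}
        sample, rest = demultiplex_index("AAAAACCCCC" + "ACGT", table)
        assert sample == "s1"
        assert rest == "ACGT"

    def test_one_mismatch_within_tolerance(self):
        rng = np.random.default_rng(1)
        table = make_index_table(6, 10, rng)
        idx = next(iter(table))
        corrupted = ("T" if idx[0] != "T" else "A") + idx[1:]
        # oracle: Hamming scan over the table
        dists = {i: hamming(corrupted, i) for i in table}
        assert dists[idx] == 1 and all(d >= 3 for i, d in dists.items() if i != idx)
        sample, _ = demultiplex_index(corrupted + "ACGT", table, max_mismatch=1)
        assert sample == table[idx]

    def test_unassignable_read(self):
        table = {"AAAAACCCCC": "s1", "GGGGGTTTTT": "s2"}
        sample, rest = demultiplex_index("TTTTTAAAAA" + "ACGT", table)
        assert sample is None
        assert rest.startswith("TTTTT")

    def test_clashing_indices_rejected(self):
        with pytest.raises(ConfigError, match="within"):
            demultiplex_index("ACGT", {"AAAAA": "s1", "AAAAT": "s2"})


class TestReadThrough:
    def test_appended_revcomp_adapter_removed(self, spec):
        rem = spec.wt_amplicon[:60] + revcomp(spec.adapter_5p) + "ACGTACGT"
        assert trim_readthrough(rem, spec) == spec.wt_amplicon[:60]

    def test_clean_remainder_unchanged(self, spec):
        assert trim_readthrough(spec.wt_amplicon, spec) == spec.wt_amplicon

    def test_pattern_with_one_error_still_trimmed(self, spec):
        pat = revcomp(spec.adapter_5p)
        pat = pat[:4] + ("A" if pat[4] != "A" else "C") + pat[5:]
        rem = spec.wt_amplicon[:60] + pat + "ACGT"
        assert trim_readthrough(rem, spec) == spec.wt_amplicon[:60]

    def test_truncated_pattern_at_read_end_trimmed(self, spec):
        rem = spec.wt_amplicon[:60] + revcomp(spec.adapter_5p)[:8]
        assert trim_readthrough(rem, spec) == spec.wt_amplicon[:60]


class TestIpcrPairs:
    def test_error_free_pair(self, spec, params):
        genomic = "ACGT" * 20
        r1 = build_read(spec, scar="TTTT" * 10)
        r2 = spec.ipcr_read2_constant + genomic
        res, gen = extract_ipcr_pair(r1, r2, spec, params)
        assert res.ok and res.barcode == BC16
        assert gen == genomic

    def test_read2_without_constant_rejects_pair(self, spec, params):
        r1 = build_read(spec)
        res, gen = extract_ipcr_pair(r1, "ACGT" * 30, spec, params)
        assert not res.ok
        assert gen is None

    def test_simulated_pairs_recover_barcodes_at_low_error(self, spec, params):
        cfg = SimulationConfig(seed=11, n_integrations=25, ipcr_depth=40,
                               substitution_error_rate=0.001)
        sim = simulate_ipcr(spec, cfg)
        truth = dict(zip(sim["truth"]["read_id"], sim["truth"]["barcode"]))
        ok = 0
        for rid, s1, s2 in sim["pairs"]:
            res, gen = extract_ipcr_pair(s1, s2, spec, params, read_id=rid)
            if res.ok and res.barcode == truth[rid] and gen:
                ok += 1
        assert ok / len(sim["pairs"]) >= 0.99


class TestStatsConservation:
    def test_counters_sum_to_total(self, spec, params):
        cfg = SimulationConfig(seed=5, n_integrations=10, depth_per_barcode=100,
                               substitution_error_rate=0.01, barcode_mutation_rate=0.05,
                               n_samples=4)
        reads, truth, index_table = simulate_indel_reads(spec, cfg)
        results, stats = extract_reads(reads, spec, params, index_table=index_table)
        stats.check()
        assert stats.total == len(reads)
        assert stats.total == sum(stats.per_step.values()) + stats.failed
        assert len(results) == len(reads)

    def test_noiseless_extraction_is_perfect_and_full(self, spec, params):
        cfg = SimulationConfig(seed=6, n_integrations=10, depth_per_barcode=50)
        reads, truth, index_table = simulate_indel_reads(spec, cfg)
        results, stats = extract_reads(reads, spec, params, index_table=index_table)
        assert stats.failed == 0
        assert stats.per_step["full"] == len(reads)
        by_id = dict(zip(truth["read_id"], truth["barcode"]))
        assert all(r.barcode == by_id[r.read_id] for r in results)
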
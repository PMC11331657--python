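"""Junction derivation, window extraction, PWM construction, composition."""

import numpy as np
import pytest

from spliceconcord.errors import NoWindowsError, WindowBoundsError
from spliceconcord.io import GenomeSequence, reverse_complement
from spliceconcord.motifs import (
    Junction,
    JunctionWindow,
    build_pwm,
    composition_profile,
    derive_junctions,
    extract_window,
    motif_pipeline,
)

from conftest import make_event


class TestDeriveJunctions:
    def test_se_plus_strand(self):
        j = derive_junctions(make_event("SE"))
        assert [(x.side, x.cut_point) for x in j] == [("3ss", 100), ("5ss", 200)]

    def test_se_minus_strand_swaps_labels(self):
        j = derive_junctions(make_event("SE", strand="-"))
        assert sorted((x.side, x.cut_point) for x in j) == [("3ss", 200), ("5ss", 100)]

    def test_ri_uses_retained_intron_boundaries(self):
        j = derive_junctions(make_event("RI"))
        assert [(x.side, x.cut_point) for x in j] == [("5ss", 80), ("3ss", 250)]

    def test_mxe_yields_both_exons_sites(self):
        j = derive_junctions(make_event("MXE"))
        assert [(x.side, x.cut_point) for x in j] == [
            ("3ss", 100), ("5ss", 150), ("3ss", 170), ("5ss", 220),
        ]

    def test_alternative_site_events_yield_both_cut_points(self):
        a5 = derive_junctions(make_event("A5SS"))
        assert [(x.side, x.cut_point) for x in a5] == [("5ss", 300), ("5ss", 250)]
        a3 = derive_junctions(make_event("A3SS"))
        assert [(x.side, x.cut_point) for x in a3] == [("3ss", 100), ("3ss", 150)]


class TestExtractWindow:
    def test_plus_strand_substring(self):
        genome = GenomeSequence({"c": "ACGT" * 15})
        w = extract_window(genome, Junction("5ss", "c", "+", 29), flank=2)
        assert w.sequence == "TACG"  # positions 27..30

    def test_minus_strand_is_reverse_complement(self):
        genome = GenomeSequence({"c": "ACGT" * 15})
        w = extract_window(genome, Junction("5ss", "c", "-", 29), flank=2)
        assert w.sequence == "CGTA"

    def test_out_of_bounds_rejected(self):
        genome = GenomeSequence({"c": "ACGT" * 15})
        with pytest.raises(WindowBoundsError):
            extract_window(genome, Junction("5ss", "c", "+", 1), flank=25)

    def test_strand_symmetry_on_random_junctions(self):
        rng = np.random.default_rng(42)
        genome = GenomeSequence({"c": "".join(rng.choice(list("ACGT"), 500))})
        for cut in rng.integers(10, 490, 50):
            plus = extract_window(genome, Junction("5ss", "c", "+", int(cut)), flank=10)
            minus = extract_window(genome, Junction("5ss", "c", "-", int(cut)), flank=10)
            assert minus.sequence == reverse_complement(plus.sequence)


class TestBuildPwm:
    def test_unanimous_columns(self):
        pwm = build_pwm(["AC", "AC"], pseudocount=0.0)
        assert pwm.probs[0, 0] == 1.0 and pwm.probs[1, 1] == 1.0
        assert pwm.consensus == "AC"
        assert pwm.info_content == pytest.approx([2.0, 2.0])

    def test_even_split_columns(self):
        pwm = build_pwm(["AA", "CC"], pseudocount=0.0)
        assert pwm.probs[:, 0] == pytest.approx([0.5, 0.5])
        assert pwm.probs[:, 1] == pytest.approx([0.5, 0.5])

    def test_pseudocount_arithmetic(self):
        pwm = build_pwm(["A"], pseudocount=0.5)
        assert pwm.probs[0, 0] == pytest.approx((1 + 0.5) / (1 + 2))
        assert pwm.probs[0, 1] == pytest.approx(0.5 / 3)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGTN"), 20)) for _ in range(30)]
        pwm = build_pwm(seqs)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_background_equal_ppm_has_zero_log_odds_and_ic(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        assert np.allclose(pwm.log_odds, 0.0)
        assert np.allclose(pwm.info_content, 0.0)

    def test_consensus_tie_breaks_alphabetically(self):
        pwm = build_pwm(["G", "T"], pseudocount=0.0)
        assert pwm.consensus == "G"

    def test_n_bases_excluded_from_counts(self):
        pwm = build_pwm(["A", "N", "N"], pseudocount=0.0)
        assert pwm.probs[0, 0] == 1.0

    def test_mixed_lengths_and_empty_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["AA", "A"])
        with pytest.raises(ValueError):
            build_pwm([])


class TestCompositionProfile:
    def _w(self, seq, side="5ss"):
        return JunctionWindow("c", "+", 0, side, seq)

    def test_pure_gc_exonic_half(self):
        windows = [self._w("GG" + "AA"), self._w("GC" + "TT")]
        prof = composition_profile(windows)
        assert prof.exonic_gc == 1.0

    def test_all_a_windows_have_zero_aggregates(self):
        prof = composition_profile([self._w("AAAA")])
        assert prof.exonic_gc == 0.0 and prof.intronic_ct == 0.0

    def test_half_assignment_follows_side_label(self):
        prof5 = composition_profile([self._w("GGAA"), self._w("TTCC")])
        assert prof5.exonic_gc == pytest.approx(0.5)  # G,G,T,T at positions 0-1
        prof3 = composition_profile([self._w("GGAA", "3ss"), self._w("TTCC", "3ss")])
        # 3ss exonic half is the last flank positions: A,A,C,C
        assert prof3.exonic_gc == pytest.approx(0.5)
        assert prof3.intronic_ct == pytest.approx(0.5)  # G,G,T,T intronic

    def test_zero_windows_rejected(self):
        with pytest.raises(ValueError):
            composition_profile([])


class TestMotifPipeline:
    def test_planted_splice_site_consensus_recovered(self, small_fixture):
        _, genome, _, tables, truth = small_fixture
        events = [e for c in tables.values() for t in c.values() for e in t]
        result = motif_pipeline(events, genome, flank=25)
        five = result.pooled["5ss"]
        assert five.n_sequences >= 50
        # intronic positions right of the cut carry the donor consensus
        assert five.consensus[25:30] == truth.five_ss_consensus
        three = result.pooled["3ss"]
        assert three.consensus[22:25] == truth.three_ss_consensus
        # planted composition bias: G/C-rich exonic 5'ss, C/T-rich intronic 3'ss
        assert result.composition["5ss"].exonic_gc > 0.55
        assert result.composition["3ss"].intronic_ct > 0.65

    def test_fdr_filter_leaves_no_windows(self, small_fixture):
        _, genome, _, tables, _ = small_fixture
        events = [e for t in tables["kd1"].values() for e in t]
        with pytest.raises(NoWindowsError):
            motif_pipeline(events, genome, fdr_threshold=1e-9)

    def test_single_se_event_gives_two_windows_of_twice_flank(self, small_fixture):
        _, genome, _, tables, _ = small_fixture
        event = tables["kd1"]["SE"][0]
        result = motif_pipeline([event], genome, flank=3)
        assert len(result.windows["5ss"]) == 1 and len(result.windows["3ss"]) == 1
        assert len(result.pooled["5ss"].probs) == 6

    def test_out_of_bounds_windows_skipped_and_counted(self):
        ev = make_event("SE", contig="tiny",
                        coords={"upstream": (0, 4), "target": (5, 9), "downstream": (10, 14)})
        genome = GenomeSequence({"tiny": "ACGTACGTACGTAC"})
        with pytest.raises(NoWindowsError):
            motif_pipeline([ev], genome, flank=25)
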
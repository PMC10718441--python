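"""Cents arithmetic, interval sets, equidistance and octave inference."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scalestats import (
    all_pair_intervals,
    cents_from_ratio,
    equidistant_reference,
    infer_octave_scale,
    mean_note_deviation,
    notes_from_steps,
    steps_from_notes,
)
from scalestats.core import OctaveInferenceOptions
from scalestats.errors import DomainError
from tests.test_corpus_io import make_record

steps_lists = st.lists(
    st.floats(min_value=1.0, max_value=500.0, allow_nan=False), min_size=1, max_size=12
)


class TestCentsArithmetic:
    @pytest.mark.parametrize(
        "f1,f2,expected",
        [(2.0, 1.0, 1200.0), (1.0, 1.0, 0.0), (3.0, 2.0, 701.955)],
    )
    def test_known_ratios(self, f1, f2, expected):
        assert cents_from_ratio(f1, f2) == pytest.approx(expected, abs=1e-3)

    def test_negative_when_descending(self):
        assert cents_from_ratio(1.0, 2.0) == pytest.approx(-1200.0)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(DomainError):
            cents_from_ratio(0.0, 1.0)

    @given(steps_lists)
    def test_steps_notes_round_trip(self, steps):
        notes = notes_from_steps(steps)
        assert notes[0] == 0.0
        assert notes.size == len(steps) + 1
        assert np.allclose(steps_from_notes(notes), steps)

    def test_equidistant_steps(self):
        notes = notes_from_steps([1200 / 7] * 7)
        assert notes[-1] == pytest.approx(1200.0)
        assert np.allclose(np.diff(notes), 1200 / 7)

    def test_non_monotone_rejected(self):
        with pytest.raises(DomainError):
            steps_from_notes([0.0, 300.0, 200.0])


class TestPairIntervals:
    def test_small_example(self):
        iv = sorted(all_pair_intervals([0.0, 100.0, 300.0]))
        assert iv == [100.0, 200.0, 300.0]

    @pytest.mark.parametrize("n", range(2, 31))
    def test_cardinality_matches_brute_force(self, n, rng):
        notes = np.concatenate([[0.0], np.sort(rng.uniform(1, 3000, n - 1))])
        iv = all_pair_intervals(notes)
        brute = [
            notes[j] - notes[i] for i in range(n) for j in range(i + 1, n)
        ]
        assert iv.size == n * (n - 1) // 2
        assert np.allclose(np.sort(iv), np.sort(brute))

    def test_equidistant_multiset(self):
        iv = all_pair_intervals(equidistant_reference(5, 1200))
        vals, counts = np.unique(np.round(iv, 6), return_counts=True)
        assert np.allclose(vals, [240, 480, 720, 960, 1200])
        assert list(counts) == [5, 4, 3, 2, 1]


class TestEquidistance:
    def test_reference_endpoints(self):
        assert list(equidistant_reference(2, 1200)) == [0.0, 600.0, 1200.0]
        ref7 = equidistant_reference(7, 1200)
        assert np.allclose(np.diff(ref7), 1200 / 7)

    def test_self_deviation_zero(self):
        ref = equidistant_reference(7)
        assert mean_note_deviation(ref, ref).mean_abs_deviation == 0.0

    def test_diatonic_vs_equiheptatonic(self):
        diatonic = [0, 200, 400, 500, 700, 900, 1100, 1200]
        stat = mean_note_deviation(diatonic, equidistant_reference(7))
        assert stat.mean_abs_deviation == pytest.approx(38.0952, abs=1e-3)
        assert stat.within  # inside the 43-cent boundary

    def test_translation_invariance(self, rng):
        scale = np.concatenate([[0.0], np.sort(rng.uniform(1, 1199, 6)), [1200.0]])
        ref = equidistant_reference(7)
        base = mean_note_deviation(scale, ref).mean_abs_deviation
        shifted = mean_note_deviation(scale + 5.0, ref + 5.0).mean_abs_deviation
        assert shifted == pytest.approx(base)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DomainError):
            mean_note_deviation([0, 600, 1200], equidistant_reference(7))


class TestOctaveInference:
    def test_exact_octave_span_passes_through(self):
        rec = make_record(notes=(0.0, 200.0, 700.0, 1200.0))
        out = infer_octave_scale(rec)
        assert len(out) == 1
        assert out[0].kind == "octave"
        assert out[0].notes == (0.0, 200.0, 700.0, 1200.0)

    def test_rescale_near_octave(self):
        rec = make_record(notes=(0.0, 200.0, 700.0, 1190.0))
        out = infer_octave_scale(rec)
        assert len(out) == 1
        notes = np.asarray(out[0].notes)
        assert notes[-1] == pytest.approx(1200.0, abs=1e-9)
        assert np.allclose(notes, np.array([0, 200, 700, 1190]) * 1200 / 1190)
        assert np.sum(np.diff(notes)) == pytest.approx(1200.0, abs=1e-6)

    def test_fold_and_merge(self):
        rec = make_record(notes=(0.0, 200.0, 700.0, 1200.0, 1400.0))
        out = infer_octave_scale(rec)
        assert len(out) == 1
        assert np.allclose(out[0].notes, [0.0, 200.0, 700.0, 1200.0])

    def test_unfoldable_returns_empty(self):
        rec = make_record(notes=(0.0, 200.0, 700.0))
        assert infer_octave_scale(rec) == []

    def test_min_notes_filter(self):
        rec = make_record(notes=(0.0, 600.0, 1200.0))
        assert infer_octave_scale(rec, OctaveInferenceOptions(min_notes=4)) == []
        kept = infer_octave_scale(rec, OctaveInferenceOptions(min_notes=3))
        assert len(kept) == 1

    def test_all_tonics_deduplicates(self):
        rec = make_record(notes=(0.0, 240.0, 480.0, 720.0, 960.0, 1200.0))
        out = infer_octave_scale(rec, OctaveInferenceOptions(tonic_mode="all", min_notes=3))
        # rotations of an equidistant scale truncate to shorter suffixes;
        # every emitted scale must be a valid octave scale
        for o in out:
            assert o.notes[-1] == 1200.0
            assert np.sum(np.diff(o.notes)) == pytest.approx(1200.0, abs=1e-6)

    def test_steps_sum_invariant(self, measured_corpus):
        for rec in measured_corpus.records[:40]:
            for out in infer_octave_scale(rec):
                assert np.sum(np.diff(out.notes)) == pytest.approx(1200.0, abs=1e-6)

    def test_theory_scale_rejected(self):
        rec = make_record(kind="theory", method="theory", notes=(0.0, 1200.0))
        with pytest.raises(DomainError):
            infer_octave_scale(rec)
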
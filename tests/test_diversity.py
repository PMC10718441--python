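"""Grid enumeration, equidistance, entropy, variants and embedding."""
import numpy as np
import pytest

from scalestats import (
    EmbeddingSpec,
    GridSpec,
    closed_form_grid_count,
    count_grid_scales,
    embed_and_cluster,
    enumerate_grid_scales,
    equidistance_fraction,
    equidistant_reference,
    note_index_entropy,
    note_index_histograms,
    shuffled_variants,
    sorted_variants,
)
from scalestats.corpus import Corpus
from scalestats.errors import DomainError
from tests.test_corpus_io import make_record


class TestGridEnumeration:
    def test_tiny_case_by_hand(self):
        spec = GridSpec(n_notes=2, span=600)
        assert list(enumerate_grid_scales(spec)) == [
            (280, 320), (300, 300), (320, 280)
        ]
        assert count_grid_scales(spec) == 3

    def test_infeasible_spec_counts_zero(self):
        spec = GridSpec(n_notes=7, span=400)  # 7 * 60 > 400
        assert count_grid_scales(spec) == 0
        assert list(enumerate_grid_scales(spec)) == []

    def test_count_matches_closed_form_for_random_specs(self, rng):
        checked = 0
        while checked < 20:
            res = 20
            n = int(rng.integers(2, 8))
            a = int(rng.integers(2, 8)) * res
            b = a + int(rng.integers(0, 8)) * res
            span = int(rng.integers(n * a // res, n * b // res + 1)) * res
            spec = GridSpec(resolution=res, step_min=a, step_max=b, span=span, n_notes=n)
            dp = count_grid_scales(spec)
            if dp == 0 or dp > 10**7:
                continue
            assert dp == closed_form_grid_count(spec)
            checked += 1

    def test_iterator_agrees_with_array(self):
        spec = GridSpec(n_notes=4, span=800, step_min=100, step_max=300, resolution=20)
        tuples = sorted(enumerate_grid_scales(spec))
        arr = enumerate_grid_scales(spec).step_array()
        assert len(tuples) == arr.shape[0] == count_grid_scales(spec)
        assert sorted(map(tuple, arr.tolist())) == tuples
        assert np.all(arr.sum(axis=1) == 800)
        assert arr.min() >= 100 and arr.max() <= 300


class TestEquidistanceFraction:
    def test_equidistant_scale_always_inside(self):
        ref = equidistant_reference(7)
        assert equidistance_fraction([ref], 7, threshold=0.0) == 1.0

    def test_diatonic_inside_43(self):
        diatonic = [0, 200, 400, 500, 700, 900, 1100, 1200]
        assert equidistance_fraction([diatonic], 7, threshold=43.0) == 1.0
        assert equidistance_fraction([diatonic], 7, threshold=30.0) == 0.0

    def test_mixed_note_counts_rejected(self):
        with pytest.raises(DomainError):
            equidistance_fraction(
                [[0, 600, 1200], [0, 400, 800, 1200]], 2
            )


class TestNoteHistogramsAndEntropy:
    def test_point_mass_has_zero_entropy(self):
        ref = equidistant_reference(7)
        hists = note_index_histograms([ref] * 10, 7)
        assert np.all(hists.counts.sum(axis=1) == 10)
        assert np.allclose(note_index_entropy(hists), 0.0)

    def test_uniform_histogram_maximises_entropy(self):
        from scalestats.diversity import NoteHistograms

        counts = np.ones((1, 16), dtype=np.int64)
        h = NoteHistograms(
            note_numbers=np.array([2]), bin_centers=np.arange(16.0), counts=counts
        )
        assert note_index_entropy(h)[0] == pytest.approx(4.0)

    def test_entropy_permutation_invariant(self, rng):
        from scalestats.diversity import NoteHistograms

        counts = rng.integers(0, 50, size=(1, 20))
        counts[0, 0] += 1  # non-empty
        perm = rng.permutation(20)
        a = NoteHistograms(np.array([2]), np.arange(20.0), counts)
        b = NoteHistograms(np.array([2]), np.arange(20.0), counts[:, perm])
        assert note_index_entropy(a)[0] == pytest.approx(note_index_entropy(b)[0])


class TestVariants:
    def test_sorted_variants_by_hand(self):
        rec = make_record(notes=(0.0, 100.0, 400.0, 600.0))  # steps 100,300,200
        out = sorted_variants(Corpus(records=[rec]))
        steps = {tuple(np.round(np.diff(r.notes), 6)) for r in out}
        assert steps == {(100, 200, 300), (200, 300, 100), (300, 100, 200)}

    def test_equidistant_input_gives_identical_copies(self):
        rec = make_record(notes=tuple(np.arange(6) * 240.0))
        out = sorted_variants(Corpus(records=[rec]))
        assert len(out) == 5
        assert all(np.allclose(r.notes, rec.notes) for r in out)

    def test_output_count_is_total_steps(self, measured_corpus):
        sub = Corpus(records=list(measured_corpus.records[:20]))
        out = sorted_variants(sub)
        assert len(out) == sum(r.n_steps for r in sub)

    def test_shuffled_variants_conserve_multisets(self, measured_corpus):
        sub = Corpus(records=list(measured_corpus.records[:20]))
        out = shuffled_variants(sub, seed=1)
        for a, b in zip(sub, out):
            assert np.allclose(np.sort(np.diff(a.notes)), np.sort(np.diff(b.notes)))
        again = shuffled_variants(sub, seed=1)
        assert all(x.notes == y.notes for x, y in zip(out, again))


class TestEmbedding:
    def planted_corpus(self, rng):
        records = []
        ref = equidistant_reference(7)
        diatonic = np.array([0, 200, 400, 500, 700, 900, 1100, 1200], dtype=float)
        for i in range(50):
            for name, base in (("eq", ref), ("dia", diatonic)):
                notes = base.copy()
                notes[1:-1] += rng.normal(0, 5, 6)
                notes[1:-1] = np.sort(notes[1:-1])
                records.append(
                    make_record(
                        scale_id=f"{name}{i}",
                        society_id=f"soc_{name}",
                        region="region_1" if name == "eq" else "region_2",
                        notes=tuple(notes),
                    )
                )
        return Corpus(records=records)

    def test_planted_clusters_recovered(self, rng):
        corpus = self.planted_corpus(rng)
        res = embed_and_cluster(corpus, EmbeddingSpec(), seed=0)
        labels = res.labels
        non_noise = sorted(set(labels) - {-1})
        assert len(non_noise) == 2
        # each cluster should be dominated by one planted group
        ids = np.array([r.scale_id.startswith("eq") for r in corpus])
        for lab in non_noise:
            members = ids[labels == lab]
            assert members.mean() > 0.9 or members.mean() < 0.1
        assert set(res.cluster_regions) == set(non_noise)

    def test_embedding_preserves_neighbourhoods(self, rng):
        from scipy.spatial.distance import pdist
        from scipy.stats import spearmanr

        corpus = self.planted_corpus(rng)
        res = embed_and_cluster(corpus, EmbeddingSpec(), seed=1)
        vec = np.vstack([r.notes[1:-1] for r in corpus])
        rho = spearmanr(pdist(vec), pdist(res.coordinates)).statistic
        assert rho > 0.5

    def test_too_few_points_all_noise(self):
        ref = equidistant_reference(7)
        records = [
            make_record(scale_id=f"x{i}", notes=tuple(ref + 0))
            for i in range(3)
        ]
        res = embed_and_cluster(
            Corpus(records=records), EmbeddingSpec(min_samples=5), seed=2
        )
        assert np.all(res.labels == -1)

    def test_mixed_note_counts_rejected(self):
        records = [
            make_record(scale_id="a", notes=(0.0, 600.0, 1200.0)),
            make_record(scale_id="b", notes=(0.0, 400.0, 800.0, 1200.0)),
        ]
        with pytest.raises(DomainError):
            embed_and_cluster(Corpus(records=records), EmbeddingSpec(), seed=3)
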
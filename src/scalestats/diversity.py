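"""Scale-space enumeration, equidistance statistics, entropy and embedding.

To put real scales in context, the space of *possible* scales is enumerated
on a cents grid: every ordered tuple of steps on a 20-cent grid, each step
within 60-320 cents, summing to the octave.  Distinct orderings are
distinct scales, because note positions (the quantity analysed) depend on
step order.  Real and grid scales are then compared through:

- the fraction of scales whose internal notes lie within a threshold of
  the equidistant reference (mean absolute deviation),
- per-note-index histograms and their Shannon entropy (notes 2..n, i.e.
  tonic and octave excluded), with sorted-step and shuffled-step variants
  of real scales as contrasts, and
- a 2-D t-SNE embedding of internal note vectors with DBSCAN density
  clustering.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE

from .core import GridSpec, OCTAVE, equidistant_reference
from .corpus import Corpus, ScaleRecord
from .errors import DomainError
from .nulls import shuffle_scale


def _grid_units(spec: GridSpec) -> tuple[int, int, int, int]:
    """(min_part, max_part, target_sum, n_parts) in units of the resolution."""
    r = spec.resolution
    return spec.step_min // r, spec.step_max // r, spec.span // r, spec.n_notes


def count_grid_scales(spec: GridSpec) -> int:
    """Number of ordered step tuples, via exact polynomial convolution.

    Counts compositions of the span into n bounded parts on the grid; the
    count of an infeasible spec is 0.
    """
    a, b, s, n = _grid_units(spec)
    if n * a > s or n * b < s:
        return 0
    # coefficient of x^(s - n*a) in (1 + x + ... + x^(b-a))^n
    block = np.ones(b - a + 1, dtype=object)
    poly = np.array([1], dtype=object)
    for _ in range(n):
        poly = np.convolve(poly, block)
    target = s - n * a
    return int(poly[target]) if target < poly.size else 0


@dataclass
class GridEnumeration:
    """Lazy enumeration of all grid scales for a spec."""

    spec: GridSpec

    @property
    def count(self) -> int:
        return count_grid_scales(self.spec)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        a, b, s, n = _grid_units(self.spec)
        r = self.spec.resolution

        def rec(prefix: list[int], remaining: int, slots: int):
            if slots == 0:
                if remaining == 0:
                    yield tuple(v * r for v in prefix)
                return
            lo = max(a, remaining - (slots - 1) * b)
            hi = min(b, remaining - (slots - 1) * a)
            for v in range(lo, hi + 1):
                prefix.append(v)
                yield from rec(prefix, remaining - v, slots - 1)
                prefix.pop()

        yield from rec([], s, n)

    def step_array(self) -> np.ndarray:
        """All step tuples as an int32 array of shape (count, n_notes), in cents.

        Built level-by-level with feasibility pruning, so it is vectorised
        and never visits dead branches.
        """
        a, b, s, n = _grid_units(self.spec)
        if n * a > s or n * b < s:
            return np.empty((0, n), dtype=np.int32)
        prefixes = np.zeros((1, 0), dtype=np.int32)
        sums = np.zeros(1, dtype=np.int64)
        values = np.arange(a, b + 1, dtype=np.int32)
        for pos in range(n):
            slots_left = n - pos - 1
            cand_sums = sums[:, None] + values[None, :]
            feasible = (cand_sums + slots_left * a <= s) & (
                cand_sums + slots_left * b >= s
            )
            rows, cols = np.nonzero(feasible)
            prefixes = np.hstack(
                [prefixes[rows], values[cols][:, None]]
            )
            sums = cand_sums[rows, cols]
        return prefixes * np.int32(self.spec.resolution)


def enumerate_grid_scales(spec: GridSpec) -> GridEnumeration:
    """All possible ordered step tuples on the grid (lazily iterable)."""
    return GridEnumeration(spec=spec)


def grid_note_array(spec: GridSpec) -> np.ndarray:
    """Note positions (including tonic and top note) of every grid scale."""
    steps = enumerate_grid_scales(spec).step_array()
    notes = np.zeros((steps.shape[0], spec.n_notes + 1), dtype=np.float64)
    np.cumsum(steps, axis=1, out=notes[:, 1:])
    return notes


def _as_note_matrix(scales: Iterable[Sequence[float]] | np.ndarray, n: int) -> np.ndarray:
    """Coerce an iterable of note lists (or a 2-D array) to shape (m, n+1)."""
    if isinstance(scales, np.ndarray) and scales.ndim == 2:
        mat = np.asarray(scales, dtype=float)
    else:
        rows = [np.asarray(s, dtype=float) for s in scales]
        if not rows:
            return np.empty((0, n + 1))
        sizes = {r.size for r in rows}
        if sizes != {n + 1}:
            raise DomainError(f"expected scales with {n + 1} notes, got sizes {sizes}")
        mat = np.vstack(rows)
    if mat.shape[1] != n + 1:
        raise DomainError(
            f"expected {n + 1} notes per scale, got {mat.shape[1]}"
        )
    return mat


def internal_deviations(notes: np.ndarray, n: int, span: float = OCTAVE) -> np.ndarray:
    """Mean |note_i - i*span/n| over internal notes i = 1..n-1, per scale."""
    ref = equidistant_reference(n, span)[1:-1]
    return np.mean(np.abs(notes[:, 1:-1] - ref[None, :]), axis=1)


def equidistance_fraction(
    scales: Iterable[Sequence[float]] | np.ndarray,
    n: int,
    threshold: float = 43.0,
) -> float:
    """Fraction of n-step scales within ``threshold`` cents of equidistant.

    The statistic is the mean absolute deviation of the n-1 internal notes
    from the equidistant reference over the octave.
    """
    mat = _as_note_matrix(scales, n)
    if mat.shape[0] == 0:
        raise DomainError("no scales given")
    dev = internal_deviations(mat, n)
    return float(np.mean(dev <= threshold))


@dataclass
class NoteHistograms:
    """Per-internal-note-index histograms (indices are note numbers 2..n)."""

    note_numbers: np.ndarray  # 2..n
    bin_centers: np.ndarray
    counts: np.ndarray  # (n-1, n_bins)


def note_index_histograms(
    scales: Iterable[Sequence[float]] | np.ndarray,
    n: int,
    bin_width: float = 20.0,
    span: float = OCTAVE,
) -> NoteHistograms:
    """Histogram of positions of each internal note across scales.

    One histogram per note number 2..n (tonic is note 1, the top note is
    note n+1); each histogram sums to the number of scales.
    """
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    mat = _as_note_matrix(scales, n)
    n_bins = int(round(span / bin_width)) + 1
    centers = np.arange(n_bins) * bin_width
    counts = np.zeros((n - 1, n_bins), dtype=np.int64)
    for j in range(1, n):
        idx = np.floor(mat[:, j] / bin_width + 0.5).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        counts[j - 1] = np.bincount(idx, minlength=n_bins)
    return NoteHistograms(
        note_numbers=np.arange(2, n + 1), bin_centers=centers, counts=counts
    )


def note_index_entropy(histograms: NoteHistograms) -> np.ndarray:
    """Shannon entropy (bits) of each internal note's normalised histogram."""
    counts = histograms.counts.astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise DomainError("empty histogram")
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def sorted_variants(corpus: Corpus) -> Corpus:
    """Rearranged scales with steps sorted low-to-high, one per rotation.

    For each input scale with k steps, the k rotations of the ascending
    step sequence are emitted — the arrangement farthest from well-mixed
    step orderings, used as an entropy contrast.
    """
    records = []
    for r in corpus:
        steps = np.sort(np.diff(r.notes))
        k = steps.size
        for rot in range(k):
            rolled = np.roll(steps, -rot)
            notes = np.concatenate([[0.0], np.cumsum(rolled)])
            notes[-1] = r.notes[-1]
            records.append(
                r.with_notes(notes, scale_id=f"{r.scale_id}_sorted{rot}")
            )
    return Corpus(records=records)


def shuffled_variants(corpus: Corpus, seed: int | np.random.Generator) -> Corpus:
    """Scales with step order randomly permuted (one variant per scale)."""
    rng = np.random.default_rng(seed)
    records = []
    for r in corpus:
        shuffled = shuffle_scale(r, rng)
        records.append(
            shuffled.with_notes(shuffled.notes, scale_id=f"{r.scale_id}_shuf")
        )
    return Corpus(records=records)


@dataclass
class EmbeddingSpec:
    """t-SNE + DBSCAN parameters; clustering runs in embedding space."""

    eps: float = 2.0
    min_samples: int = 5
    perplexity: float = 30.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise DomainError("eps must be positive")
        if self.min_samples < 1:
            raise DomainError("min_samples must be >= 1")


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (m, 2)
    labels: np.ndarray  # cluster labels, -1 = noise
    cluster_note_means: dict[int, np.ndarray]
    cluster_regions: dict[int, dict[str, int]]

    def to_frame(self, corpus: Corpus) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scale_id": [r.scale_id for r in corpus],
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "cluster": self.labels,
            }
        )


def embed_and_cluster(
    corpus: Corpus,
    spec: EmbeddingSpec | None = None,
    seed: int | None = None,
) -> EmbeddingResult:
    """2-D t-SNE embedding of internal note vectors + DBSCAN clustering.

    All scales must share one note count (vectors of internal notes are the
    features).  Noise points get label -1.  Per non-noise cluster, the mean
    internal note vector and the region composition are reported.
    """
    spec = spec or EmbeddingSpec()
    counts = {len(r.notes) for r in corpus}
    if len(counts) != 1:
        raise DomainError(f"scales must share one note count, got {sorted(counts)}")
    vectors = np.vstack([np.asarray(r.notes[1:-1]) for r in corpus])
    m = vectors.shape[0]
    perplexity = min(spec.perplexity, max(1.0, (m - 1) / 3.0))
    if m <= 3 or float(np.ptp(vectors, axis=0).max()) < 1e-12:
        # degenerate input (too few or all-duplicate points): t-SNE is
        # undefined, every point embeds to the origin
        coords = np.zeros((m, 2))
    else:
        coords = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=np.random.default_rng(seed).integers(2**31 - 1),
            init="pca",
            # Barnes-Hut is unstable on small inputs
            method="exact" if m < 200 else "barnes_hut",
        ).fit_transform(vectors)
    labels = DBSCAN(eps=spec.eps, min_samples=spec.min_samples).fit_predict(coords)
    note_means: dict[int, np.ndarray] = {}
    regions: dict[int, dict[str, int]] = {}
    for lab in sorted(set(labels) - {-1}):
        members = labels == lab
        note_means[int(lab)] = vectors[members].mean(axis=0)
        reg: dict[str, int] = {}
        for r, keep in zip(corpus, members):
            if keep:
                reg[r.region] = reg.get(r.region, 0) + 1
        regions[int(lab)] = reg
    return EmbeddingResult(
        coordinates=coords,
        labels=labels,
        cluster_note_means=note_means,
        cluster_regions=regions,
    )


def closed_form_grid_count(spec: GridSpec) -> int:
    """Inclusion-exclusion count of bounded compositions (independent oracle).

    With parts shifted to 0..m (m = (step_max - step_min)/resolution) and
    target U, the count is sum_j (-1)^j C(n, j) C(U - j(m+1) + n - 1, n - 1).
    """
    a, b, s, n = _grid_units(spec)
    m = b - a
    U = s - n * a
    if U < 0 or U > n * m:
        return 0
    total = 0
    for j in range(n + 1):
        rem = U - j * (m + 1)
        if rem < 0:
            break
        total += (-1) ** j * math.comb(n, j) * math.comb(rem + n - 1, n - 1)
    return total
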
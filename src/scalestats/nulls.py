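"""Null models of scale generation: Lognorm, Shuffle and Resample.

Each model produces alternative scale sets whose *layout* — the number of
scales and the number of notes in each scale — matches the original corpus:

- **Lognorm**: scale notes are drawn independently from a lognormal
  distribution fitted to the pooled note positions.  Small intervals are
  rare (limits of pitch perception) and very large intervals are rare
  (instrument/anatomy constraints), which a lognormal captures with two
  parameters.
- **Shuffle**: each scale keeps its own step sizes but their order is
  randomly permuted, preserving the per-scale step multiset and span.
- **Resample**: step sizes are drawn i.i.d. from the pooled empirical step
  distribution and arranged into scales.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import Corpus, ScaleRecord
from .errors import DomainError

#: jitter added to duplicate lognormal draws to keep notes strictly increasing
_DUP_EPS = 1e-9


@dataclass(frozen=True)
class LognormParams:
    """Location and scale of a lognormal note distribution (log-cents units)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError("sigma must be non-negative")


@dataclass(frozen=True)
class Layout:
    """Notes-per-scale of a corpus (tonic included); all entries >= 2."""

    notes_per_scale: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(k < 2 for k in self.notes_per_scale):
            raise DomainError("every scale needs at least 2 notes")

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "Layout":
        return cls(notes_per_scale=tuple(corpus.layout()))

    def __len__(self) -> int:
        return len(self.notes_per_scale)


def fit_lognormal(values: Sequence[float]) -> LognormParams:
    """Maximum-likelihood lognormal fit.

    mu is the mean of natural logs and sigma the *population* (1/n) standard
    deviation of natural logs — the true MLE of the lognormal.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("need at least two values")
    if np.any(v <= 0):
        raise DomainError("values must be positive")
    logs = np.log(v)
    mu = float(np.mean(logs))
    sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
    return LognormParams(mu=mu, sigma=sigma)


def _null_record(i: int, prefix: str, notes: Sequence[float]) -> ScaleRecord:
    return ScaleRecord(
        scale_id=f"{prefix}_{i:05d}",
        society_id=prefix,
        region="null",
        country="null",
        kind="measured",
        method="instrument",
        tonic_known=False,
        notes=tuple(notes),
    )


def sample_lognorm_scales(
    params: LognormParams, layout: Layout, seed: int | np.random.Generator
) -> Corpus:
    """Draw scales with independent lognormal notes, matching ``layout``.

    Per scale, k-1 non-tonic notes are drawn independently, sorted ascending
    and prefixed with the tonic at 0.  Duplicate draws (possible when sigma
    is tiny) are perturbed by a negligible offset so notes stay strictly
    increasing.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i, k in enumerate(layout.notes_per_scale):
        notes = np.sort(rng.lognormal(params.mu, params.sigma, size=k - 1))
        # break exact ties
        for j in range(1, notes.size):
            if notes[j] <= notes[j - 1]:
                notes[j] = notes[j - 1] + _DUP_EPS
        records.append(_null_record(i, "lognorm", [0.0, *notes]))
    return Corpus(records=records)


def shuffle_scale(record: ScaleRecord, seed: int | np.random.Generator) -> ScaleRecord:
    """Permute the order of a scale's steps uniformly at random.

    The step multiset, note count and total span are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    steps = np.diff(record.notes)
    perm = rng.permutation(steps)
    notes = np.concatenate([[0.0], np.cumsum(perm)])
    notes[-1] = record.notes[-1]  # guard against float drift in the span
    return record.with_notes(notes)


def shuffle_corpus(corpus: Corpus, seed: int | np.random.Generator) -> Corpus:
    """Apply :func:`shuffle_scale` to every record."""
    rng = np.random.default_rng(seed)
    return Corpus(records=[shuffle_scale(r, rng) for r in corpus.records])


def step_pool(corpus: Corpus) -> np.ndarray:
    """Pooled empirical multiset of step sizes across a corpus."""
    pool = corpus.all_steps()
    if pool.size == 0:
        raise DomainError("corpus has no steps")
    return pool


def resample_scales(
    pool: Sequence[float], layout: Layout, seed: int | np.random.Generator
) -> Corpus:
    """Build scales from steps drawn i.i.d. with replacement from ``pool``."""
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise DomainError("step pool is empty")
    rng = np.random.default_rng(seed)
    records = []
    for i, k in enumerate(layout.notes_per_scale):
        steps = rng.choice(pool, size=k - 1, replace=True)
        records.append(_null_record(i, "resample", [0.0, *np.cumsum(steps)]))
    return Corpus(records=records)


def resample_like(corpus: Corpus, seed: int | np.random.Generator) -> Corpus:
    """Resample-model corpus matching the layout and step pool of ``corpus``."""
    return resample_scales(step_pool(corpus), Layout.from_corpus(corpus), seed)
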
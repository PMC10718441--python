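"""Cents arithmetic, interval sets, equidistance metrics and octave-scale inference.

Pitch intervals are measured in cents: 1200 * log2 of a frequency ratio, so
an octave (ratio 2:1) is 1200 cents and a just fifth (3:2) is ~701.955
cents.  Scales are represented as strictly increasing note positions in
cents from the tonic (note 0).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import ScaleRecord
from .errors import DomainError

OCTAVE = 1200.0


@dataclass(frozen=True)
class GridSpec:
    """Specification of a grid of hypothetical scales.

    Steps live on a regular cents grid and are bounded; a scale is an ordered
    tuple of ``n_notes`` steps summing to ``span``.
    """

    resolution: int = 20
    step_min: int = 60
    step_max: int = 320
    span: int = 1200
    n_notes: int = 7

    def __post_init__(self) -> None:
        for name in ("step_min", "step_max", "span"):
            v = getattr(self, name)
            if v <= 0 or v % self.resolution != 0:
                raise DomainError(
                    f"{name}={v} must be a positive multiple of resolution "
                    f"{self.resolution}"
                )
        if self.step_min > self.step_max:
            raise DomainError("step_min must not exceed step_max")
        if self.n_notes < 1:
            raise DomainError("n_notes must be >= 1")


@dataclass(frozen=True)
class EquidistanceStat:
    """Mean absolute deviation of internal notes from a reference scale."""

    mean_abs_deviation: float
    reference_n: int
    threshold: float

    @property
    def within(self) -> bool:
        return self.mean_abs_deviation <= self.threshold


def cents_from_ratio(f1: float, f2: float) -> float:
    """Interval in cents between frequencies ``f1`` and ``f2``.

    Negative when ``f1 < f2``.
    """
    if f1 <= 0 or f2 <= 0:
        raise DomainError("frequencies must be positive")
    return OCTAVE * math.log2(f1 / f2)


def notes_from_steps(steps: Sequence[float]) -> np.ndarray:
    """Cumulative note positions from adjacent step sizes (tonic 0 prepended)."""
    steps = np.asarray(steps, dtype=float)
    if steps.size == 0:
        raise DomainError("need at least one step")
    if np.any(steps <= 0):
        raise DomainError("steps must be positive")
    out = np.empty(steps.size + 1)
    out[0] = 0.0
    np.cumsum(steps, out=out[1:])
    return out


def steps_from_notes(notes: Sequence[float]) -> np.ndarray:
    """Successive differences of a strictly increasing note list starting at 0."""
    notes = np.asarray(notes, dtype=float)
    if notes.size < 2:
        raise DomainError("need at least two notes")
    if notes[0] != 0:
        raise DomainError("first note must be 0")
    steps = np.diff(notes)
    if np.any(steps <= 0):
        raise DomainError("notes must be strictly increasing")
    return steps


def all_pair_intervals(notes: Sequence[float]) -> np.ndarray:
    """All positive pairwise intervals of a scale.

    For N notes this is the multiset of N*(N-1)/2 differences
    ``notes[j] - notes[i]`` with i < j — the full set of intervals playable
    on an instrument with those notes, not just the intervals from the tonic.
    """
    notes = np.asarray(notes, dtype=float)
    if notes.size < 2:
        raise DomainError("need at least two notes")
    if np.any(np.diff(notes) <= 0):
        raise DomainError("notes must be strictly increasing")
    i, j = np.triu_indices(notes.size, k=1)
    return notes[j] - notes[i]


def equidistant_reference(n: int, span: float = OCTAVE) -> np.ndarray:
    """Note positions of the n-step equidistant scale over ``span``.

    Returns n+1 notes at ``k * span / n`` for k = 0..n (tonic and top note
    included); the equiheptatonic scale is ``equidistant_reference(7)``.
    """
    if n < 2:
        raise DomainError("need at least 2 steps")
    if span <= 0:
        raise DomainError("span must be positive")
    return np.arange(n + 1) * (span / n)


def mean_note_deviation(
    scale_notes: Sequence[float],
    reference_notes: Sequence[float],
    threshold: float = 43.0,
) -> EquidistanceStat:
    """Mean absolute deviation of internal notes from a reference scale.

    Only internal notes (indices 1..n-1) enter the mean: the tonic and the
    top note are fixed by construction in octave scales, so including them
    would dilute the statistic.
    """
    a = np.asarray(scale_notes, dtype=float)
    b = np.asarray(reference_notes, dtype=float)
    if a.shape != b.shape:
        raise DomainError("scale and reference must have equal note counts")
    if a.size < 3:
        raise DomainError("need at least one internal note")
    dev = float(np.mean(np.abs(a[1:-1] - b[1:-1])))
    return EquidistanceStat(
        mean_abs_deviation=dev, reference_n=a.size - 1, threshold=threshold
    )


@dataclass(frozen=True)
class OctaveInferenceOptions:
    """Options controlling how octave scales are inferred from measured scales.

    tonic_mode:
        "first" uses the recorded first note as tonic; "reported" trusts the
        record's tonic flag but falls back to the first note; "all" tries
        every note as a candidate tonic and emits one octave scale per
        rotation (duplicates removed by exact note equality).
    fold_mode:
        "fold" maps notes into [0, 1200) by subtracting whole octaves;
        "truncate" drops notes above the octave window instead.
    rescale:
        If True, spans within ``octave_tolerance_cents`` of 1200 are
        rescaled multiplicatively to exactly 1200; if False only the final
        note is snapped to 1200.
    """

    tonic_mode: str = "first"
    fold_mode: str = "fold"
    rescale: bool = True
    octave_tolerance_cents: float = 50.0
    merge_threshold_cents: float = 20.0
    min_notes: int = 4

    def __post_init__(self) -> None:
        if self.tonic_mode not in ("first", "reported", "all"):
            raise DomainError(f"unknown tonic_mode {self.tonic_mode!r}")
        if self.fold_mode not in ("fold", "truncate"):
            raise DomainError(f"unknown fold_mode {self.fold_mode!r}")


def _merge_close(values: np.ndarray, threshold: float) -> list[float]:
    """Merge sorted values closer than ``threshold`` into their means."""
    merged: list[list[float]] = []
    for v in values:
        if merged and v - merged[-1][-1] < threshold:
            merged[-1].append(v)
        else:
            merged.append([v])
    return [float(np.mean(group)) for group in merged]


def _infer_one(notes: np.ndarray, opts: OctaveInferenceOptions) -> list[float] | None:
    """Infer a single octave scale from tonic-referenced notes, or None."""
    tol = opts.octave_tolerance_cents
    span = notes[-1]
    if span < OCTAVE - tol:
        return None  # unfoldable: does not reach the octave window

    if span <= OCTAVE + tol:
        if opts.rescale and span != OCTAVE:
            notes = notes * (OCTAVE / span)
        else:
            notes = notes.copy()
            notes[-1] = OCTAVE
        internal = notes[1:-1]
    elif opts.fold_mode == "truncate":
        kept = notes[notes <= OCTAVE + tol]
        if kept[-1] < OCTAVE - tol:
            return None
        return _infer_one(kept, opts)
    else:  # fold into one octave
        pcs = np.mod(notes[1:], OCTAVE)
        internal = pcs[(pcs > 0) & (pcs < OCTAVE)]
        internal = np.sort(internal)

    # merge folded/rescaled notes closer than the merge threshold; absorb
    # notes within the threshold of the tonic or the octave
    thr = opts.merge_threshold_cents
    internal = np.asarray(
        [v for v in internal if thr <= v <= OCTAVE - thr], dtype=float
    )
    merged = _merge_close(np.sort(internal), thr)
    out = [0.0] + merged + [OCTAVE]
    if len(out) < opts.min_notes:
        return None
    return out


def infer_octave_scale(
    record: ScaleRecord,
    options: OctaveInferenceOptions | None = None,
) -> list[ScaleRecord]:
    """Infer octave scales from a measured scale.

    The governing assumption is that measured scales are organised around an
    octave: a scale whose span reaches the octave window is reduced to notes
    in [0, 1200] with the final note exactly 1200.  Depending on options this
    involves rescaling near-octave spans, folding super-octave notes down by
    whole octaves, merging notes that land close together, and optionally
    trying every note as candidate tonic.

    Returns a (possibly empty) list of records with ``kind="octave"``.
    """
    opts = options or OctaveInferenceOptions()
    if record.kind != "measured":
        raise DomainError("octave inference applies to measured scales")
    base = np.asarray(record.notes, dtype=float)

    candidates: list[np.ndarray] = []
    if opts.tonic_mode in ("first", "reported"):
        candidates.append(base)
    else:  # every note as candidate tonic
        for t in base[:-1]:
            shifted = base[base >= t] - t
            if shifted.size >= 2:
                candidates.append(shifted)

    results: list[ScaleRecord] = []
    seen: set[tuple[float, ...]] = set()
    for idx, cand in enumerate(candidates):
        notes = _infer_one(cand, opts)
        if notes is None:
            continue
        key = tuple(round(x, 6) for x in notes)
        if key in seen:
            continue
        seen.add(key)
        suffix = f"_oct{idx}" if len(candidates) > 1 else "_oct"
        results.append(
            record.with_notes(notes, kind="octave", scale_id=record.scale_id + suffix)
        )
    return results
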
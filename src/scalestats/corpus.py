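"""Scale corpus containers and CSV input/output.

A *scale* is stored as an ordered list of note positions in cents measured
from the tonic (the first note, always 0 cents).  A :class:`Corpus` is the
unit every analysis consumes: a list of :class:`ScaleRecord` objects plus
society and region indices for group-balanced subsampling.

The on-disk format is a flat UTF-8 CSV with one row per scale and the
variable-length note list serialized as a semicolon-joined cell::

    scale_id,society_id,region,country,kind,method,tonic_known,notes
    s000_000,s000,region_1,country_000,measured,instrument,false,"0;204.000;702.000;1200.000"

Cents are written with 3 fractional digits, which is lossless relative to
the >=1 cent measurement error of ethnographic tuning data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RecordError, SchemaError

logger = logging.getLogger(__name__)

KINDS = ("theory", "measured", "octave")
METHODS = ("instrument", "song", "theory")
COLUMNS = (
    "scale_id",
    "society_id",
    "region",
    "country",
    "kind",
    "method",
    "tonic_known",
    "notes",
)

#: cents tolerance on the final note of a kind="octave" record
OCTAVE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class ScaleRecord:
    """One scale: metadata plus monotone note positions in cents from the tonic."""

    scale_id: str
    society_id: str
    region: str
    country: str
    kind: str
    method: str
    tonic_known: bool
    notes: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise RecordError(f"{self.scale_id}: unknown kind {self.kind!r}")
        if self.method not in METHODS:
            raise RecordError(f"{self.scale_id}: unknown method {self.method!r}")
        notes = tuple(float(x) for x in self.notes)
        object.__setattr__(self, "notes", notes)
        if len(notes) < 2:
            raise RecordError(f"{self.scale_id}: fewer than 2 notes")
        if notes[0] != 0.0:
            raise RecordError(f"{self.scale_id}: first note must be 0, got {notes[0]}")
        if any(b <= a for a, b in zip(notes, notes[1:])):
            raise RecordError(f"{self.scale_id}: notes not strictly increasing")
        if self.kind == "octave" and abs(notes[-1] - 1200.0) > OCTAVE_TOLERANCE:
            raise RecordError(
                f"{self.scale_id}: octave scale must end at 1200 cents, "
                f"got {notes[-1]}"
            )

    @property
    def steps(self) -> tuple[float, ...]:
        """Intervals between adjacent notes."""
        return tuple(b - a for a, b in zip(self.notes, self.notes[1:]))

    @property
    def n_steps(self) -> int:
        return len(self.notes) - 1

    @property
    def span(self) -> float:
        return self.notes[-1]

    def with_notes(self, notes: Sequence[float], **changes) -> "ScaleRecord":
        """Copy of this record with replaced notes (and optional field changes)."""
        return replace(self, notes=tuple(notes), **changes)


@dataclass
class Corpus:
    """A collection of scale records with society and region indices."""

    records: list[ScaleRecord] = field(default_factory=list)
    n_skipped: int = 0
    society_index: dict[str, list[int]] = field(init=False, repr=False)
    region_index: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [r.scale_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise RecordError("duplicate scale_id in corpus")
        self.rebuild_indices()

    def rebuild_indices(self) -> None:
        soc: dict[str, list[int]] = {}
        reg: dict[str, list[int]] = {}
        for i, r in enumerate(self.records):
            soc.setdefault(r.society_id, []).append(i)
            reg.setdefault(r.region, []).append(i)
        self.society_index = soc
        self.region_index = reg

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ScaleRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ScaleRecord:
        return self.records[i]

    def subset(self, indices: Iterable[int]) -> "Corpus":
        return Corpus(records=[self.records[i] for i in indices])

    def layout(self) -> list[int]:
        """Number of notes per scale (tonic included)."""
        return [len(r.notes) for r in self.records]

    def all_steps(self) -> np.ndarray:
        """Pooled step sizes across all scales."""
        if not self.records:
            return np.empty(0)
        return np.concatenate([np.diff(r.notes) for r in self.records])

    def all_notes(self, include_tonic: bool = False) -> np.ndarray:
        """Pooled note positions across all scales (tonic excluded by default)."""
        if not self.records:
            return np.empty(0)
        start = 0 if include_tonic else 1
        return np.concatenate([np.asarray(r.notes[start:]) for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scale_id": r.scale_id,
                "society_id": r.society_id,
                "region": r.region,
                "country": r.country,
                "kind": r.kind,
                "method": r.method,
                "tonic_known": "true" if r.tonic_known else "false",
                "notes": ";".join(f"{x:.3f}" for x in r.notes),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise RecordError(f"cannot parse boolean {value!r}")


def _parse_notes(cell: str) -> tuple[float, ...]:
    try:
        return tuple(float(x) for x in str(cell).split(";"))
    except ValueError as exc:
        raise RecordError(f"cannot parse notes cell {cell!r}") from exc


def read_corpus(path, strict: bool = False) -> Corpus:
    """Read a corpus CSV.

    Parameters
    ----------
    path:
        CSV file with the schema documented in this module.
    strict:
        If True, abort on the first invalid row.  Otherwise invalid rows are
        skipped with a logged warning and counted in ``Corpus.n_skipped``.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    records: list[ScaleRecord] = []
    skipped = 0
    for _, row in frame.iterrows():
        try:
            records.append(
                ScaleRecord(
                    scale_id=row["scale_id"],
                    society_id=row["society_id"],
                    region=row["region"],
                    country=row["country"],
                    kind=row["kind"],
                    method=row["method"],
                    tonic_known=_parse_bool(row["tonic_known"]),
                    notes=_parse_notes(row["notes"]),
                )
            )
        except RecordError as exc:
            if strict:
                raise
            skipped += 1
            logger.warning("skipping invalid record: %s", exc)
    return Corpus(records=records, n_skipped=skipped)


def write_corpus(corpus: Corpus, path) -> int:
    """Write a corpus to CSV; returns the number of data rows written."""
    frame = corpus.to_frame()
    frame.to_csv(path, index=False, lineterminator="\n")
    return len(frame)


def filter_corpus(corpus: Corpus, kind: str | None = None, region: str | None = None) -> Corpus:
    """Subset by scale kind and/or region; indices are rebuilt.

    An empty result is allowed (e.g. a region absent from the corpus).
    """
    records = [
        r
        for r in corpus.records
        if (kind is None or r.kind == kind) and (region is None or r.region == region)
    ]
    return Corpus(records=records)
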
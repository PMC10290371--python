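"""Append-only measurement database.

One JSON record per line; appends never rewrite earlier lines, so the file
is diffable and safe to version.  Whenever a new record of an already-known
patient is appended, migration deltas against that patient's most recent
earlier record (same method) are computed automatically and returned —
alignment change between follow-up timepoints is detected at write time,
not by a separate analysis step.  Patient identifiers are opaque strings;
no clinical metadata schema exists by construction.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .alignment import (
    ANGLE_PARAMS,
    DISTANCE_PARAMS,
    AlignmentMeasurement,
    MigrationDelta,
    migration_delta,
)

__all__ = ["MeasurementStore"]


class DuplicateRecordError(ValueError):
    """A record with the same (patient, timepoint, method, observer) exists."""


def _key(m: AlignmentMeasurement) -> tuple:
    return (m.patient_id, m.timepoint, m.method, m.observer_id)


class MeasurementStore:
    """JSON-lines store of :class:`AlignmentMeasurement` records."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._records: list[AlignmentMeasurement] = []
        if self.path.exists():
            with open(self.path) as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        self._records.append(AlignmentMeasurement.from_dict(json.loads(line)))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    @property
    def records(self) -> tuple[AlignmentMeasurement, ...]:
        return tuple(self._records)

    def append(
        self,
        measurement: AlignmentMeasurement,
        angle_threshold: float = 2.0,
        distance_threshold: float = 2.0,
    ) -> list[MigrationDelta]:
        """Append a record and return migration deltas against the most
        recent earlier record of the same patient and method (per observer)."""
        if any(_key(r) == _key(measurement) for r in self._records):
            raise DuplicateRecordError(f"duplicate record key {_key(measurement)}")
        earlier = [
            r
            for r in self._records
            if r.patient_id == measurement.patient_id
            and r.method == measurement.method
            and r.timepoint < measurement.timepoint
        ]
        deltas: list[MigrationDelta] = []
        if earlier:
            latest = max(earlier, key=lambda r: r.timepoint)
            deltas.append(
                migration_delta(
                    latest,
                    measurement,
                    angle_threshold=angle_threshold,
                    distance_threshold=distance_threshold,
                )
            )
        self._records.append(measurement)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(measurement.to_dict(), sort_keys=True) + "\n")
        return deltas

    def for_patient(self, patient_id: str) -> list[AlignmentMeasurement]:
        return [r for r in self._records if r.patient_id == patient_id]

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["patient_id", "timepoint", "observer_id", "method"]
        cols += list(ANGLE_PARAMS + DISTANCE_PARAMS)
        rows = [{c: getattr(r, c) for c in cols} for r in self._records]
        return pd.DataFrame(rows, columns=cols)

    def export_csv(self, path: str | Path) -> None:
        """Flat CSV export, one measurement per row."""
        self.to_dataframe().to_csv(path, index=False)
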
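"""Tabular container for tumor-volume measurements.

A :class:`MeasurementTable` holds one row per measurement in the study
design — patient × method (manual / semiauto) × observer (resident /
consultant) × contrast phase (arterial / venous) — and knows how to form
the paired comparisons the agreement statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agreement import PairedMeasurements
from .errors import ValidationError

__all__ = ["MeasurementTable", "METHODS", "OBSERVERS", "PHASES"]

METHODS = ("manual", "semiauto")
OBSERVERS = ("resident", "consultant")
PHASES = ("arterial", "venous")

REQUIRED_COLUMNS = ["patient", "method", "observer", "phase", "volume_ml"]


@dataclass
class MeasurementTable:
    """Long-format measurement table with one volume per
    patient × method × observer × phase cell."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"measurement table lacks columns {missing}")
        bad_m = set(self.df["method"]) - set(METHODS)
        bad_p = set(self.df["phase"]) - set(PHASES)
        if bad_m or bad_p:
            raise ValidationError(f"unknown method/phase labels: {bad_m | bad_p}")
        if (self.df["volume_ml"] < 0).any():
            raise ValidationError("volumes must be >= 0 ml")
        key = self.df[["patient", "method", "observer", "phase"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate measurement cell: {dup}")

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "MeasurementTable":
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    # -- basic queries -------------------------------------------------------
    @property
    def patients(self) -> list:
        return sorted(self.df["patient"].unique().tolist())

    @property
    def observers(self) -> list:
        return sorted(self.df["observer"].unique().tolist())

    def volumes(self, method: str) -> np.ndarray:
        """All volumes for one method, phases and observers merged."""
        return self.df.loc[self.df["method"] == method, "volume_ml"].to_numpy(dtype=float)

    def _cell(self, patients, method, observer, phase) -> np.ndarray:
        d = self.df
        sel = d[(d["method"] == method) & (d["observer"] == observer) & (d["phase"] == phase)]
        sel = sel.set_index("patient").reindex(patients)
        if sel["volume_ml"].isna().any():
            miss = sel[sel["volume_ml"].isna()].index.tolist()
            raise ValidationError(f"missing {method}/{observer}/{phase} measurements for patients {miss}")
        return sel["volume_ml"].to_numpy(dtype=float)

    # -- paired comparisons --------------------------------------------------
    def interobserver_pairs(
        self,
        method: str,
        pooling: str = "pooled",
        patients: Sequence | None = None,
        observers: Sequence[str] | None = None,
    ) -> PairedMeasurements:
        """Pairs (observer 1, observer 2) for one method.

        ``pooling='pooled'`` enters each phase as a separate item (2 items
        per patient); ``pooling='phase_mean'`` averages the two phases first
        (1 item per patient).
        """
        obs = list(observers) if observers is not None else self.observers
        if len(obs) != 2:
            raise ValidationError(f"interobserver pairing needs exactly 2 observers, got {obs}")
        pts = list(patients) if patients is not None else self.patients
        if pooling == "pooled":
            items = []
            for phase in PHASES:
                a = self._cell(pts, method, obs[0], phase)
                b = self._cell(pts, method, obs[1], phase)
                items += [(f"{p}-{phase}", float(x), float(y)) for p, x, y in zip(pts, a, b)]
            return PairedMeasurements(items)
        elif pooling == "phase_mean":
            a = (self._cell(pts, method, obs[0], PHASES[0]) + self._cell(pts, method, obs[0], PHASES[1])) / 2
            b = (self._cell(pts, method, obs[1], PHASES[0]) + self._cell(pts, method, obs[1], PHASES[1])) / 2
            return PairedMeasurements([(str(p), float(x), float(y)) for p, x, y in zip(pts, a, b)])
        raise ValidationError(f"unknown pooling {pooling!r}; expected 'pooled' or 'phase_mean'")

    def intraobserver_pairs(
        self,
        method: str,
        observer: str | None = None,
        patients: Sequence | None = None,
    ) -> PairedMeasurements:
        """Pairs (arterial, venous) within each observer for one method;
        both observers pooled unless one is named."""
        obs = [observer] if observer is not None else self.observers
        pts = list(patients) if patients is not None else self.patients
        items = []
        for o in obs:
            a = self._cell(pts, method, o, "arterial")
            v = self._cell(pts, method, o, "venous")
            items += [(f"{p}-{o}", float(x), float(y)) for p, x, y in zip(pts, a, v)]
        return PairedMeasurements(items)
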
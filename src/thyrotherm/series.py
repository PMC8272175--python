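"""Temperature-series transformations and summary metrics.

These operate identically on simulated series and on series extracted from
thermogram sequences: rebasing to a common origin for cross-case plots,
consecutive differences (the per-15 s heating rate), and the two scalar
summaries delta_TCL (front-minus-contralateral steady skin difference) and
delta_TF (temperature drop across the fat layer along the nodule line).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import NeckGeometry
from .protocol import TemperatureSeries

__all__ = [
    "DifferenceSeries",
    "SummaryMetrics",
    "rebase_series",
    "consecutive_differences",
    "summarize",
]


@dataclass
class DifferenceSeries:
    """Consecutive temperature differences; times are those of the second
    sample of each pair."""

    times: np.ndarray
    deltas: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if len(self.times) != len(self.deltas):
            raise ValueError("times and deltas must have equal length")

    def __len__(self) -> int:
        return len(self.deltas)

    def to_csv(self) -> str:
        header = f"# label: {self.label}\n" if self.label else ""
        return header + pd.DataFrame(
            {"time_s": self.times, "delta_degC": self.deltas}
        ).to_csv(index=False)


@dataclass(frozen=True)
class SummaryMetrics:
    start: float
    cooling_min: float
    end: float
    delta_TF: float
    delta_TCL: float

    def __post_init__(self) -> None:
        vals = [self.start, self.cooling_min, self.end, self.delta_TF, self.delta_TCL]
        if not np.isfinite(vals).all():
            raise ValueError("summary metrics must be finite")
        if self.cooling_min > self.start + 1e-12:
            raise ValueError("cooling minimum cannot exceed the start value")


def rebase_series(s: TemperatureSeries) -> TemperatureSeries:
    """Shift so the first value is 0 (common origin for comparison plots)."""
    if len(s) == 0:
        raise ValueError("cannot rebase an empty series")
    return TemperatureSeries(
        times=s.times.copy(), values=s.values - s.values[0], label=s.label
    )


def consecutive_differences(s: TemperatureSeries) -> DifferenceSeries:
    """deltas[i] = values[i+1] - values[i]; needs at least two samples."""
    if len(s) < 2:
        raise ValueError("need at least two samples for differences")
    return DifferenceSeries(
        times=s.times[1:].copy(), deltas=np.diff(s.values), label=s.label
    )


def _fat_drop(line_profile: pd.DataFrame, fat_thickness: float) -> float:
    """Temperature drop across the fat segment of an annotated line profile.

    Endpoint temperatures are interpolated linearly at the segment
    boundaries (midpoints between the straddling samples).
    """
    tissue = line_profile["tissue"].to_numpy()
    fat_idx = np.nonzero(tissue == "fat")[0]
    if len(fat_idx) == 0:
        if fat_thickness > 0:
            raise ValueError(
                "line profile has no fat segment although fat_thickness > 0"
            )
        return 0.0
    T = line_profile["T_degC"].to_numpy()
    i0, i1 = fat_idx[0], fat_idx[-1]
    T_outer = T[i0] if i0 == 0 else 0.5 * (T[i0 - 1] + T[i0])
    T_inner = T[i1] if i1 == len(T) - 1 else 0.5 * (T[i1] + T[i1 + 1])
    return float(T_inner - T_outer)


def summarize(
    series_front: TemperatureSeries,
    series_contra: TemperatureSeries,
    line_profile: pd.DataFrame,
    geom: NeckGeometry,
) -> SummaryMetrics:
    """Scalar summaries of one protocol run.

    delta_TCL is the steady-state (t = 0) front-minus-contralateral skin
    difference; delta_TF the drop across the fat segment of the annotated
    line profile (0 by definition when there is no fat layer).
    """
    if len(series_front) != len(series_contra) or not np.allclose(
        series_front.times, series_contra.times
    ):
        raise ValueError("front and contralateral series must be time-aligned")
    return SummaryMetrics(
        start=float(series_front.values[0]),
        cooling_min=float(series_front.values.min()),
        end=float(series_front.values[-1]),
        delta_TF=_fat_drop(line_profile, geom.fat_thickness),
        delta_TCL=float(series_front.values[0] - series_contra.values[0]),
    )
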
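"""Synthetic thermogram sequences, matrix I/O and ROI series extraction.

Emulates what the infrared camera (FLIR SC620 class) delivers during the
reheating phase of the exam: up to 640x480 temperature frames, one every
15 s for 5 min (20 frames), with additive Gaussian sensor noise at the NETD
scale (default sd 0.04 degC) and a marked pixel in front of the nodule.

Rendering maps the simulated anterior skin-arc profile onto image columns
inside a horizontal band; the background is filled with the room-air
temperature.  Full radiometric rendering of a neck is deliberately out of
scope — the sequences exist to exercise the ROI series pipeline (11x11
window mean around the marked pixel), which is shared verbatim with series
extracted from real matrix exports.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolResult, TemperatureSeries

__all__ = [
    "CAMERA_RANGE",
    "Thermogram",
    "ThermogramSequence",
    "synthesize_thermogram_sequence",
    "window_mean",
    "patient_series",
    "read_thermogram_matrix",
    "write_thermogram_matrix",
    "write_sequence",
    "read_sequence",
]

#: Radiometric capture range of the camera, degC.
CAMERA_RANGE = (-40.0, 2000.0)

DEFAULT_FRAME_SHAPE = (480, 640)  # rows, cols
DEFAULT_NOISE_SD = 0.04
#: Height of the rendered skin band, pixels.
BAND_HEIGHT = 41


class ThermogramValidationError(ValueError):
    pass


@dataclass
class Thermogram:
    """One temperature frame (degC matrix) with an optional marked pixel."""

    values: np.ndarray
    timestamp: float = 0.0
    marked_point: tuple[int, int] | None = None  # (row, col)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ThermogramValidationError("thermogram must be a 2D matrix")
        lo, hi = CAMERA_RANGE
        if (self.values < lo).any() or (self.values > hi).any():
            raise ThermogramValidationError(
                f"temperatures outside the camera capture range "
                f"[{lo}, {hi}] degC"
            )
        if self.marked_point is not None:
            r, c = self.marked_point
            nr, nc = self.values.shape
            if not (0 <= r < nr and 0 <= c < nc):
                raise ThermogramValidationError("marked_point outside frame")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ThermogramSequence:
    frames: list[Thermogram]
    provenance: str = ""
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ThermogramValidationError("sequence has no frames")
        shape = self.frames[0].shape
        mark = self.frames[0].marked_point
        for f in self.frames:
            if f.shape != shape or f.marked_point != mark:
                raise ThermogramValidationError(
                    "all frames must share shape and marked_point"
                )
        times = [f.timestamp for f in self.frames]
        if len(times) > 1:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ThermogramValidationError(
                    "frames must be uniformly spaced in time"
                )

    def __len__(self) -> int:
        return len(self.frames)


def synthesize_thermogram_sequence(
    result: ProtocolResult,
    frame_shape: tuple[int, int] = DEFAULT_FRAME_SHAPE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> ThermogramSequence:
    """Render the reheating-phase samples as a camera-like sequence.

    One frame per post-junction reheating sample (20 under the default
    protocol).  The anterior skin profile is painted across a horizontal
    band (column c maps to arc s_mark + (c - c_mark) * pitch, anchored so
    the marked column sits exactly on the front-of-nodule arc); elsewhere
    the frame shows the room-air temperature.  Gaussian noise of sd
    ``noise_sd`` is added with the given integer seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if seed is not None and not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    fields = result.reheating_fields[1:]
    if not fields:
        raise ValueError("protocol result has no reheating samples")
    nr, nc = frame_shape
    geom = result.geometry
    s_front = result.probes.front_arc
    row_mark = nr // 2
    # pitch spans the full anterior arc across the frame width (~0.28 mm/px
    # at the native 640-column format)
    s_max = geom.gamma1_half_angle * geom.outer_radius
    pitch = 2.0 * s_max / (nc - 1)
    col_mark = nc // 2 + int(round(s_front / pitch))
    if not 0 <= col_mark < nc:
        raise ValueError("frame too narrow for the front-of-nodule column")
    cols = np.arange(nc)
    arcs = s_front + (cols - col_mark) * pitch
    visible = np.abs(arcs) <= s_max
    band_lo = max(0, row_mark - BAND_HEIGHT // 2)
    band_hi = min(nr, row_mark + BAND_HEIGHT // 2 + 1)

    rng = np.random.default_rng(seed)
    Tair = result.config.reheating.Tair
    frames = []
    pts = geom.point_at_arc(arcs[visible])
    for fld in fields:
        from . import fem

        skin = fem.evaluate_field(fld, pts)
        frame = np.full((nr, nc), Tair)
        frame[band_lo:band_hi, visible] = skin
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames.append(
            Thermogram(
                values=frame,
                timestamp=float(fld.time_tag),
                marked_point=(row_mark, col_mark),
            )
        )
    return ThermogramSequence(
        frames=frames,
        provenance=result.case.case_id,
        noise_sd=noise_sd,
        seed=seed,
    )


def window_mean(frame: Thermogram, p: tuple[int, int], size: int = 11) -> float:
    """Mean of the size x size pixel block centred at p (row, col).

    The window must lie fully inside the frame: silent truncation at the
    border would bias the series, so it is an error instead.
    """
    if size % 2 != 1 or size < 1:
        raise ValueError("window size must be an odd positive integer")
    r, c = p
    half = size // 2
    nr, nc = frame.shape
    if r - half < 0 or c - half < 0 or r + half >= nr or c + half >= nc:
        raise ValueError(
            f"{size}x{size} window at ({r}, {c}) crosses the frame border"
        )
    block = frame.values[r - half : r + half + 1, c - half : c + half + 1]
    return float(block.mean())


def patient_series(seq: ThermogramSequence, size: int = 11) -> TemperatureSeries:
    """ROI series: window mean at the marked pixel, one value per frame."""
    mark = seq.frames[0].marked_point
    if mark is None:
        raise ValueError("sequence has no marked_point")
    values = []
    for i, frame in enumerate(seq.frames):
        try:
            values.append(window_mean(frame, mark, size=size))
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    times = np.asarray([f.timestamp for f in seq.frames])
    return TemperatureSeries(
        times=times, values=np.asarray(values), label=seq.provenance
    )


# ---------------------------------------------------------------------------
# matrix I/O (camera CSV exports and their synthetic stand-ins)


def write_thermogram_matrix(frame: Thermogram, path) -> None:
    np.savetxt(path, frame.values, fmt="%.17g", delimiter=",")


def read_thermogram_matrix(path) -> Thermogram:
    """Parse a plain-text temperature matrix.

    Accepts comma or semicolon separators; with semicolons, a decimal comma
    is assumed and converted.  Ragged rows are a parse error; values outside
    the camera range a validation error.
    """
    text = pathlib.Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ThermogramValidationError(f"{path}: empty matrix file")
    if ";" in lines[0]:
        rows = [ln.replace(",", ".").split(";") for ln in lines]
    else:
        rows = [ln.split(",") for ln in lines]
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ThermogramValidationError(
                f"{path}: ragged row {i} ({len(row)} fields, expected {width})"
            )
    try:
        values = np.asarray([[float(v) for v in row] for row in rows])
    except ValueError as exc:
        raise ThermogramValidationError(f"{path}: non-numeric cell: {exc}") from exc
    return Thermogram(values=values)


def write_sequence(seq: ThermogramSequence, out_dir) -> None:
    """One CSV matrix per frame plus a JSON manifest."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(seq.frames):
        name = f"frame_{i:03d}.csv"
        write_thermogram_matrix(frame, out / name)
        names.append(name)
    manifest = {
        "frames": names,
        "timestamps": [f.timestamp for f in seq.frames],
        "marked_point": list(seq.frames[0].marked_point or ()),
        "noise_sd": seq.noise_sd,
        "seed": seq.seed,
        "provenance": seq.provenance,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_sequence(in_dir) -> ThermogramSequence:
    src = pathlib.Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    mark = tuple(manifest["marked_point"]) or None
    frames = []
    for name, ts in zip(manifest["frames"], manifest["timestamps"]):
        frame = read_thermogram_matrix(src / name)
        frames.append(
            Thermogram(values=frame.values, timestamp=ts, marked_point=mark)
        )
    return ThermogramSequence(
        frames=frames,
        provenance=manifest.get("provenance", ""),
        noise_sd=manifest.get("noise_sd", 0.0),
        seed=manifest.get("seed"),
    )
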
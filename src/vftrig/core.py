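"""Shared data containers: optical movies, scalar maps, pseudo-ECG records.

These are the objects that move between pipeline stages.  Movies are plain
float32 frame stacks with physical metadata; on disk they are multi-frame
TIFF files with a JSON sidecar.  ECG records are 2-column CSV plus a JSON
sidecar carrying the pacing-event log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class OpticalMovie:
    """A fluorescence (or transmembrane-voltage) frame stack.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_rows, n_cols)``, float.
    dx_mm
        Pixel pitch in millimetres.
    frame_interval_ms
        Time between consecutive frames in milliseconds.
    t0_ms
        Absolute time of the first frame.
    """

    frames: np.ndarray
    dx_mm: float
    frame_interval_ms: float
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie needs a (time, rows, cols) stack with >= 2 frames")
        if not (self.dx_mm > 0 and self.frame_interval_ms > 0):
            raise ValueError("dx_mm and frame_interval_ms must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_frames) * self.frame_interval_ms

    def frame_index(self, t_ms: float) -> int:
        return int(round((t_ms - self.t0_ms) / self.frame_interval_ms))

    def trace(self, row: int, col: int) -> np.ndarray:
        return self.frames[:, row, col]

    def save(self, path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        sidecar = {
            "dx_mm": float(self.dx_mm),
            "frame_interval_ms": float(self.frame_interval_ms),
            "t0_ms": float(self.t0_ms),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "OpticalMovie":
        path = Path(path)
        frames = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(frames=frames, **meta)


@dataclass
class ScalarMap:
    """Per-pixel 2D scalar map (AT, APD80, RT or gradient magnitude)."""

    values: np.ndarray
    valid: np.ndarray
    kind: str  # "AT" | "APD80" | "RT" | "gradient"
    dx_mm: float
    beat_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape or self.values.ndim != 2:
            raise ValueError("values and valid must be matching 2D arrays")

    @property
    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def save(self, path) -> None:
        path = Path(path)
        out = self.values.astype(np.float32).copy()
        out[~self.valid] = np.nan
        tifffile.imwrite(path, out)

    def to_csv(self, path) -> None:
        rows, cols = np.indices(self.values.shape)
        import pandas as pd

        pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "value": self.values.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        ).to_csv(path, index=False)


@dataclass
class EcgRecord:
    """Uniformly sampled pseudo-ECG with its pacing-event log.

    ``pacing_times_ms`` holds regular (S1) pacing stimuli only; programmed
    extrastimuli, if any, go in ``extra_stim_times_ms``.  Spontaneous tissue
    ectopy produced by the generator is *not* a pacing event.
    """

    time_ms: np.ndarray
    amplitude: np.ndarray
    pacing_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    extra_stim_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.pacing_times_ms = np.sort(np.asarray(self.pacing_times_ms, dtype=float))
        self.extra_stim_times_ms = np.sort(np.asarray(self.extra_stim_times_ms, dtype=float))
        if self.time_ms.shape != self.amplitude.shape:
            raise ValueError("time and amplitude must match")
        if len(self.time_ms) >= 2:
            dt = np.diff(self.time_ms)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-6):
                raise ValueError("ECG must be uniformly sampled")

    @property
    def sampling_interval_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def duration_ms(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0])

    def save(self, path) -> None:
        path = Path(path)
        import pandas as pd

        pd.DataFrame({"time_ms": self.time_ms, "amplitude": self.amplitude}).to_csv(
            path, index=False
        )
        sidecar = {
            "pacing_times_ms": self.pacing_times_ms.tolist(),
            "extra_stim_times_ms": self.extra_stim_times_ms.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "EcgRecord":
        path = Path(path)
        import pandas as pd

        df = pd.read_csv(path)
        meta = {}
        side = path.with_suffix(".json")
        if side.exists():
            meta = json.loads(side.read_text())
        return cls(
            time_ms=df["time_ms"].to_numpy(),
            amplitude=df["amplitude"].to_numpy(),
            pacing_times_ms=np.asarray(meta.get("pacing_times_ms", [])),
            extra_stim_times_ms=np.asarray(meta.get("extra_stim_times_ms", [])),
        )
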
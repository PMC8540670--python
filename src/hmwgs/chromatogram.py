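"""Uniform-grid chromatogram container with CSV round-trip."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np


class ChromatogramFormatError(ValueError):
    """Malformed chromatogram data (grid or file format)."""


@dataclasses.dataclass
class Chromatogram:
    """A time/intensity trace on a strictly increasing uniform grid.

    Time is in minutes, intensity in arbitrary detector units (the method
    monitors absorbance at 210 nm but no absolute scale is assumed).
    """

    time: np.ndarray
    intensity: np.ndarray
    line_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ChromatogramFormatError(
                "time and intensity must be 1-D arrays of equal length"
            )
        if len(self.time) < 2:
            raise ChromatogramFormatError("trace needs at least two samples")
        steps = np.diff(self.time)
        if not np.all(steps > 0):
            raise ChromatogramFormatError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        steps = np.diff(self.time)
        return bool(np.allclose(steps, steps[0], rtol=rtol, atol=0.0))

    def require_uniform(self) -> None:
        if not self.is_uniform():
            raise ChromatogramFormatError("non-uniform time grid")

    # -- I/O ----------------------------------------------------------

    def to_csv(self, path: str | Path, header_comments: list[str] | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            fh.write("time_min,intensity_au\n")
            for t, y in zip(self.time, self.intensity):
                fh.write(f"{t:.6f},{y:.6f}\n")

    @classmethod
    def from_csv(cls, path: str | Path, line_id: str | None = None) -> "Chromatogram":
        path = Path(path)
        times, values = [], []
        with open(path) as fh:
            header = None
            for raw in fh:
                raw = raw.strip()
                if not raw or raw.startswith("#"):
                    continue
                if header is None:
                    header = [c.strip() for c in raw.split(",")]
                    if header[:2] != ["time_min", "intensity_au"]:
                        raise ChromatogramFormatError(
                            f"{path}: expected header 'time_min,intensity_au'"
                        )
                    continue
                parts = raw.split(",")
                if len(parts) < 2:
                    raise ChromatogramFormatError(f"{path}: bad row {raw!r}")
                try:
                    times.append(float(parts[0]))
                    values.append(float(parts[1]))
                except ValueError as exc:
                    raise ChromatogramFormatError(f"{path}: bad row {raw!r}") from exc
        if header is None:
            raise ChromatogramFormatError(f"{path}: empty file")
        return cls(np.array(times), np.array(values),
                   line_id=line_id if line_id is not None else path.stem)
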
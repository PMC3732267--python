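"""Frequency-domain spectrum container and its on-disk text form.

A spectrum is a strictly monotone-descending ppm axis (the NMR plotting
convention) with one intensity value per point plus free-form metadata.
Spectra read from files with an ascending axis are flipped on load so all
downstream code can assume the descending convention.

On disk a spectrum is a two-column delimited text file; metadata travels in
``# key: value`` header lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Spectrum:
    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least two points")
        steps = np.diff(self.ppm)
        if np.all(steps > 0):  # ascending input: normalize to NMR convention
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(steps < 0):
            raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    # -- geometry -------------------------------------------------------

    @property
    def step(self) -> float:
        """Median axis spacing in ppm (positive)."""
        return float(np.median(-np.diff(self.ppm)))

    def window(self, lo: float, hi: float) -> slice:
        """Index slice covering ppm values in [lo, hi] (axis is descending)."""
        lo, hi = min(lo, hi), max(lo, hi)
        mask = (self.ppm >= lo) & (self.ppm <= hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"window [{lo}, {hi}] ppm outside the axis")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def crop(self, lo: float, hi: float) -> "Spectrum":
        sl = self.window(lo, hi)
        return Spectrum(self.ppm[sl].copy(), self.intensity[sl].copy(), dict(self.meta))

    def shifted(self, delta: float) -> "Spectrum":
        """Translate the axis by ``delta`` ppm (positive moves peaks upfield)."""
        return Spectrum(self.ppm + delta, self.intensity.copy(), dict(self.meta))

    # -- i/o ------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        path = Path(path)
        lines = ["# uremiq spectrum v1"]
        for key in sorted(self.meta):
            lines.append(f"# {key}: {self.meta[key]}")
        lines.append("# columns: ppm\tintensity")
        for p, y in zip(self.ppm, self.intensity):
            lines.append(f"{p:.6f}\t{y:.8e}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum":
        path = Path(path)
        meta: dict = {}
        ppm: list[float] = []
        intensity: list[float] = []
        with path.open() as fh:
            for raw in fh:
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if ":" in body:
                        key, _, value = body.partition(":")
                        meta[key.strip()] = value.strip()
                    continue
                cols = line.replace(",", "\t").split()
                if len(cols) < 2:
                    raise ValueError(f"{path}: malformed data line {line!r}")
                ppm.append(float(cols[0]))
                intensity.append(float(cols[1]))
        if not ppm:
            raise ValueError(f"{path}: no data points")
        return cls(np.array(ppm), np.array(intensity), meta)
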
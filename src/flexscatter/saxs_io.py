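"""Reading, writing and combining solution-scattering curves.

The on-disk format is the ubiquitous 3-column ASCII ``.dat`` file: whitespace
separated columns ``q  I(q)  [sigma]`` with ``q`` in inverse Angstrom
(q = 4*pi*sin(theta)/lambda), arbitrary intensity units, and optional 1-sigma
uncertainties.  Lines starting with ``#`` and non-numeric header/footer lines
are ignored on input.

SEC-SAXS elutions are handled as a :class:`FrameSeries` -- an ordered list of
curves sharing one q grid -- which can be averaged over arbitrary frame
subsets (e.g. the frames spanning an elution peak).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    ArgumentError,
    FormatError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "ScatteringCurve",
    "FrameSeries",
    "read_dat",
    "write_dat",
    "truncate",
    "average_frames",
    "load_frame_series",
]


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1-D scattering curve I(q) with optional uncertainties.

    Parameters
    ----------
    q : array
        Momentum transfer in 1/Angstrom; strictly increasing, all positive.
    I : array
        Intensity, arbitrary units.
    sigma : array or None
        1-sigma uncertainty of ``I`` (same units); ``None`` when unknown.
    label : str
        Free-text provenance label.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        I = np.asarray(self.I, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", I)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
        if q.ndim != 1 or I.shape != q.shape:
            raise ValidationError("q and I must be 1-D arrays of equal length")
        if self.sigma is not None and self.sigma.shape != q.shape:
            raise ValidationError("sigma must match q in length")
        if len(q) < 3:
            raise InsufficientDataError(
                f"scattering curve needs >= 3 points, got {len(q)}"
            )
        if np.any(q <= 0):
            raise ValidationError("all q must be positive")
        if np.any(np.diff(q) <= 0):
            raise ValidationError("q must be strictly increasing")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise ValidationError("all sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    def with_label(self, label: str) -> "ScatteringCurve":
        return replace(self, label=label)


@dataclass(frozen=True)
class FrameSeries:
    """An ordered series of curves on a common q grid (a SEC-SAXS elution)."""

    frames: tuple
    frame_index: tuple

    def __init__(self, frames: Sequence[ScatteringCurve],
                 frame_index: Sequence[int] | None = None):
        frames = tuple(frames)
        if not frames:
            raise ArgumentError("FrameSeries needs at least one frame")
        if frame_index is None:
            frame_index = tuple(range(len(frames)))
        else:
            frame_index = tuple(int(i) for i in frame_index)
        if len(frame_index) != len(frames):
            raise ValidationError("frame_index must match number of frames")
        q0 = frames[0].q
        for f in frames[1:]:
            if len(f.q) != len(q0) or not np.allclose(f.q, q0, rtol=1e-9, atol=0):
                raise ValidationError("all frames must share an identical q grid")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_index", frame_index)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ScatteringCurve:
        return self.frames[i]

    @property
    def q(self) -> np.ndarray:
        return self.frames[0].q


def read_dat(path: str | os.PathLike) -> ScatteringCurve:
    """Read a 2- or 3-column ASCII scattering file.

    ``#``-prefixed and non-numeric header/footer lines are skipped.  The
    sigma column is populated only if every data line has a third column.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            try:
                vals = [float(t) for t in toks]
            except ValueError:
                continue  # header/footer text
            if len(vals) >= 2:
                rows.append(vals[:3])
    if not rows:
        raise FormatError(f"no numeric data rows found in {path}")
    if len(rows) < 3:
        raise InsufficientDataError(
            f"{path} has {len(rows)} data points; >= 3 required"
        )
    ncol = min(len(r) for r in rows)
    q = np.array([r[0] for r in rows])
    I = np.array([r[1] for r in rows])
    sigma = np.array([r[2] for r in rows]) if ncol >= 3 else None
    return ScatteringCurve(q=q, I=I, sigma=sigma, label=path.name)


def write_dat(curve: ScatteringCurve, path: str | os.PathLike) -> None:
    """Write a curve as ``# q(1/A) I sigma`` ASCII with 8 significant digits."""
    with open(path, "w") as fh:
        fh.write("# q(1/A) I sigma\n")
        if curve.has_sigma:
            for q, I, s in zip(curve.q, curve.I, curve.sigma):
                fh.write(f"{q:.8e} {I:.8e} {s:.8e}\n")
        else:
            for q, I in zip(curve.q, curve.I):
                fh.write(f"{q:.8e} {I:.8e}\n")


def truncate(curve: ScatteringCurve, qmin: float, qmax: float) -> ScatteringCurve:
    """Return the sub-curve with ``qmin <= q <= qmax``.

    Idempotent; raises if the bounds are inverted or select fewer than
    3 points.
    """
    if qmin >= qmax:
        raise ArgumentError(f"qmin ({qmin}) must be < qmax ({qmax})")
    mask = (curve.q >= qmin) & (curve.q <= qmax)
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"truncation to [{qmin}, {qmax}] leaves {n} points (< 3)"
        )
    return ScatteringCurve(
        q=curve.q[mask],
        I=curve.I[mask],
        sigma=curve.sigma[mask] if curve.has_sigma else None,
        label=curve.label,
    )


def average_frames(series: FrameSeries,
                   indices: Iterable[int] | None = None) -> ScatteringCurve:
    """Pointwise unweighted mean of the selected frames.

    Intensities are averaged without weights; uncertainties are propagated
    as ``sqrt(sum sigma_i^2) / n``, i.e. the standard error of the mean of
    independent measurements.  With a single frame the curve is returned
    unchanged.  The result is independent of the order of ``indices``.
    """
    if indices is None:
        idx = list(range(len(series)))
    else:
        idx = sorted(set(int(i) for i in indices))
    if not idx:
        raise ArgumentError("empty frame index set")
    for i in idx:
        if i < 0 or i >= len(series):
            raise ArgumentError(f"frame index {i} out of range 0..{len(series)-1}")
    sel = [series.frames[i] for i in idx]
    n = len(sel)
    I = np.mean([f.I for f in sel], axis=0)
    if all(f.has_sigma for f in sel):
        sigma = np.sqrt(np.sum([f.sigma**2 for f in sel], axis=0)) / n
    else:
        sigma = None
    return ScatteringCurve(q=series.q, I=I, sigma=sigma,
                           label=f"average of {n} frames")


def load_frame_series(paths: Sequence[str | os.PathLike]) -> FrameSeries:
    """Read an ordered list of .dat files into a :class:`FrameSeries`."""
    frames = [read_dat(p) for p in paths]
    return FrameSeries(frames)
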
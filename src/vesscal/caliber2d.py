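"""2D angiography preprocessing and FWHM vessel-diameter measurement.

A contrast sequence is background-corrected by subtracting each frame from
the temporal mean (digital subtraction: static anatomy cancels, iodinated --
darker -- vessels become positive enhancement), smoothed with a truncated
temporal moving average, and the most intensely filled frame is selected.
Vessel caliber is measured on a line across the vessel with the
full-width-at-half-maximum rule, averaged over five parallel lines.

FWHM contract: profiles are sampled by bilinear interpolation at <= 0.25 px
steps; the baseline is the lower of the two outer-10% tail means; the width
is the distance between the two half-level crossings nearest the peak, each
located by linear interpolation between samples.  Lines whose profile never
crosses the half level on both sides are dropped (and counted); the reported
diameter is the mean of the remaining per-line widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as _ndi

from .phantom import AngioSequence

__all__ = [
    "LineSelection",
    "DiameterMeasurement",
    "background_correct",
    "temporal_moving_average",
    "select_peak_frame",
    "fwhm_diameter",
]


@dataclass(frozen=True)
class LineSelection:
    """A measurement line across a vessel, in image pixel coordinates.

    Endpoints are ``(x, y)`` = (column, row).  ``n_parallel`` lines offset
    perpendicular to the line by multiples of ``spacing`` px (symmetric about
    the central line) are measured and averaged.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    n_parallel: int = 5
    spacing: float = 1.0
    label: str = ""

    def __post_init__(self):
        if self.length < 3.0:
            raise ValueError("line must be at least 3 px long")
        if self.n_parallel < 1 or self.n_parallel % 2 == 0:
            raise ValueError("n_parallel must be an odd integer >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def length(self) -> float:
        return math.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1])

    def unit(self) -> tuple[float, float]:
        l = self.length
        return ((self.p1[0] - self.p0[0]) / l, (self.p1[1] - self.p0[1]) / l)

    def normal(self) -> tuple[float, float]:
        ux, uy = self.unit()
        return (-uy, ux)

    def shifted(self, dx: float, dy: float) -> "LineSelection":
        return replace(
            self,
            p0=(self.p0[0] + dx, self.p0[1] + dy),
            p1=(self.p1[0] + dx, self.p1[1] + dy),
        )


@dataclass
class DiameterMeasurement:
    """One averaged FWHM caliber reading."""

    line: LineSelection
    widths: list[float]          # valid per-line FWHM values, px
    d_fwhm: float                # mean of widths, px
    d_mm: float | None = None    # d_fwhm * pixel size, if given
    n_dropped: int = 0           # parallel lines without two half crossings


def _as_frames(seq) -> np.ndarray:
    return seq.frames if isinstance(seq, AngioSequence) else np.asarray(seq)


def background_correct(seq: AngioSequence) -> AngioSequence:
    """Subtract each frame from the temporal mean of the whole sequence.

    Static structures cancel to ~0 and iodinated (darker) vessels turn into
    positive enhancement, which is the polarity the FWHM measure expects.
    """
    frames = _as_frames(seq)
    if frames.shape[0] < 2:
        raise ValueError("background correction needs at least 2 frames")
    mean = frames.mean(axis=0)
    corrected = mean[None] - frames
    return replace(seq, frames=corrected.astype(frames.dtype))


def temporal_moving_average(seq: AngioSequence, halfwidth: int = 5) -> AngioSequence:
    """Replace frame t by the mean of frames [t - halfwidth, t + halfwidth],
    truncating the window at the sequence edges."""
    frames = _as_frames(seq)
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    n = frames.shape[0]
    if n < 2 * halfwidth + 1:
        raise ValueError(
            f"need at least {2 * halfwidth + 1} frames for halfwidth {halfwidth}"
        )
    if halfwidth == 0:
        return replace(seq, frames=frames.copy())
    csum = np.cumsum(frames.astype(np.float64), axis=0)
    csum = np.concatenate([np.zeros_like(csum[:1]), csum], axis=0)
    out = np.empty_like(frames, dtype=np.float64)
    for t in range(n):
        lo = max(0, t - halfwidth)
        hi = min(n, t + halfwidth + 1)
        out[t] = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(seq, frames=out.astype(frames.dtype))


def select_peak_frame(seq: AngioSequence, roi: np.ndarray | None = None) -> int:
    """Index of the frame with the largest total enhancement (within an
    optional boolean ROI); ties resolve to the earliest frame."""
    frames = _as_frames(seq)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != frames.shape[1:]:
            raise ValueError("roi shape must match the frame shape")
        totals = frames[:, roi].sum(axis=1)
    else:
        totals = frames.reshape(frames.shape[0], -1).sum(axis=1)
    return int(np.argmax(totals))


def sample_profile(image: np.ndarray, p0, p1, step: float = 0.25):
    """Bilinear profile samples along p0->p1 (inclusive) and their positions."""
    length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = max(2, int(math.ceil(length / step)) + 1)
    s = np.linspace(0.0, length, n)
    xs = p0[0] + (p1[0] - p0[0]) * (s / length)
    ys = p0[1] + (p1[1] - p0[1]) * (s / length)
    vals = _ndi.map_coordinates(
        np.asarray(image, dtype=np.float64), np.stack([ys, xs]), order=1,
        mode="nearest",
    )
    return s, vals


def _fwhm_of_profile(s: np.ndarray, v: np.ndarray) -> float | None:
    """FWHM of a single-peak profile; None when a half crossing is missing.

    Raises ``ValueError`` when the peak sits at the profile edge (the line is
    too short to contain the vessel).
    """
    n = len(v)
    if v.max() - v.min() <= 0:
        return None  # featureless profile: no measurable peak
    tail = max(1, int(0.1 * n))
    baseline = min(float(v[:tail].mean()), float(v[-tail:].mean()))
    ipeak = int(np.argmax(v))
    peak = float(v[ipeak])
    if ipeak == 0 or ipeak == n - 1:
        raise ValueError("peak at profile edge; line selection is too short")
    if peak <= baseline:
        return None
    half = baseline + (peak - baseline) / 2.0

    def cross(lo_side: bool) -> float | None:
        rng = range(ipeak, 0, -1) if lo_side else range(ipeak, n - 1)
        for i in rng:
            a, b = (i - 1, i) if lo_side else (i, i + 1)
            va, vb = v[a], v[b]
            lo, hi = (va, vb) if lo_side else (vb, va)
            if lo < half <= hi:
                # linear interpolation between samples a and b
                frac = (half - va) / (vb - va)
                return float(s[a] + frac * (s[b] - s[a]))
        return None

    left = cross(True)
    right = cross(False)
    if left is None or right is None:
        return None
    return right - left


def fwhm_diameter(
    image: np.ndarray,
    line: LineSelection,
    pixel_size: float | None = None,
    step: float = 0.25,
) -> DiameterMeasurement:
    """FWHM vessel diameter on an enhancement image, averaged over the
    parallel lines of the selection.

    The image must have bright vessels on a darker background (the output of
    :func:`background_correct`, or a maximum intensity projection of a
    bright-vessel volume).
    """
    if step > 0.25:
        raise ValueError("profile sampling step must be <= 0.25 px")
    nx_, ny_ = line.normal()
    k = (line.n_parallel - 1) // 2
    widths: list[float] = []
    dropped = 0
    for i in range(-k, k + 1):
        shifted = line.shifted(i * line.spacing * nx_, i * line.spacing * ny_)
        s, v = sample_profile(image, shifted.p0, shifted.p1, step=step)
        w = _fwhm_of_profile(s, v)
        if w is None:
            dropped += 1
        else:
            widths.append(w)
    if not widths:
        raise ValueError("no parallel line produced two half-level crossings")
    d = float(np.mean(widths))
    return DiameterMeasurement(
        line=line, widths=widths, d_fwhm=d,
        d_mm=(d * pixel_size if pixel_size is not None else None),
        n_dropped=dropped,
    )
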
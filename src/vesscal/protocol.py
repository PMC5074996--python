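"""Imaging-geometry and radiation-dose arithmetic for protocol planning.

Small, exact helpers: effective voxel size from the cone-beam magnification
geometry, cumulative air-kerma dose over a gated CT acquisition, that dose as
a fraction of the murine LD50/30, and ventilator respiratory rate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ImagingGeometry",
    "DoseProtocol",
    "effective_voxel_size",
    "total_dose",
    "dose_fraction_of_ld50",
    "respiratory_rate",
    "summarize",
]


@dataclass(frozen=True)
class ImagingGeometry:
    """Source/detector geometry setting the reconstruction magnification."""

    detector_pixel: float       # mm
    source_to_isocenter: float  # mm
    source_to_detector: float   # mm

    def __post_init__(self):
        if not self.detector_pixel > 0:
            raise ValueError("detector_pixel must be positive")
        if not 0 < self.source_to_isocenter < self.source_to_detector:
            raise ValueError("need 0 < source_to_isocenter < source_to_detector")


@dataclass(frozen=True)
class DoseProtocol:
    """Exposure bookkeeping for one gated CT scan."""

    n_projections: int
    exposure: float      # s per projection
    kerma_rate: float    # mGy/s
    ld50: float = 7.0    # Gy; LD50/30 for BALB/c mice

    def __post_init__(self):
        if min(self.n_projections, self.exposure, self.kerma_rate, self.ld50) <= 0:
            raise ValueError("all dose-protocol fields must be positive")


def effective_voxel_size(g: ImagingGeometry) -> float:
    """Isotropic reconstruction voxel size in mm: detector pixel demagnified
    by the source-to-isocenter / source-to-detector ratio."""
    return g.detector_pixel * g.source_to_isocenter / g.source_to_detector


def total_dose(p: DoseProtocol) -> float:
    """Cumulative air-kerma dose in mGy over all projections."""
    return p.n_projections * p.exposure * p.kerma_rate


def dose_fraction_of_ld50(dose_mgy: float, ld50_gy: float) -> float:
    """Dose as a percentage of the LD50/30, reported to one decimal."""
    if not ld50_gy > 0:
        raise ValueError("ld50 must be positive")
    return round(100.0 * dose_mgy / (1000.0 * ld50_gy), 1)


def respiratory_rate(insp_ms: float, exp_ms: float) -> float:
    """Breaths per minute from inspiratory + expiratory durations in ms."""
    if not insp_ms + exp_ms > 0:
        raise ValueError("breath duration must be positive")
    return 60000.0 / (insp_ms + exp_ms)


def summarize(geometry: ImagingGeometry, dose: DoseProtocol,
              insp_ms: float | None = None, exp_ms: float | None = None) -> dict:
    """Protocol summary with presentation rounding (voxel size to 3
    significant figures, dose percentage to one decimal); raw values kept."""
    vox = effective_voxel_size(geometry)
    d = total_dose(dose)
    out = {
        "voxel_size_mm": float(f"{vox:.3g}"),
        "voxel_size_mm_raw": vox,
        "total_dose_mgy": d,
        "dose_percent_ld50": dose_fraction_of_ld50(d, dose.ld50),
    }
    if insp_ms is not None and exp_ms is not None:
        out["respiratory_rate_bpm"] = respiratory_rate(insp_ms, exp_ms)
    return out
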
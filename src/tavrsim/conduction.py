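"""Conduction-disturbance scoring over the membranous-septum region of interest.

The membranous septum (MS) is the anatomical surrogate for the
atrioventricular bundle and proximal left bundle branch. It is located at
three landmarks (noncoronary cusp, mid-course, right coronary cusp); the
region of interest (ROI) spans circumferentially from the NCC landmark,
through the mid-course, to 25 degrees laterally beyond the RCC landmark
(away from the NCC, following the course of the bundle), and axially 15 mm
caudal from the aortic annulus (z in [-15, 0] mm).

Two scores are computed on the deployed contact-pressure field:

* CPI (contact pressure index): the percentage of ROI *area* subject to
  contact pressure (area-weighted, with a numerical-zero threshold);
* CPMax: the maximum element contact pressure (MPa) within the ROI.

Implantation depth is the axial distance from the annulus plane down to the
frame inflow edge, read at the noncoronary and left coronary cusp angles.
Risk flags use closed (>=) comparisons at CPI 20%, CPMax 0.40 MPa and depth
5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .anatomy import AorticRootModel, angle_in_span
from .deployment import ContactPressureField, FrameState
from .errors import ConfigError, EmptyRegionError, InvalidParameterError

CPI_CUTOFF = 20.0  # %
CPMAX_CUTOFF = 0.40  # MPa
DEPTH_CUTOFF = 5.0  # mm
DEFAULT_CONTACT_THRESHOLD = 1e-6  # MPa, numerical zero


@dataclass
class ConductionROI:
    """Element set standing in for the AV bundle / proximal LBB territory."""

    mask: np.ndarray  # (n_z - 1, n_circ) element membership
    total_area: float  # mm^2
    theta_span: Tuple[float, float]  # degrees
    z_span: Tuple[float, float]  # mm
    ms_landmarks: Dict[str, Tuple[float, float]]


def build_roi(
    model: AorticRootModel,
    lateral_extension_deg: float = 25.0,
    caudal_extent_mm: float = 15.0,
    clip_to_ms_depth: bool = False,
) -> ConductionROI:
    """Build the conduction ROI from the model's MS landmarks.

    ``clip_to_ms_depth`` optionally bounds the ROI inferiorly by the local MS
    depth instead of the fixed caudal extent (off by default: the caudal
    boundary is defined by the annulus and the 15 mm extension; the MS depths
    remain available as covariates).
    """
    if not model.ms_landmarks:
        raise ConfigError("model carries no membranous-septum landmarks")
    if lateral_extension_deg < 0 or caudal_extent_mm <= 0:
        raise InvalidParameterError("ROI extensions must be positive")
    th_ncc, _ = model.ms_landmarks["NCC"]
    th_rcc, _ = model.ms_landmarks["RCC"]
    theta_start = th_ncc
    theta_end = (th_rcc + lateral_extension_deg) % 360.0
    z_lo, z_hi = -caudal_extent_mm, 0.0

    in_theta = angle_in_span(model.element_theta, theta_start, theta_end)
    in_z = (model.element_z >= z_lo) & (model.element_z <= z_hi)
    if clip_to_ms_depth:
        depths = _interpolated_ms_depth(model, model.element_theta)
        in_z = in_z & (model.element_z >= -depths)
    mask = in_theta & in_z
    if not mask.any():
        raise EmptyRegionError("conduction ROI contains no elements")
    total = float(model.element_area[mask].sum())
    return ConductionROI(
        mask=mask,
        total_area=total,
        theta_span=(theta_start, theta_end),
        z_span=(z_lo, z_hi),
        ms_landmarks=dict(model.ms_landmarks),
    )


def _interpolated_ms_depth(model: AorticRootModel, theta) -> np.ndarray:
    angles = np.array([model.ms_landmarks[k][0] for k in ("NCC", "mid", "RCC")])
    depths = np.array([model.ms_landmarks[k][1] for k in ("NCC", "mid", "RCC")])
    order = np.argsort(angles)
    return np.interp(
        np.asarray(theta, float), angles[order], depths[order],
        left=depths[order][0], right=depths[order][-1],
    )


def compute_cpi(
    field: ContactPressureField,
    roi: ConductionROI,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> float:
    """Percentage of ROI area under contact pressure (area-weighted)."""
    _check_shapes(field, roi)
    areas = field.element_area[roi.mask]
    total = areas.sum()
    if total <= 0:
        raise EmptyRegionError("ROI has zero area")
    loaded = field.pressure[roi.mask] > contact_threshold
    return float(100.0 * areas[loaded].sum() / total)


def compute_cpmax(field: ContactPressureField, roi: ConductionROI) -> float:
    """Maximum element contact pressure (MPa) over the ROI; 0 without contact."""
    _check_shapes(field, roi)
    if not roi.mask.any():
        raise EmptyRegionError("ROI contains no elements")
    return float(field.pressure[roi.mask].max(initial=0.0))


def _check_shapes(field: ContactPressureField, roi: ConductionROI) -> None:
    if field.pressure.shape != roi.mask.shape:
        raise InvalidParameterError(
            "pressure field and ROI were built on different meshes"
        )


def measure_depth(
    frame: FrameState, model: AorticRootModel
) -> Tuple[float, float, float, bool]:
    """Implantation depth (mm) at the NCC and LCC, plus their mean.

    Depth is the axial distance from the annulus plane (z = 0) down to the
    frame inflow edge at the cusp angle. The final element is a warning flag
    set when the frame sits entirely above the annulus (depths clipped to 0).
    """
    edge_z = frame.inflow_edge_z()
    depth = max(-edge_z, 0.0)
    warn = edge_z > 0.0
    depth_ncc = depth_lcc = depth
    return depth_ncc, depth_lcc, (depth_ncc + depth_lcc) / 2.0, warn


@dataclass
class ConductionMetrics:
    """CPI / CPMax / depth scores with the risk flags at the standard cutoffs."""

    cpi: float  # %
    cpmax: float  # MPa
    depth_ncc: float  # mm
    depth_lcc: float  # mm
    depth_mean: float  # mm
    cpi_ge_20: bool
    cpmax_ge_040: bool
    depth_ge_5: bool
    depth_warning: bool = False

    def __post_init__(self):
        if not (0.0 <= self.cpi <= 100.0):
            raise InvalidParameterError(f"CPI out of [0, 100]: {self.cpi}")
        if self.cpmax < 0:
            raise InvalidParameterError(f"CPMax must be >= 0: {self.cpmax}")

    def to_dict(self) -> Dict[str, float]:
        return {
            "cpi": self.cpi,
            "cpmax": self.cpmax,
            "depth_ncc": self.depth_ncc,
            "depth_lcc": self.depth_lcc,
            "depth_mean": self.depth_mean,
            "cpi_ge_20": bool(self.cpi_ge_20),
            "cpmax_ge_040": bool(self.cpmax_ge_040),
            "depth_ge_5": bool(self.depth_ge_5),
        }


def compute_metrics(
    field: ContactPressureField,
    roi: ConductionROI,
    frame: FrameState,
    model: AorticRootModel,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> ConductionMetrics:
    """Assemble the full score set for one deployed case."""
    cpi = compute_cpi(field, roi, contact_threshold)
    cpmax = compute_cpmax(field, roi)
    d_ncc, d_lcc, d_mean, warn = measure_depth(frame, model)
    return ConductionMetrics(
        cpi=cpi,
        cpmax=cpmax,
        depth_ncc=d_ncc,
        depth_lcc=d_lcc,
        depth_mean=d_mean,
        cpi_ge_20=cpi >= CPI_CUTOFF,
        cpmax_ge_040=cpmax >= CPMAX_CUTOFF,
        depth_ge_5=d_mean >= DEPTH_CUTOFF,
        depth_warning=warn,
    )
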
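"""Parametric synthetic aortic-root anatomy.

The aortic root is represented as a structured surface of revolution: a grid of
nodes over circumferential angle theta (degrees) and axial coordinate z (mm),
with one radius per node. The annulus plane sits at z = 0; the ventricular
(caudal) side is z < 0. Cusp nadirs default to theta = 0/120/240 degrees for
the non-, right- and left-coronary cusps. Axial radius interpolation between
the five standard measurement levels (LVOT, annulus, sinus of Valsalva,
sinotubular junction, ascending aorta) is monotone-cubic, so the perimeter
measured on the generated mesh recovers the requested level diameters.

Wall mechanics are reduced to a per-node radial stiffness (N/mm):

* a thin-shell hoop term ``E_wall * t / r^2`` per unit area (pressure per unit
  radial displacement of a cylindrical shell) times the node's tributary area;
* a distributed foundation term standing in for the surrounding cardiac
  structures (the "spring at each node" idealization);
* an extra septal-support term below the annulus, where the outflow tract is
  muscular rather than thin aortic wall;
* a leaflet band between the annulus and the sinus level;
* calcium, deposited as contiguous patches whose volume matches the request,
  adds a stiffer, elastic--perfectly-plastic contribution that yields at the
  calcium yield stress.

All stiffness constants are *distributed* (per area / per volume) so that the
contact pressures extracted downstream are independent of mesh resolution.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import CapacityError, InvalidParameterError

CUSPS = ("NCC", "RCC", "LCC")
REGIONS = ("leaflet", "upper_leaflet", "device_landing_zone", "lvot")

#: Cohort anatomy distributions (mean, SD) used by :func:`sample_root_params`.
TABLE1_ANATOMY: Dict[str, Tuple[float, float]] = {
    "lvot_diameter": (25.4, 3.1),
    "annulus_diameter": (25.1, 2.5),
    "sinus_diameter": (34.3, 4.0),
    "stj_diameter": (28.9, 3.5),
    "ascending_diameter": (32.1, 3.2),
    "ms_depth_ncc": (5.1, 3.0),
    "ms_depth_mid": (3.5, 2.3),
    "ms_depth_rcc": (1.7, 2.2),
}

#: Per-(region, cusp) calcium volume distributions, mm^3 (mean, SD).
TABLE1_CALCIUM: Dict[Tuple[str, str], Tuple[float, float]] = {
    ("leaflet", "NCC"): (172.1, 198.4),
    ("leaflet", "RCC"): (80.2, 95.4),
    ("leaflet", "LCC"): (91.5, 99.7),
    ("upper_leaflet", "NCC"): (164.1, 188.8),
    ("upper_leaflet", "RCC"): (78.2, 93.3),
    ("upper_leaflet", "LCC"): (82.8, 91.0),
    ("device_landing_zone", "NCC"): (10.0, 25.3),
    ("device_landing_zone", "RCC"): (1.7, 4.9),
    ("device_landing_zone", "LCC"): (11.8, 23.3),
    ("lvot", "NCC"): (4.2, 14.7),
    ("lvot", "RCC"): (0.1, 1.1),
    ("lvot", "LCC"): (12.5, 29.6),
}


@dataclass(frozen=True)
class MaterialParams:
    """Linear-elastic material: modulus E (MPa), Poisson ratio, optional yield (MPa)."""

    e: float
    nu: float
    yield_stress: Optional[float] = None

    def __post_init__(self):
        if self.e <= 0:
            raise InvalidParameterError(f"elastic modulus must be > 0, got {self.e}")
        if not (0.0 <= self.nu < 0.5):
            raise InvalidParameterError(f"Poisson ratio must be in [0, 0.5), got {self.nu}")
        if self.yield_stress is not None and self.yield_stress <= 0:
            raise InvalidParameterError("yield stress must be > 0 when given")


WALL_MATERIAL = MaterialParams(e=2.0, nu=0.45)
LEAFLET_MATERIAL = MaterialParams(e=0.6, nu=0.3)
CALCIUM_MATERIAL = MaterialParams(e=4.0, nu=0.3, yield_stress=0.6)


def _default_calcium_volumes() -> Dict[Tuple[str, str], float]:
    return {key: mean for key, (mean, _sd) in TABLE1_CALCIUM.items()}


@dataclass
class RootParams:
    """Parametric description of one patient's aortic root.

    Diameters are perimeter-derived equivalents (mm); ``axial_heights`` gives
    the axial position (mm, annulus = 0) of the five diameter levels in the
    order LVOT, annulus, sinus, STJ, ascending aorta. Membranous-septum (MS)
    depths are measured at the three landmarks; ``ms_angles`` locates those
    landmarks circumferentially (degrees).
    """

    lvot_diameter: float = 25.4
    annulus_diameter: float = 25.1
    sinus_diameter: float = 34.3
    stj_diameter: float = 28.9
    ascending_diameter: float = 32.1
    axial_heights: Tuple[float, float, float, float, float] = (-10.0, 0.0, 10.0, 20.0, 30.0)
    ms_depth_ncc: float = 5.1
    ms_depth_mid: float = 3.5
    ms_depth_rcc: float = 1.7
    calcium_volumes: Dict[Tuple[str, str], float] = field(default_factory=_default_calcium_volumes)
    cusp_angles: Tuple[float, float, float] = (0.0, 120.0, 240.0)
    ms_angles: Tuple[float, float, float] = (30.0, 60.0, 90.0)

    @property
    def diameters(self) -> Tuple[float, float, float, float, float]:
        return (
            self.lvot_diameter,
            self.annulus_diameter,
            self.sinus_diameter,
            self.stj_diameter,
            self.ascending_diameter,
        )

    @property
    def ms_depths(self) -> Tuple[float, float, float]:
        return (self.ms_depth_ncc, self.ms_depth_mid, self.ms_depth_rcc)

    def validate(self) -> None:
        for name, d in zip(
            ("lvot", "annulus", "sinus", "stj", "ascending"), self.diameters
        ):
            if not np.isfinite(d) or d <= 0:
                raise InvalidParameterError(f"{name}_diameter must be > 0, got {d}")
        if any(d < 0 for d in self.ms_depths):
            raise InvalidParameterError("membranous-septum depths must be >= 0")
        for key, v in self.calcium_volumes.items():
            if v < 0:
                raise InvalidParameterError(f"calcium volume {key} must be >= 0")
        heights = np.asarray(self.axial_heights, float)
        if not np.all(np.diff(heights) > 0):
            raise InvalidParameterError("axial_heights must be strictly increasing")
        angles = np.sort(np.mod(self.cusp_angles, 360.0))
        if np.min(np.diff(np.concatenate([angles, [angles[0] + 360.0]]))) <= 0:
            raise InvalidParameterError("cusp angles must be distinct modulo 360")


@dataclass(frozen=True)
class WallModelConfig:
    """Structural constants of the reduced wall model.

    These are modelling configuration, not clinically measured quantities:
    the source anatomy gives material moduli but no stiffness constants for
    the nodal support springs.

    wall_thickness : mm, thin-shell thickness of the aortic wall.
    leaflet_thickness : mm, effective thickness of the leaflet resistance band.
    foundation_modulus : N/mm per mm^2 of wall, distributed support of the
        surrounding cardiac structures (equivalent to ~0.02 N/mm per node on
        the default 72 x 0.5 mm grid of a 25 mm root).
    septal_support_modulus : N/mm per mm^2, extra support below the annulus
        where the outflow tract is muscular septum rather than aortic wall.
    calcium_thickness : mm, nominal thickness used to turn a requested deposit
        volume into a patch footprint area.
    calcium_max_thickness : mm, capacity bound per unit wall area.
    """

    wall_thickness: float = 2.0
    leaflet_thickness: float = 2.0
    foundation_modulus: float = 0.0367
    septal_support_modulus: float = 0.15
    calcium_thickness: float = 2.0
    calcium_max_thickness: float = 6.0


def angle_in_span(theta, start: float, end: float):
    """True where angle ``theta`` lies in the arc from ``start`` to ``end`` (deg, CCW)."""
    width = np.mod(end - start, 360.0)
    if width == 0.0:
        width = 360.0
    return np.mod(np.asarray(theta) - start, 360.0) <= width + 1e-9


@dataclass
class AorticRootModel:
    """Discretized aortic-root wall with per-node mechanical state.

    ``radius[iz, ic]`` is the wall radius at ``z[iz]``, ``theta[ic]``.
    ``k_base`` is the per-node elastic radial stiffness (N/mm) from wall,
    foundation, septal support and leaflet band; ``k_calcium`` is the extra
    elastic stiffness from deposited calcium, capped in force by
    ``yield_stress`` (elastic--perfectly-plastic; 1% hardening).
    """

    theta: np.ndarray
    z: np.ndarray
    radius: np.ndarray
    node_area: np.ndarray
    k_base: np.ndarray
    k_calcium: np.ndarray
    calcium_volume: np.ndarray
    yield_stress: float
    wall_thickness: float
    landmarks: Dict[str, Tuple[float, float]]
    ms_landmarks: Dict[str, Tuple[float, float]]
    params: RootParams
    wall_config: WallModelConfig
    element_area: np.ndarray = field(default=None, repr=False)
    element_theta: np.ndarray = field(default=None, repr=False)
    element_z: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.element_area is None:
            self.refresh_geometry()

    # -- geometry -----------------------------------------------------------
    @property
    def n_circ(self) -> int:
        return self.theta.size

    @property
    def n_z(self) -> int:
        return self.z.size

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    def node_coordinates(self) -> np.ndarray:
        """(n_z, n_circ, 3) Cartesian node coordinates (mm)."""
        th = np.deg2rad(self.theta)[None, :]
        r = self.radius
        return np.stack(
            [r * np.cos(th), r * np.sin(th), np.broadcast_to(self.z[:, None], r.shape)],
            axis=-1,
        )

    def refresh_geometry(self) -> None:
        """Recompute element areas/centroids and nodal tributary areas."""
        pts = self.node_coordinates()
        p00 = pts[:-1, :, :]
        p01 = np.roll(pts, -1, axis=1)[:-1, :, :]
        p10 = pts[1:, :, :]
        p11 = np.roll(pts, -1, axis=1)[1:, :, :]
        a1 = 0.5 * np.linalg.norm(np.cross(p01 - p00, p11 - p00), axis=-1)
        a2 = 0.5 * np.linalg.norm(np.cross(p11 - p00, p10 - p00), axis=-1)
        self.element_area = a1 + a2
        dtheta = 360.0 / self.n_circ
        self.element_theta = np.mod(self.theta + dtheta / 2.0, 360.0)[None, :] * np.ones(
            (self.n_z - 1, 1)
        )
        self.element_z = 0.5 * (self.z[:-1] + self.z[1:])[:, None] * np.ones((1, self.n_circ))
        # tributary node areas: each quad contributes a quarter to its 4 nodes
        na = np.zeros_like(self.radius)
        quarter = self.element_area / 4.0
        na[:-1, :] += quarter
        na[1:, :] += quarter
        na[:-1, :] += np.roll(quarter, 1, axis=1)
        na[1:, :] += np.roll(quarter, 1, axis=1)
        self.node_area = na

    def total_area(self) -> float:
        return float(self.element_area.sum())

    def element_node_indices(self):
        """Index arrays of the four nodes of each quad element."""
        iz = np.arange(self.n_z - 1)[:, None] * np.ones((1, self.n_circ), int)
        ic = np.arange(self.n_circ)[None, :] * np.ones((self.n_z - 1, 1), int)
        icp = (ic + 1) % self.n_circ
        return (iz, ic), (iz, icp), (iz + 1, ic), (iz + 1, icp)

    def measure_diameter(self, z_level: float) -> float:
        """Perimeter-derived diameter (mm) at the mesh row nearest ``z_level``."""
        iz = int(np.argmin(np.abs(self.z - z_level)))
        pts = self.node_coordinates()[iz, :, :2]
        chords = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        return float(chords.sum() / np.pi)

    def annulus_radius(self) -> float:
        return self.measure_diameter(0.0) / 2.0

    def copy(self) -> "AorticRootModel":
        return copy.deepcopy(self)


def _radius_profile(params: RootParams) -> PchipInterpolator:
    zs = np.asarray(params.axial_heights, float)
    rs = np.asarray(params.diameters, float) / 2.0
    # flat extension beyond the measured levels keeps extrapolation bounded
    zs = np.concatenate([[zs[0] - 100.0], zs, [zs[-1] + 100.0]])
    rs = np.concatenate([[rs[0]], rs, [rs[-1]]])
    return PchipInterpolator(zs, rs)


def generate_root(
    params: RootParams,
    n_circ: int = 72,
    dz: float = 0.5,
    z_min: float = -20.0,
    z_max: float = 30.0,
    seed: int = 0,
    wall_config: Optional[WallModelConfig] = None,
    wall_material: MaterialParams = WALL_MATERIAL,
    leaflet_material: MaterialParams = LEAFLET_MATERIAL,
    radial_perturbation_sd: float = 0.0,
) -> AorticRootModel:
    """Generate a discretized aortic-root wall model from parametric anatomy.

    ``radial_perturbation_sd`` (mm) optionally roughens the surface with
    seeded Gaussian noise; it defaults to 0 so generation is exactly the
    smooth surface of revolution.
    """
    params.validate()
    if n_circ < 16:
        raise InvalidParameterError(f"n_circ must be >= 16, got {n_circ}")
    if dz <= 0:
        raise InvalidParameterError(f"dz must be > 0, got {dz}")
    wall_config = wall_config or WallModelConfig()

    n_axial = int(round((z_max - z_min) / dz))
    z = z_min + dz * np.arange(n_axial + 1)
    if not np.any(np.isclose(z, 0.0, atol=1e-9)):
        raise InvalidParameterError(
            "axial spacing must place a node row on the annulus plane z = 0"
        )
    theta = np.arange(n_circ) * (360.0 / n_circ)
    radius = np.broadcast_to(_radius_profile(params)(z)[:, None], (z.size, n_circ)).copy()
    if radial_perturbation_sd > 0:
        rng = np.random.default_rng(seed)
        radius += rng.normal(0.0, radial_perturbation_sd, radius.shape)

    ncc, rcc, lcc = params.cusp_angles
    sinus_z = params.axial_heights[2]
    landmarks: Dict[str, Tuple[float, float]] = {
        "nadir_NCC": (ncc % 360.0, 0.0),
        "nadir_RCC": (rcc % 360.0, 0.0),
        "nadir_LCC": (lcc % 360.0, 0.0),
        "commissure_NCC_RCC": ((ncc + rcc) / 2.0 % 360.0, 0.9 * sinus_z),
        "commissure_RCC_LCC": ((rcc + lcc) / 2.0 % 360.0, 0.9 * sinus_z),
        "commissure_LCC_NCC": (((lcc + ncc + 360.0) / 2.0) % 360.0, 0.9 * sinus_z),
    }
    ms_landmarks = {
        "NCC": (params.ms_angles[0] % 360.0, params.ms_depth_ncc),
        "mid": (params.ms_angles[1] % 360.0, params.ms_depth_mid),
        "RCC": (params.ms_angles[2] % 360.0, params.ms_depth_rcc),
    }

    model = AorticRootModel(
        theta=theta,
        z=z,
        radius=radius,
        node_area=None,
        k_base=np.zeros_like(radius),
        k_calcium=np.zeros_like(radius),
        calcium_volume=np.zeros_like(radius),
        yield_stress=CALCIUM_MATERIAL.yield_stress,
        wall_thickness=wall_config.wall_thickness,
        landmarks=landmarks,
        ms_landmarks=ms_landmarks,
        params=params,
        wall_config=wall_config,
    )

    # per-area stiffness densities (N/mm per mm^2), then scale by node area
    shell = wall_material.e * wall_config.wall_thickness / model.radius**2
    density = shell + wall_config.foundation_modulus
    density = density + wall_config.septal_support_modulus * (model.z[:, None] < 0.0)
    leaflet_band = (model.z[:, None] > 0.0) & (model.z[:, None] < sinus_z)
    density = density + (
        leaflet_material.e * wall_config.leaflet_thickness / model.radius**2
    ) * leaflet_band
    model.k_base = density * model.node_area
    return model


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

def _region_band(model: AorticRootModel, region: str) -> Tuple[float, float]:
    sinus_z = model.params.axial_heights[2]
    lvot_z = model.params.axial_heights[0]
    bands = {
        "leaflet": (0.0, sinus_z),
        "upper_leaflet": (sinus_z / 2.0, sinus_z),
        "device_landing_zone": (-4.0, 0.0),
        "lvot": (lvot_z, -4.0),
    }
    if region not in bands:
        raise InvalidParameterError(f"unknown calcium region {region!r}")
    return bands[region]


def _cusp_angle(model: AorticRootModel, cusp: str) -> float:
    if cusp not in CUSPS:
        raise InvalidParameterError(f"unknown cusp {cusp!r}")
    return model.landmarks[f"nadir_{cusp}"][0]


def place_calcium(
    model: AorticRootModel,
    params: Optional[RootParams] = None,
    seed: int = 0,
) -> AorticRootModel:
    """Deposit calcium patches matching the requested per-(region, cusp) volumes.

    Each request becomes a contiguous patch of nodes inside its cusp's 120
    degree angular sector and its region's axial band, sized so patch area x
    nominal thickness equals the requested volume; per-node volumes are then
    rescaled so the deposited total matches the request exactly. The patch
    centre is drawn uniformly within the sector (seeded, hence deterministic
    per seed), reflecting that calcification position within a leaflet
    segment varies patient to patient.
    """
    params = params or model.params
    rng = np.random.default_rng(seed)
    out = model.copy()
    e_ratio = CALCIUM_MATERIAL.e
    cfg = out.wall_config
    dtheta_mm = None
    for (region, cusp), volume in params.calcium_volumes.items():
        if volume <= 0.0:
            continue
        z_lo, z_hi = _region_band(out, region)
        center_theta = _cusp_angle(out, cusp)
        band_rows = (out.z >= z_lo - 1e-9) & (out.z <= z_hi + 1e-9)
        if not band_rows.any():
            raise CapacityError(f"region {region} axial band is outside the mesh")
        r_band = float(out.radius[band_rows, :].mean())
        dtheta_mm = r_band * np.deg2rad(360.0 / out.n_circ)
        band_height = z_hi - z_lo
        sector_arc = r_band * np.deg2rad(120.0)
        capacity = sector_arc * band_height * cfg.calcium_max_thickness
        if volume > capacity:
            raise CapacityError(
                f"calcium request {volume:.1f} mm^3 exceeds capacity "
                f"{capacity:.1f} mm^3 of ({region}, {cusp})"
            )
        footprint = volume / cfg.calcium_thickness
        w_z = min(band_height, np.sqrt(footprint))
        w_arc = footprint / max(w_z, 1e-9)
        if w_arc > sector_arc:
            w_arc = sector_arc
            w_z = min(band_height, footprint / w_arc)
        half_width_deg = np.rad2deg(w_arc / r_band) / 2.0
        margin = max(60.0 - half_width_deg, 0.0)
        center_theta = (center_theta + rng.uniform(-margin, margin)) % 360.0
        z_center = (z_lo + z_hi) / 2.0
        dth = np.abs((out.theta - center_theta + 180.0) % 360.0 - 180.0)
        sel_c = dth <= max(half_width_deg, 1e-9)
        sel_z = band_rows & (np.abs(out.z - z_center) <= max(w_z / 2.0, 1e-9))
        mask = sel_z[:, None] & sel_c[None, :]
        if not mask.any():
            # sub-cell deposit: assign the single nearest node in the sector/band
            iz = int(np.argmin(np.where(band_rows, np.abs(out.z - z_center), np.inf)))
            ic = int(np.argmin(dth))
            mask = np.zeros_like(out.radius, bool)
            mask[iz, ic] = True
        areas = out.node_area[mask]
        node_vol = volume * areas / areas.sum()
        out.calcium_volume[mask] += node_vol
    # Calcium acts as a stiff compressive inclusion between frame and wall:
    # stiffness per unit area E_ca * (t_ca / t_wall^2), growing with deposit
    # thickness and far exceeding the hoop-shell scale, but force-capped by
    # the elastic--perfectly-plastic yield at 0.6 MPa in the solver.
    thickness = np.where(
        out.node_area > 0, out.calcium_volume / np.maximum(out.node_area, 1e-12), 0.0
    )
    out.k_calcium = (
        e_ratio * thickness / cfg.wall_thickness**2 * out.node_area
    )
    del dtheta_mm
    return out


def deposited_volume(model: AorticRootModel) -> float:
    """Total calcium volume (mm^3) carried by the model."""
    return float(model.calcium_volume.sum())


# ---------------------------------------------------------------------------
# cohort-level parameter sampling
# ---------------------------------------------------------------------------

def sample_root_params(
    n: int,
    table1_config: Optional[Dict] = None,
    seed: int = 0,
) -> List[RootParams]:
    """Draw ``n`` parametric anatomies from the cohort distributions.

    ``table1_config`` may override any ``(mean, sd)`` entry of
    :data:`TABLE1_ANATOMY` (by field name) or :data:`TABLE1_CALCIUM` (by
    ``(region, cusp)`` key). Draws are Gaussian; quantities that cannot be
    negative (MS depths, calcium volumes) are censored at 0, which preserves
    the configured means far better than resampling-truncation for the
    strongly left-truncated MS depths. Diameters are floored at 5 mm.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    anatomy = dict(TABLE1_ANATOMY)
    calcium = dict(TABLE1_CALCIUM)
    for key, val in (table1_config or {}).items():
        if isinstance(key, tuple):
            calcium[key] = val
        elif key in anatomy:
            anatomy[key] = val
        else:
            raise InvalidParameterError(f"unknown table1_config entry {key!r}")
    for key, (_m, sd) in {**anatomy, **calcium}.items():
        if sd < 0:
            raise InvalidParameterError(f"SD for {key!r} must be >= 0")

    rng = np.random.default_rng(seed)
    out: List[RootParams] = []
    for _ in range(n):
        draws = {k: rng.normal(m, sd) for k, (m, sd) in anatomy.items()}
        for k in ("lvot_diameter", "annulus_diameter", "sinus_diameter",
                  "stj_diameter", "ascending_diameter"):
            draws[k] = max(draws[k], 5.0)
        for k in ("ms_depth_ncc", "ms_depth_mid", "ms_depth_rcc"):
            draws[k] = max(draws[k], 0.0)
        vols = {key: max(rng.normal(m, sd), 0.0) for key, (m, sd) in calcium.items()}
        out.append(RootParams(calcium_volumes=vols, **draws))
    return out


def reference_root_params() -> RootParams:
    """The cohort-mean anatomy used as the package's reference case."""
    return RootParams()


def mean_ms_depth(params: RootParams) -> float:
    """Arithmetic mean of the three membranous-septum landmark depths (mm)."""
    return float(np.mean(params.ms_depths))
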
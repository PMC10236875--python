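"""Quasi-static frame--wall deployment and contact pressure extraction.

The frame is idealized as a stack of independent circumferential rings, one
per axial mesh row it overlaps, each following the device's radial
force--diameter characteristic. The wall resists radially through the
per-node springs assembled by the anatomy module (elastic base + elastic--
perfectly-plastic calcium). Deployment is staged: the sheath is retracted
from the inflow (ventricular) end upwards over ``n_retraction_steps``,
releasing ring groups which are then driven to equilibrium by a damped
fixed-point radial update. At equilibrium each ring's outward force balances
the sum of wall spring reactions of the nodes it penetrates; rings never
exceed their local free diameter.

The solver is deterministic and exposes its residual history for diagnosis.
Contact pressures are obtained by distributing each node's normal force
equally over its incident elements and dividing by element area, which
conserves total force exactly.

The public surface follows the Model/Results idiom: build a
:class:`DeploymentModel` from an anatomy, a device and a configuration, call
:meth:`~DeploymentModel.fit`, and read scores and diagnostics off the
returned :class:`DeploymentResults`. The :func:`deploy` and
:func:`extract_pressure` functions are thin wrappers over the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .anatomy import AorticRootModel
from .device import THVDevice
from .errors import ConvergenceError, InvalidParameterError


@dataclass(frozen=True)
class DeploymentConfig:
    """Solver and positioning configuration.

    implantation_depth_target : mm below the annulus plane of the frame
        inflow edge at the noncoronary cusp.
    lateral_offset_fraction : frame-axis offset toward the outer curvature,
        as a fraction of the annulus radius (0 = coaxial).
    offset_direction_deg : circumferential direction of that offset.
    n_retraction_steps : sheath-retraction stages (inflow released first).
    contact_penalty : N/mm spring used for wall nodes whose own stiffness is
        non-finite (rigid-wall limit).
    convergence_tol : mm; converged when the largest radial update of a sweep
        falls below this.
    relaxation : under-relaxation factor of the fixed-point update.
    """

    implantation_depth_target: float = 6.2
    lateral_offset_fraction: float = 0.0
    offset_direction_deg: float = 0.0
    n_retraction_steps: int = 20
    contact_penalty: float = 1.0e5
    convergence_tol: float = 1.0e-4
    max_iterations: int = 10_000
    relaxation: float = 0.5

    def __post_init__(self):
        if self.implantation_depth_target < 0:
            raise InvalidParameterError("implantation depth target must be >= 0")
        if self.n_retraction_steps < 1:
            raise InvalidParameterError("n_retraction_steps must be >= 1")
        if self.convergence_tol <= 0:
            raise InvalidParameterError("convergence_tol must be > 0")
        if not (0.0 < self.relaxation <= 1.0):
            raise InvalidParameterError("relaxation must be in (0, 1]")


@dataclass
class ContactPressureField:
    """Per-element contact pressure (MPa) on the root mesh after deployment."""

    pressure: np.ndarray  # (n_z - 1, n_circ), MPa
    element_area: np.ndarray  # mm^2
    nodal_force: np.ndarray  # (n_z, n_circ), N (radial, outward-positive)
    converged: bool
    iterations: int

    def total_force(self) -> float:
        return float(self.nodal_force.sum())

    def check_conservation(self, rtol: float = 1e-3) -> bool:
        lhs = float((self.pressure * self.element_area).sum())
        rhs = self.total_force()
        if rhs == 0.0:
            return lhs == 0.0
        return abs(lhs - rhs) <= rtol * abs(rhs)


@dataclass
class FrameState:
    """Deployed frame geometry: one ring per overlapped mesh row."""

    device: THVDevice
    depth: float
    level_index: np.ndarray  # mesh z-row index of each ring
    z: np.ndarray  # ring axial positions (mm)
    ring_height: np.ndarray  # height above the frame inflow edge (mm)
    radius: np.ndarray  # equilibrium ring radii (mm)
    free_radius: np.ndarray  # local unloaded radii (mm)
    offset: float
    offset_direction_deg: float

    def inflow_edge_z(self) -> float:
        return -self.depth


def _wall_force(
    u: np.ndarray,
    k_base: np.ndarray,
    k_ca: np.ndarray,
    area: np.ndarray,
    yield_stress: float,
) -> np.ndarray:
    """Nodal radial reaction (N) at outward wall displacement ``u`` (mm >= 0).

    Base springs are linear; the calcium contribution is elastic--perfectly-
    plastic, capped at ``yield_stress`` x tributary area with 1% hardening.
    """
    f = k_base * u
    if np.any(k_ca > 0):
        f_yield = yield_stress * area
        u_yield = np.where(k_ca > 0, f_yield / np.maximum(k_ca, 1e-30), np.inf)
        excess = np.clip(u - u_yield, 0.0, None)  # 0 where still elastic
        f = f + np.minimum(k_ca * u, f_yield + 0.01 * k_ca * excess)
    return f


class DeploymentModel:
    """Quasi-static deployment of one device into one anatomy.

    Parameters
    ----------
    root : AorticRootModel
        Discretized anatomy with assembled nodal stiffness.
    device : THVDevice
        Frame geometry and radial force characteristic.
    config : DeploymentConfig, optional
        Positioning and solver settings (defaults target 6.2 mm depth).
    """

    def __init__(
        self,
        root: AorticRootModel,
        device: THVDevice,
        config: Optional[DeploymentConfig] = None,
    ):
        self.root = root
        self.device = device
        self.config = config or DeploymentConfig()
        d = self.config.implantation_depth_target
        z = root.z
        overlap = (z >= -d - 1e-9) & (z <= -d + device.frame_height + 1e-9)
        if not overlap.any():
            raise InvalidParameterError(
                "frame axial span does not overlap the meshed extent"
            )
        self._levels = np.nonzero(overlap)[0]

    # -- solve --------------------------------------------------------------
    def fit(self) -> "DeploymentResults":
        root, dev, cfg = self.root, self.device, self.config
        levels = self._levels
        z = root.z[levels]
        ring_h = z + cfg.implantation_depth_target
        free_r = np.asarray(dev.free_diameter(ring_h), float) / 2.0

        offset = cfg.lateral_offset_fraction * root.annulus_radius()
        dth = np.deg2rad(root.theta - cfg.offset_direction_deg)
        # wall radius as seen from the (laterally offset) frame axis
        rho = root.radius[levels, :] - offset * np.cos(dth)[None, :]

        k_base = root.k_base[levels, :]
        k_ca = root.k_calcium[levels, :]
        area = root.node_area[levels, :]
        rigid = ~np.isfinite(k_base)
        if rigid.any():
            k_base = np.where(rigid, cfg.contact_penalty, k_base)

        n_rings = levels.size
        radius = np.full(n_rings, dev.crimped_diameter / 2.0)
        no_contact = free_r <= rho.min(axis=1) + 1e-12
        radius[no_contact] = free_r[no_contact]

        # frame force slope (N/mm of radius) for damping scale
        d_knee = dev.knee_fraction * 2.0 * free_r
        slope = 2.0 * dev.plateau_n_per_mm * root.dz / np.maximum(
            2.0 * free_r - d_knee, 1e-9
        )

        # sheath retraction: release inflow-first ring groups
        order = np.argsort(ring_h)
        groups = np.array_split(order, min(cfg.n_retraction_steps, n_rings))
        released = np.zeros(n_rings, bool)
        residual_history: List[float] = []
        iterations = 0
        converged = True

        def sweep(active: np.ndarray) -> float:
            nonlocal iterations
            u = np.maximum(radius[active, None] - rho[active, :], 0.0)
            w = _wall_force(
                u, k_base[active, :], k_ca[active, :], area[active, :],
                root.yield_stress,
            ).sum(axis=1)
            f_frame = dev.radial_force(ring_h[active], 2.0 * radius[active]) * root.dz
            contact = (u > 0).astype(float)
            k_contact = ((k_base[active, :] + k_ca[active, :]) * contact).sum(axis=1)
            scale = k_contact + slope[active] + 1e-9
            step = cfg.relaxation * (f_frame - w) / scale
            radius[active] = np.clip(
                radius[active] + step, dev.crimped_diameter / 2.0, free_r[active]
            )
            iterations += 1
            return float(np.max(np.abs(step))) if step.size else 0.0

        for group in groups:
            released[group] = True
            active = np.nonzero(released & ~no_contact)[0]
            if active.size == 0:
                continue
            budget = max(cfg.max_iterations // max(len(groups), 1), 50)
            for _ in range(budget):
                res = sweep(active)
                residual_history.append(res)
                if res < cfg.convergence_tol:
                    break

        active = np.nonzero(~no_contact)[0]
        if active.size:
            for _ in range(cfg.max_iterations):
                res = sweep(active)
                residual_history.append(res)
                if res < cfg.convergence_tol:
                    break
            else:
                raise ConvergenceError(
                    f"deployment did not converge within {cfg.max_iterations} "
                    f"iterations (last residual {residual_history[-1]:.3e} mm)",
                    residual_history,
                )

        # nodal reactions at equilibrium
        nodal_force = np.zeros_like(root.radius)
        u = np.maximum(radius[:, None] - rho, 0.0)
        nodal_force[levels, :] = _wall_force(
            u, k_base, k_ca, area, root.yield_stress
        )

        field_ = extract_pressure(nodal_force, root, converged=converged,
                                  iterations=iterations)
        frame = FrameState(
            device=dev,
            depth=cfg.implantation_depth_target,
            level_index=levels,
            z=z,
            ring_height=ring_h,
            radius=radius,
            free_radius=free_r,
            offset=offset,
            offset_direction_deg=cfg.offset_direction_deg,
        )
        return DeploymentResults(
            model=self,
            field=field_,
            frame=frame,
            residual_history=residual_history,
        )


@dataclass
class DeploymentResults:
    """Converged deployment state: pressure field, frame geometry, diagnostics."""

    model: DeploymentModel
    field: ContactPressureField
    frame: FrameState
    residual_history: List[float]

    @property
    def root(self) -> AorticRootModel:
        return self.model.root

    @property
    def converged(self) -> bool:
        return self.field.converged

    @property
    def iterations(self) -> int:
        return self.field.iterations

    def conduction_metrics(self, **roi_kwargs):
        """CPI / CPMax / depth metrics over the conduction region of interest."""
        from .conduction import build_roi, compute_metrics

        roi = build_roi(self.root, **roi_kwargs)
        return compute_metrics(self.field, roi, self.frame, self.root)

    def summary(self) -> str:
        m = self.conduction_metrics()
        lines = [
            "Deployment summary",
            "==================",
            f"device              : {self.frame.device.model_name}",
            f"implantation depth  : {m.depth_mean:.2f} mm (NCC {m.depth_ncc:.2f}, LCC {m.depth_lcc:.2f})",
            f"CPI                 : {m.cpi:.1f} %",
            f"CPMax               : {m.cpmax:.3f} MPa",
            f"risk flags          : CPI>=20%: {m.cpi_ge_20}, CPMax>=0.40 MPa: {m.cpmax_ge_040}, depth>=5mm: {m.depth_ge_5}",
            f"converged           : {self.converged} ({self.iterations} sweeps)",
            f"total contact force : {self.field.total_force():.2f} N",
        ]
        return "\n".join(lines)


def deploy(
    root: AorticRootModel,
    device: THVDevice,
    config: Optional[DeploymentConfig] = None,
) -> DeploymentResults:
    """Convenience wrapper: ``DeploymentModel(root, device, config).fit()``."""
    return DeploymentModel(root, device, config).fit()


def extract_pressure(
    nodal_forces: np.ndarray,
    mesh: AorticRootModel,
    converged: bool = True,
    iterations: int = 0,
) -> ContactPressureField:
    """Translate nodal normal forces (N) into per-element pressure (MPa).

    Each node's force is split equally among its incident elements; an
    element's pressure is the sum of its incident shares divided by its area.
    This conserves ``sum(pressure * area) == sum(nodal force)`` exactly.
    """
    f = np.asarray(nodal_forces, float)
    if f.shape != mesh.radius.shape:
        raise InvalidParameterError(
            f"force array shape {f.shape} does not match mesh {mesh.radius.shape}"
        )
    incidence = np.full(f.shape, 4.0)
    incidence[0, :] = 2.0
    incidence[-1, :] = 2.0
    share = f / incidence
    p = np.zeros_like(mesh.element_area)
    p += share[:-1, :]
    p += share[1:, :]
    p += np.roll(share, -1, axis=1)[:-1, :]
    p += np.roll(share, -1, axis=1)[1:, :]
    p /= mesh.element_area
    return ContactPressureField(
        pressure=p,
        element_area=mesh.element_area.copy(),
        nodal_force=f.copy(),
        converged=converged,
        iterations=iterations,
    )


def mesh_sensitivity(
    model_generator: Callable[[Tuple[int, float]], AorticRootModel],
    device: THVDevice,
    config: Optional[DeploymentConfig] = None,
    levels: Sequence[Tuple[int, float]] = ((72, 0.5), (144, 0.25)),
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Deploy at successive mesh refinements and report CPI/CPMax stability.

    ``model_generator`` maps a ``(n_circ, dz)`` resolution to an anatomy.
    The study passes when the relative change of both scores between the last
    two levels is below ``threshold`` (default 5%).
    """
    from .conduction import build_roi, compute_cpi, compute_cpmax

    if len(levels) < 2:
        raise InvalidParameterError("need at least two refinement levels")
    rows = []
    prev = None
    for level in levels:
        root = model_generator(level)
        res = deploy(root, device, config)
        roi = build_roi(root)
        cpi = compute_cpi(res.field, roi)
        cpmax = compute_cpmax(res.field, roi)
        d_cpi = d_cpmax = np.nan
        if prev is not None:
            p_cpi, p_cpmax = prev
            d_cpi = abs(cpi - p_cpi) / max(abs(p_cpi), 1e-12)
            d_cpmax = abs(cpmax - p_cpmax) / max(abs(p_cpmax), 1e-12)
        rows.append(
            {
                "n_circ": level[0],
                "dz": level[1],
                "cpi": cpi,
                "cpmax": cpmax,
                "rel_change_cpi": d_cpi,
                "rel_change_cpmax": d_cpmax,
            }
        )
        prev = (cpi, cpmax)
    out = pd.DataFrame(rows)
    last = out.iloc[-1]
    out.attrs["passed"] = bool(
        (last["rel_change_cpi"] < threshold) and (last["rel_change_cpmax"] < threshold)
    )
    out.attrs["threshold"] = threshold
    return out
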
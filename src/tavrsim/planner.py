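"""Patient-specific implantation-depth planning.

Scans candidate implantation depths, re-deploying the device at each, and
recommends the depth minimizing CPI (ties broken by CPMax, then by the
shallower depth — a higher implant). A residual-risk flag is raised when
even the best depth leaves CPMax at or above 0.40 MPa, i.e. the patient is
predicted to remain at risk of major conduction disturbance regardless of
positioning. Embolization risk of very high implants is out of scope
mechanically; the CLI prints a fixed caution instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .anatomy import AorticRootModel
from .conduction import CPMAX_CUTOFF, build_roi, compute_cpi, compute_cpmax
from .deployment import DeploymentConfig, DeploymentModel
from .device import THVDevice
from .errors import ConvergenceError, InvalidParameterError

DEFAULT_DEPTH_GRID = tuple(float(d) for d in range(0, 11))
#: High-implant preset: target depth 0-3 mm.
HIGH_IMPLANT_GRID = (0.0, 1.0, 2.0, 3.0)

EMBOLIZATION_CAUTION = (
    "Caution: a very high implantation depth may increase the risk of THV "
    "embolization; positioning trade-offs beyond contact mechanics are not "
    "modelled."
)


@dataclass
class DepthScanResult:
    """Depth grid with per-depth scores and the planning recommendation."""

    table: pd.DataFrame  # depth, cpi, cpmax, converged, error
    recommended_depth: float
    nominal_depth: float
    predicted_residual_risk: bool
    failures: Dict[float, str]

    def summary(self) -> str:
        lines = ["Depth scan", "=========="]
        for _, row in self.table.iterrows():
            mark = " <- recommended" if row["depth"] == self.recommended_depth else ""
            lines.append(
                f"depth {row['depth']:5.1f} mm : CPI {row['cpi']:5.1f} %, "
                f"CPMax {row['cpmax']:.3f} MPa{mark}"
            )
        lines.append(
            f"residual risk (CPMax >= {CPMAX_CUTOFF} MPa at best depth): "
            f"{self.predicted_residual_risk}"
        )
        return "\n".join(lines)


def depth_scan(
    root: AorticRootModel,
    device: THVDevice,
    base_config: Optional[DeploymentConfig] = None,
    depth_grid: Sequence[float] = DEFAULT_DEPTH_GRID,
) -> DepthScanResult:
    """One deployment solve per candidate depth; pure function of its inputs."""
    base_config = base_config or DeploymentConfig()
    grid = sorted(float(d) for d in depth_grid)
    if not grid:
        raise InvalidParameterError("depth grid must be non-empty")
    if any(d < 0 for d in grid):
        raise InvalidParameterError("depths must be >= 0")

    rows: List[dict] = []
    failures: Dict[float, str] = {}
    roi = build_roi(root)
    for d in grid:
        cfg = replace(base_config, implantation_depth_target=d)
        try:
            res = DeploymentModel(root, device, cfg).fit()
            cpi = compute_cpi(res.field, roi)
            cpmax = compute_cpmax(res.field, roi)
            rows.append(
                {"depth": d, "cpi": cpi, "cpmax": cpmax, "converged": True, "error": ""}
            )
        except ConvergenceError as exc:  # record and exclude from the argmin
            failures[d] = str(exc)
            rows.append(
                {"depth": d, "cpi": np.nan, "cpmax": np.nan, "converged": False,
                 "error": str(exc)}
            )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise ConvergenceError("no depth in the grid produced a converged solve")
    # argmin CPI, tiebreak CPMax, then lowest depth (rows are depth-sorted)
    best = ok.sort_values(["cpi", "cpmax", "depth"], kind="stable").iloc[0]
    return DepthScanResult(
        table=table,
        recommended_depth=float(best["depth"]),
        nominal_depth=float(base_config.implantation_depth_target),
        predicted_residual_risk=bool(best["cpmax"] >= CPMAX_CUTOFF),
        failures=failures,
    )
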
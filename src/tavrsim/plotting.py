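"""Diagnostic plots for deployments, depth scans and ROC analyses.

Matplotlib is imported lazily so headless/statistics-only use never touches
a display backend.
"""

from __future__ import annotations

import numpy as np

from .conduction import ConductionROI
from .deployment import DeploymentResults
from .planner import DepthScanResult
from .stats import RocResult


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_pressure_map(result: DeploymentResults, roi: ConductionROI = None, ax=None):
    """Unrolled (theta, z) map of element contact pressure, ROI outlined."""
    ax = _axes(ax)
    root = result.root
    mesh = ax.pcolormesh(
        np.append(root.theta, 360.0),
        root.z,
        result.field.pressure,
        shading="flat",
        cmap="inferno",
    )
    ax.figure.colorbar(mesh, ax=ax, label="contact pressure (MPa)")
    if roi is not None:
        ax.contour(
            np.mod(root.element_theta, 360.0),
            root.element_z,
            roi.mask.astype(float),
            levels=[0.5],
            colors="cyan",
            linewidths=1.0,
        )
    ax.axhline(0.0, color="w", lw=0.5, ls="--")
    ax.set_xlabel("circumferential angle (deg)")
    ax.set_ylabel("z (mm, annulus = 0)")
    return ax


def plot_depth_scan(result: DepthScanResult, ax=None):
    """CPI and CPMax versus candidate implantation depth."""
    ax = _axes(ax)
    ok = result.table[result.table["converged"]]
    ax.plot(ok["depth"], ok["cpi"], "o-", label="CPI (%)")
    ax.set_xlabel("implantation depth (mm)")
    ax.set_ylabel("CPI (%)")
    ax2 = ax.twinx()
    ax2.plot(ok["depth"], ok["cpmax"], "s--", color="C3", label="CPMax (MPa)")
    ax2.set_ylabel("CPMax (MPa)")
    ax.axvline(result.recommended_depth, color="k", ls=":", lw=1)
    return ax


def plot_roc(roc: RocResult, label: str = "", ax=None):
    """Empirical ROC curve with the chance diagonal."""
    ax = _axes(ax)
    t = roc.thresholds.sort_values("threshold")
    fpr = 1.0 - t["specificity"]
    ax.plot(fpr, t["sensitivity"], "-", label=f"{label} AUC={roc.auc:.2f}".strip())
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax
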
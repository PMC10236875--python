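"""Self-expanding THV frame models.

The supported devices are the 23/26/29 mm Evolut PRO and the 34 mm Evolut R.
A device is a frame-height profile of unloaded ("free") diameters plus a
radial force--diameter characteristic shaped like a chronic outward force
curve: a plateau at small diameters decaying linearly to zero at the local
free diameter. Forces are expressed per unit frame height (N/mm) so that the
deployment solver's results do not depend on its axial discretization.

Definitions live in a versioned YAML catalog (``data/devices.yaml``); custom
devices can be registered at run time through :func:`register_device`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

from .errors import InvalidParameterError, UnsupportedDeviceError


@dataclass(frozen=True)
class THVDevice:
    """One self-expanding frame.

    ``profile`` is a sequence of (height mm from the inflow edge, unloaded
    diameter mm) control points interpolated monotone-cubically.
    ``plateau_n_per_mm`` is the outward-force plateau per mm of frame height;
    the force decays linearly from the plateau (for diameters at or below
    ``knee_fraction`` x local free diameter) to zero at the free diameter.
    """

    model_name: str
    size: int
    frame_height: float
    crimped_diameter: float
    has_pericardial_wrap: bool
    profile: Tuple[Tuple[float, float], ...]
    plateau_n_per_mm: float
    knee_fraction: float = 0.7

    def __post_init__(self):
        heights = np.array([p[0] for p in self.profile], float)
        diams = np.array([p[1] for p in self.profile], float)
        if heights[0] != 0.0 or heights[-1] != self.frame_height:
            raise InvalidParameterError("profile must span [0, frame_height]")
        if not np.all(np.diff(heights) > 0):
            raise InvalidParameterError("profile heights must be strictly increasing")
        if np.any(diams <= 0):
            raise InvalidParameterError("profile diameters must be > 0")
        if self.crimped_diameter >= diams.min():
            raise InvalidParameterError("crimped diameter must be below the free profile")
        if self.plateau_n_per_mm < 0:
            raise InvalidParameterError("force plateau must be >= 0")
        if not (0.0 < self.knee_fraction < 1.0):
            raise InvalidParameterError("knee_fraction must be in (0, 1)")
        object.__setattr__(
            self, "_profile_interp", PchipInterpolator(heights, diams)
        )

    def free_diameter(self, height) -> np.ndarray:
        """Unloaded diameter (mm) at ``height`` mm above the inflow edge."""
        h = np.asarray(height, float)
        if np.any(h < -1e-9) or np.any(h > self.frame_height + 1e-9):
            raise InvalidParameterError(
                f"height outside frame [0, {self.frame_height}] mm"
            )
        return self._profile_interp(np.clip(h, 0.0, self.frame_height))

    def radial_force(self, ring_height, diameter) -> np.ndarray:
        """Outward radial force (N per mm frame height) at a given ring diameter.

        Zero at and above the local free diameter; plateau below the knee;
        linear in between. Continuous and non-increasing in diameter.
        """
        d = np.asarray(diameter, float)
        if np.any(d <= 0):
            raise InvalidParameterError("diameter must be > 0")
        d_free = self.free_diameter(ring_height)
        d_knee = self.knee_fraction * d_free
        span = np.maximum(d_free - d_knee, 1e-9)
        frac = np.clip((d_free - d) / span, 0.0, 1.0)
        return self.plateau_n_per_mm * frac


def _device_from_entry(name: str, entry: dict) -> THVDevice:
    return THVDevice(
        model_name=name,
        size=int(entry["size"]),
        frame_height=float(entry["frame_height"]),
        crimped_diameter=float(entry["crimped_diameter"]),
        has_pericardial_wrap=bool(entry["has_pericardial_wrap"]),
        profile=tuple((float(h), float(d)) for h, d in entry["profile"]),
        plateau_n_per_mm=float(entry["plateau_n_per_mm"]),
        knee_fraction=float(entry.get("knee_fraction", 0.7)),
    )


def _load_catalog() -> Dict[str, THVDevice]:
    text = (
        importlib.resources.files("tavrsim") / "data" / "devices.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {name: _device_from_entry(name, e) for name, e in raw["devices"].items()}


_CATALOG: Dict[str, THVDevice] = _load_catalog()


def catalog_names() -> List[str]:
    return sorted(_CATALOG)


def get_device(model_name: str) -> THVDevice:
    """Look up a device by catalog name (case-insensitive)."""
    for name, dev in _CATALOG.items():
        if name.lower() == str(model_name).lower():
            return dev
    raise UnsupportedDeviceError(
        f"unsupported device {model_name!r}; catalog has {catalog_names()}"
    )


def register_device(device: THVDevice) -> None:
    """Add (or replace) a custom device in the run-time catalog."""
    _CATALOG[device.model_name] = device


def radial_force(device: THVDevice, ring_height: float, diameter: float) -> float:
    """Functional wrapper over :meth:`THVDevice.radial_force`."""
    return float(device.radial_force(ring_height, diameter))
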
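"""Core data types for long-term lake monitoring records.

A monitoring record is a time series of depth profiles (one per sampling
date, several analytes per depth), a hypsographic curve (planar area as a
function of depth) used for all volume integrations, and two auxiliary
records: hypolimnetic withdrawal (outflow rate and phosphorus content of
the withdrawn water) and inflow total phosphorus.

Depths are metres below the surface, positive down, 0 = surface.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

#: Analyte column names shared by the CSV interchange format and the
#: in-memory containers (units in the name).
ANALYTES = (
    "temp_c",
    "o2_mg_l",
    "tp_ug_l",
    "chla_ug_l",
    "so4_mmol_l",
    "no3_mmol_l",
    "nh4_ug_l",
)


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


class SchemaError(ValueError):
    """An input file is missing mandatory columns or is malformed."""


@dataclass(frozen=True)
class DepthProfile:
    """One sampling date's measurements at fixed depths.

    ``values`` maps an analyte name (see :data:`ANALYTES`) to an array
    aligned with ``depths``; missing measurements are NaN.
    """

    date: dt.date
    depths: np.ndarray
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        if self.depths.ndim != 1 or self.depths.size < 1:
            raise ValidationError(f"{self.date}: profile needs >=1 depth")
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError(
                f"{self.date}: depths must be strictly increasing, got {self.depths}"
            )
        if self.depths[0] < 0:
            raise ValidationError(f"{self.date}: negative depth {self.depths[0]}")
        clean = {}
        for name, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != self.depths.shape:
                raise ValidationError(
                    f"{self.date}: analyte {name!r} has {arr.size} values "
                    f"for {self.depths.size} depths"
                )
            clean[name] = arr
        object.__setattr__(self, "values", clean)

    def analyte(self, name: str) -> np.ndarray:
        """Values for ``name`` aligned with ``depths`` (all-NaN if absent)."""
        if name in self.values:
            return self.values[name]
        return np.full_like(self.depths, np.nan)

    def has(self, name: str) -> bool:
        return name in self.values and bool(np.any(np.isfinite(self.values[name])))


@dataclass(frozen=True)
class Hypsography:
    """Monotone depth -> planar area curve.

    Area is linearly interpolated between tabulated depths; volumes are
    trapezoidal integrals of area over depth (exact for the piecewise
    linear curve).
    """

    depths: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if d.ndim != 1 or d.size < 2 or a.shape != d.shape:
            raise ValidationError("hypsography needs >=2 aligned (depth, area) rows")
        if np.any(np.diff(d) <= 0):
            raise ValidationError("hypsography depths must be strictly increasing")
        if d[0] != 0.0:
            raise ValidationError("hypsography must include the surface (depth 0) row")
        if np.any(np.diff(a) > 0):
            raise ValidationError("non-monotone hypsography: area increases with depth")
        if a[0] <= 0:
            raise ValidationError("surface area must be positive")
        if np.any(a < 0):
            raise ValidationError("negative planar area")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "areas", a)

    @property
    def surface_area(self) -> float:
        """A0, planar area at depth 0 (m^2)."""
        return float(self.areas[0])

    @property
    def max_depth(self) -> float:
        return float(self.depths[-1])

    @property
    def total_volume(self) -> float:
        """Whole-lake volume (m^3), trapezoidal in depth."""
        return float(np.trapezoid(self.areas, self.depths))

    def area_at(self, z) -> np.ndarray | float:
        """Planar (sediment-contact) area at depth z, linear interpolation."""
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-12) or np.any(z > self.max_depth + 1e-9):
            raise ValidationError(
                f"depth outside hypsography range [0, {self.max_depth}]"
            )
        out = np.interp(np.clip(z, 0.0, self.max_depth), self.depths, self.areas)
        return float(out) if out.ndim == 0 else out

    def volume_between(self, top: float, bottom: float) -> float:
        """Water volume between two depths (m^3), exact for the curve."""
        if not (0.0 <= top < bottom <= self.max_depth + 1e-9):
            raise ValidationError(f"invalid layer [{top}, {bottom}]")
        zs = np.unique(
            np.concatenate(
                [[top, bottom], self.depths[(self.depths > top) & (self.depths < bottom)]]
            )
        )
        return float(np.trapezoid(self.area_at(zs), zs))

    def depth_at_area(self, area: float) -> float:
        """Inverse curve: shallowest depth whose planar area equals ``area``."""
        if not (self.areas[-1] - 1e-9 <= area <= self.areas[0] + 1e-9):
            raise ValidationError("area outside hypsographic range")
        # areas decrease with depth -> reverse for np.interp
        return float(np.interp(-area, -self.areas, self.depths))


@dataclass(frozen=True)
class LayerSpec:
    """A labelled depth stratum, e.g. epilimnion or hypolimnion."""

    top: float
    bottom: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.top < self.bottom):
            raise ValidationError(f"layer {self.label!r}: need 0 <= top < bottom")


@dataclass(frozen=True)
class WithdrawalRecord:
    """One month's hypolimnetic withdrawal: outflow and withdrawn-water TP."""

    date: dt.date
    outflow_l_s: float
    tp_ug_l: float

    def __post_init__(self) -> None:
        if self.outflow_l_s < 0:
            raise ValidationError(f"{self.date}: negative outflow")
        if self.tp_ug_l < 0:
            raise ValidationError(f"{self.date}: negative TP")


@dataclass(frozen=True)
class InflowRecord:
    """Total phosphorus measured at the lake inflow."""

    date: dt.date
    tp_ug_l: float

    def __post_init__(self) -> None:
        if self.tp_ug_l < 0:
            raise ValidationError(f"{self.date}: negative TP")


@dataclass
class LakeDataset:
    """Everything the pipeline consumes for one lake."""

    profiles: list[DepthProfile]
    hypsography: Hypsography
    withdrawal: list[WithdrawalRecord] = field(default_factory=list)
    inflow: list[InflowRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.profiles = sorted(self.profiles, key=lambda p: p.date)
        dates = [p.date for p in self.profiles]
        if len(set(dates)) != len(dates):
            dup = sorted({d for d in dates if dates.count(d) > 1})
            raise ValidationError(f"duplicate profile dates: {dup}")
        zmax = self.hypsography.max_depth
        for p in self.profiles:
            if p.depths[-1] > zmax + 1e-9:
                raise ValidationError(
                    f"{p.date}: profile depth {p.depths[-1]} m exceeds "
                    f"hypsography maximum {zmax} m"
                )
        self.withdrawal = sorted(self.withdrawal, key=lambda r: r.date)
        self.inflow = sorted(self.inflow, key=lambda r: r.date)

    @property
    def years(self) -> list[int]:
        return sorted({p.date.year for p in self.profiles})
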
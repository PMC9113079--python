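"""Idealized stenosed-vessel geometry: lesion specs and discretized area profiles.

A vessel segment is a straight tube of constant reference diameter carrying
zero or more non-overlapping lesions.  Each lesion narrows the lumen either
concentrically (in both orthogonal planes) or eccentrically (in one plane,
modelled as a circle truncated by a flat plaque), with a longitudinal outline
that is either rounded (raised-cosine) or rectangular (step edges), and a
taper that is either focal (tightest only at mid-lesion) or uniform (constant
maximal narrowing with short rounded shoulders).

The discretized :class:`AreaProfile` is the interface consumed by the
haemodynamic solver.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "CrossSection",
    "LongitudinalProfile",
    "Taper",
    "LesionSpec",
    "SegmentSpec",
    "AreaProfile",
    "InvalidLesionError",
    "OverlappingLesionsError",
    "csa_concentric",
    "csa_eccentric",
    "lesion_shape_function",
    "build_area_profile",
]

#: default axial discretization step [mm]
DEFAULT_GRID_STEP_MM = 0.1

#: offset used to bracket step discontinuities of rectangular lesions [mm]
_EDGE_EPS_MM = 1e-7


class CrossSection(str, Enum):
    """How the lumen is narrowed in cross-section."""

    CONCENTRIC = "concentric"  # narrowed in both orthogonal planes
    ECCENTRIC = "eccentric"  # narrowed in one plane (flat plaque)


class LongitudinalProfile(str, Enum):
    """Longitudinal outline of the lesion."""

    ROUNDED = "rounded"
    RECTANGULAR = "rectangular"


class Taper(str, Enum):
    """Axial distribution of the narrowing within the lesion."""

    FOCAL = "focal"  # maximal narrowing only at mid-lesion
    UNIFORM = "uniform"  # maximal narrowing sustained along the body


class InvalidLesionError(ValueError):
    """Raised for physically impossible lesion parameters."""


class OverlappingLesionsError(ValueError):
    """Raised when two lesions in one segment overlap axially."""


def csa_concentric(ds_fraction: float, diameter_mm: float) -> float:
    """Lumen cross-sectional area [mm^2] of a concentric stenosis.

    The residual lumen is a circle of diameter ``(1 - ds) * D``, so the area
    stenosis is ``1 - (1 - ds)**2``.

    Parameters
    ----------
    ds_fraction
        Diameter stenosis as a fraction in ``[0, 1)``.
    diameter_mm
        Reference (healthy) lumen diameter [mm].
    """
    _check_ds(ds_fraction)
    r = (1.0 - np.asarray(ds_fraction, dtype=float)) * diameter_mm / 2.0
    area = np.pi * r * r
    return area if area.ndim else float(area)


def csa_eccentric(ds_fraction: float, diameter_mm: float) -> float:
    """Lumen cross-sectional area [mm^2] of an eccentric (flat-plaque) stenosis.

    The lumen is the reference circle truncated by a chord, leaving a circular
    segment of height ``h = (1 - ds) * D``.  At 50% diameter stenosis the
    chord passes through the centre and the area is exactly half the
    reference area.
    """
    _check_ds(ds_fraction)
    r = diameter_mm / 2.0
    h = (1.0 - ds_fraction) * diameter_mm
    if h >= 2.0 * r:  # no narrowing
        return float(np.pi * r * r)
    d = r - h  # signed distance from centre to chord
    return float(r * r * np.arccos(d / r) - d * np.sqrt(2.0 * r * h - h * h))


def _check_ds(ds_fraction) -> None:
    ds = np.asarray(ds_fraction, dtype=float)
    if np.any(ds < 0.0) or np.any(ds >= 1.0):
        raise InvalidLesionError(
            f"ds_fraction must lie in [0, 1); got {ds_fraction!r} "
            "(a fully occluded vessel is not modelled)"
        )


@dataclass(frozen=True)
class LesionSpec:
    """One stenosis attached to a vessel segment.

    Parameters
    ----------
    ds_fraction
        Diameter stenosis in ``[0, 1)`` (e.g. 0.7 for a 70% DS).
    length_mm
        Axial lesion length [mm].
    center_mm
        Axial position of the lesion midpoint within its segment [mm].
    cross_section, profile, taper
        Morphology enums; see module docstring.
    shoulder_mm
        Ramp length at each end of a rounded *uniform* lesion [mm].
    """

    ds_fraction: float
    length_mm: float
    center_mm: float
    cross_section: CrossSection = CrossSection.CONCENTRIC
    profile: LongitudinalProfile = LongitudinalProfile.ROUNDED
    taper: Taper = Taper.FOCAL
    shoulder_mm: float = 1.0

    def __post_init__(self) -> None:
        _check_ds(self.ds_fraction)
        if self.length_mm <= 0:
            raise InvalidLesionError(f"length_mm must be > 0, got {self.length_mm}")
        if self.shoulder_mm <= 0:
            raise InvalidLesionError(f"shoulder_mm must be > 0, got {self.shoulder_mm}")
        # normalize plain strings to enums
        object.__setattr__(self, "cross_section", CrossSection(self.cross_section))
        object.__setattr__(self, "profile", LongitudinalProfile(self.profile))
        object.__setattr__(self, "taper", Taper(self.taper))

    @property
    def start_mm(self) -> float:
        return self.center_mm - self.length_mm / 2.0

    @property
    def end_mm(self) -> float:
        return self.center_mm + self.length_mm / 2.0

    def min_area_mm2(self, diameter_mm: float) -> float:
        """Anatomical minimal lumen area [mm^2] of this lesion."""
        if self.cross_section is CrossSection.CONCENTRIC:
            return csa_concentric(self.ds_fraction, diameter_mm)
        return csa_eccentric(self.ds_fraction, diameter_mm)

    def translated(self, delta_mm: float) -> "LesionSpec":
        return replace(self, center_mm=self.center_mm + delta_mm)

    def to_dict(self) -> dict:
        return {
            "ds_fraction": self.ds_fraction,
            "length_mm": self.length_mm,
            "center_mm": self.center_mm,
            "cross_section": self.cross_section.value,
            "profile": self.profile.value,
            "taper": self.taper.value,
            "shoulder_mm": self.shoulder_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LesionSpec":
        return cls(**d)


def lesion_shape_function(lesion: LesionSpec, x_mm) -> np.ndarray:
    """Local diameter-severity of ``lesion`` at axial positions ``x_mm``.

    Returns values in ``[0, ds_fraction]``; zero outside the lesion extent.

    * rectangular: step to full severity over the whole lesion length;
    * rounded focal: raised-cosine bell peaking at mid-lesion, zero at ends;
    * rounded uniform: raised-cosine ramps over ``shoulder_mm`` at each end
      with a constant-severity plateau between.
    """
    x = np.asarray(x_mm, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    s = np.zeros_like(x)
    rel = x - lesion.start_mm
    L = lesion.length_mm
    ds = lesion.ds_fraction
    inside = (rel >= 0.0) & (rel <= L)
    if lesion.profile is LongitudinalProfile.RECTANGULAR:
        s[inside] = ds
    elif lesion.taper is Taper.FOCAL:
        s[inside] = ds * 0.5 * (1.0 - np.cos(2.0 * np.pi * rel[inside] / L))
    else:
        sh = min(lesion.shoulder_mm, L / 2.0)
        r = rel[inside]
        v = np.full_like(r, ds)
        up = r < sh
        dn = r > L - sh
        v[up] = ds * 0.5 * (1.0 - np.cos(np.pi * r[up] / sh))
        v[dn] = ds * 0.5 * (1.0 - np.cos(np.pi * (L - r[dn]) / sh))
        s[inside] = v
    return float(s[0]) if scalar else s


@dataclass(frozen=True)
class SegmentSpec:
    """A straight vessel segment with an ordered list of lesions."""

    diameter_mm: float
    length_mm: float
    lesions: tuple[LesionSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be > 0, got {self.diameter_mm}")
        if self.length_mm <= 0:
            raise ValueError(f"length_mm must be > 0, got {self.length_mm}")
        lesions = tuple(
            les if isinstance(les, LesionSpec) else LesionSpec.from_dict(les)
            for les in self.lesions
        )
        lesions = tuple(sorted(lesions, key=lambda les: les.center_mm))
        object.__setattr__(self, "lesions", lesions)
        for les in lesions:
            if les.start_mm < 0.0 or les.end_mm > self.length_mm:
                raise InvalidLesionError(
                    f"lesion [{les.start_mm}, {les.end_mm}] mm not contained in "
                    f"segment of length {self.length_mm} mm"
                )
        for a, b in zip(lesions, lesions[1:]):
            if b.start_mm < a.end_mm:
                raise OverlappingLesionsError(
                    f"lesions at centers {a.center_mm} mm and {b.center_mm} mm "
                    f"overlap ({a.end_mm} > {b.start_mm})"
                )

    @property
    def reference_area_mm2(self) -> float:
        return csa_concentric(0.0, self.diameter_mm)

    def to_dict(self) -> dict:
        return {
            "diameter_mm": self.diameter_mm,
            "length_mm": self.length_mm,
            "lesions": [les.to_dict() for les in self.lesions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentSpec":
        return cls(
            diameter_mm=d["diameter_mm"],
            length_mm=d["length_mm"],
            lesions=tuple(LesionSpec.from_dict(x) for x in d.get("lesions", ())),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class AreaProfile:
    """Discretized axial lumen description A(x); solver-facing interface.

    Attributes
    ----------
    x_mm
        Strictly increasing axial grid [mm].
    area_mm2
        Lumen cross-sectional area at each grid node [mm^2].
    d_eff_mm
        Effective circular diameter ``sqrt(4 A / pi)`` at each node [mm].
    min_area_mm2, min_area_x_mm
        Minimal area over the grid and its axial location.
    reference_area_mm2
        Healthy lumen area of the parent segment [mm^2].
    """

    x_mm: np.ndarray
    area_mm2: np.ndarray
    d_eff_mm: np.ndarray
    min_area_mm2: float
    min_area_x_mm: float
    reference_area_mm2: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_mm, dtype=float)
        a = np.asarray(self.area_mm2, dtype=float)
        if x.shape != a.shape or x.ndim != 1:
            raise ValueError("x_mm and area_mm2 must be 1-D arrays of equal length")
        if np.any(np.diff(x) <= 0.0):
            raise ValueError("x_mm must be strictly increasing")
        if np.any(a <= 0.0):
            raise ValueError("area_mm2 must be positive everywhere")

    @property
    def length_mm(self) -> float:
        return float(self.x_mm[-1] - self.x_mm[0])


def _grid(segment: SegmentSpec, grid_step_mm: float) -> np.ndarray:
    """Base grid plus a lesion-local grid anchored at each lesion start.

    Anchoring makes the discretization translate rigidly with the lesion, so
    axial position cannot perturb the quadrature.  Step discontinuities of
    rectangular lesions are bracketed by near-coincident nodes so the viscous
    integral converges under refinement.
    """
    n = max(int(round(segment.length_mm / grid_step_mm)), 2)
    parts = [np.linspace(0.0, segment.length_mm, n + 1)]
    for les in segment.lesions:
        m = max(int(np.ceil(les.length_mm / grid_step_mm)), 2)
        if m % 2:  # keep the mid-lesion minimum on a node
            m += 1
        parts.append(np.linspace(les.start_mm, les.end_mm, m + 1))
        if les.profile is LongitudinalProfile.RECTANGULAR:
            parts.append(
                np.asarray([les.start_mm - _EDGE_EPS_MM, les.end_mm + _EDGE_EPS_MM])
            )
    x = np.unique(np.concatenate(parts))
    # drop base nodes that fall (nearly) inside a lesion so its local grid
    # alone samples the narrowing, independent of where the lesion sits
    keep = np.ones_like(x, dtype=bool)
    for les in segment.lesions:
        inside = (x > les.start_mm) & (x < les.end_mm)
        local = np.abs(
            (x - les.start_mm) / (les.length_mm / _local_n(les, grid_step_mm))
        )
        on_local = np.abs(local - np.round(local)) < 1e-9
        keep &= ~(inside & ~on_local)
    x = x[keep]
    return x[(x >= 0.0) & (x <= segment.length_mm)]


def _local_n(les: LesionSpec, grid_step_mm: float) -> int:
    m = max(int(np.ceil(les.length_mm / grid_step_mm)), 2)
    return m + 1 if m % 2 else m


def build_area_profile(
    segment: SegmentSpec, grid_step_mm: float = DEFAULT_GRID_STEP_MM
) -> AreaProfile:
    """Compose the segment's lesion shape functions into an :class:`AreaProfile`.

    Outside every lesion extent the area equals the reference area.  Serial
    lesions are separated by fully recovered healthy lumen.
    """
    if grid_step_mm <= 0:
        raise ValueError("grid_step_mm must be > 0")
    x = _grid(segment, grid_step_mm)
    area = np.full_like(x, segment.reference_area_mm2)
    for les in segment.lesions:
        s = lesion_shape_function(les, x)
        m = s > 0.0
        if not np.any(m):
            continue
        if les.cross_section is CrossSection.CONCENTRIC:
            area[m] = csa_concentric(s[m], segment.diameter_mm)
        else:
            r = segment.diameter_mm / 2.0
            h = (1.0 - s[m]) * segment.diameter_mm
            d = r - h
            area[m] = r * r * np.arccos(np.clip(d / r, -1.0, 1.0)) - d * np.sqrt(
                np.clip(2.0 * r * h - h * h, 0.0, None)
            )
    d_eff = np.sqrt(4.0 * area / np.pi)
    i_min = int(np.argmin(area))
    return AreaProfile(
        x_mm=x,
        area_mm2=area,
        d_eff_mm=d_eff,
        min_area_mm2=float(area[i_min]),
        min_area_x_mm=float(x[i_min]),
        reference_area_mm2=segment.reference_area_mm2,
    )
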
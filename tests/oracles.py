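"""Independent oracles used by the test suite.

These deliberately avoid the package's quadrature and root-find paths:
closed-form lesion areas, Simpson integration on a very fine independent
grid, and explicit algebra.
"""

import math

import numpy as np
from scipy.integrate import simpson

MM = 1e-3


def poiseuille_resistance(mu, length_mm, diameter_mm):
    """Closed-form straight-tube viscous resistance [Pa.s/m^3]."""
    return 128.0 * mu * (length_mm * MM) / (math.pi * (diameter_mm * MM) ** 4)


def circle_area(diameter_mm):
    return math.pi * (diameter_mm / 2.0) ** 2


def segment_area_by_quadrature(ds, diameter_mm, n=200_000):
    """Area of the circle truncated by a chord, by midpoint quadrature of
    horizontal strips (independent of the arccos closed form)."""
    r = diameter_mm / 2.0
    h = (1.0 - ds) * diameter_mm  # residual height measured from the bottom
    y = np.linspace(-r, min(-r + h, r), n + 1)
    ym = 0.5 * (y[1:] + y[:-1])
    width = 2.0 * np.sqrt(np.clip(r * r - ym * ym, 0.0, None))
    return float(np.sum(width * np.diff(y)))


def lesion_severity(ds, length, center, profile, taper, x, shoulder=1.0):
    """Scalar severity evaluated point-wise with plain Python math."""
    rel = x - (center - length / 2.0)
    if rel < 0.0 or rel > length:
        return 0.0
    if profile == "rectangular":
        return ds
    if taper == "focal":
        return ds * 0.5 * (1.0 - math.cos(2.0 * math.pi * rel / length))
    sh = min(shoulder, length / 2.0)
    if rel < sh:
        return ds * 0.5 * (1.0 - math.cos(math.pi * rel / sh))
    if rel > length - sh:
        return ds * 0.5 * (1.0 - math.cos(math.pi * (length - rel) / sh))
    return ds


def fine_grid_pressure_drop(segment, params, fluid, q, dx_mm=0.005):
    """1-D energy-balance pressure drop on an independent fine grid.

    Viscous part: Simpson quadrature of the local Poiseuille gradient with
    lesion areas from the closed-form cross-section formulas.  Expansion
    part: Borda-Carnot loss per lesion from the closed-form minimal area
    (not the profile grid minimum).
    """
    n = int(round(segment.length_mm / dx_mm))
    x = np.linspace(0.0, segment.length_mm, n + 1)
    area = np.full_like(x, circle_area(segment.diameter_mm))
    for les in segment.lesions:
        for i, xi in enumerate(x):
            s = lesion_severity(
                les.ds_fraction, les.length_mm, les.center_mm,
                les.profile.value, les.taper.value, xi, les.shoulder_mm,
            )
            if s <= 0.0:
                continue
            if les.cross_section.value == "concentric":
                area[i] = circle_area((1.0 - s) * segment.diameter_mm)
            else:
                # closed form here; the quadrature variant is exercised in
                # the geometry unit tests
                r = segment.diameter_mm / 2.0
                h = (1.0 - s) * segment.diameter_mm
                d = r - h
                area[i] = r * r * math.acos(d / r) - d * math.sqrt(
                    2.0 * r * h - h * h
                )
    d4 = (np.sqrt(4.0 * area / math.pi) * MM) ** 4
    dp_visc = 128.0 * fluid.viscosity_Pa_s / math.pi * q * simpson(1.0 / d4, x=x * MM)

    dp_exp = 0.0
    a_ref = circle_area(segment.diameter_mm) * MM**2
    for les in segment.lesions:
        if les.cross_section.value == "concentric":
            a_min = circle_area((1.0 - les.ds_fraction) * segment.diameter_mm)
        else:
            a_min = segment_area_by_quadrature(les.ds_fraction, segment.diameter_mm)
        a_min *= MM**2
        if les.profile.value == "rectangular":
            cc = params.cc_rectangular
        elif les.taper.value == "uniform":
            cc = params.cc_uniform
        else:
            cc = params.cc_rounded
        cc_eff = cc + (1.0 - cc) * (a_min / a_ref) ** 3
        jet = 1.0 / (cc_eff * a_min) - 1.0 / a_ref
        if jet > 0.0:
            dp_exp += params.kt * fluid.density_kg_m3 / 2.0 * jet * jet * q * abs(q)
    return dp_visc + dp_exp


def linear_network_vffr(pa, pv, r_seg, r_mv):
    """Closed-form vFFR of a linear (viscous-only) segment + MVR outlet."""
    q = (pa - pv) / (r_seg + r_mv)
    return (pv + r_mv * q) / pa
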
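"""Triangulated lumen surfaces for visual QC and CFD interoperability.

Concentric vessels become surfaces of revolution of the effective radius;
eccentric vessels are extruded truncated-circle sections (reference circle
cut by the flat plaque chord).  Output is watertight (end caps included) and
written as ASCII STL or legacy ASCII VTK.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import AreaProfile, CrossSection

__all__ = ["tessellate", "export_surface", "cross_section_polygon"]

DEFAULT_SECTIONS = 64


def cross_section_polygon(
    area_mm2: float,
    reference_area_mm2: float,
    cross_section: CrossSection,
    n: int = DEFAULT_SECTIONS,
) -> np.ndarray:
    """Closed polygon (n x 2, mm) of one lumen cross-section, centroid-free.

    Concentric sections are circles of the effective radius.  Eccentric
    sections keep the reference circle of radius R and truncate it with a
    horizontal chord from above; the chord height is recovered from the
    requested area by bisection on the circular-segment area formula.
    """
    if cross_section is CrossSection.CONCENTRIC:
        r = np.sqrt(area_mm2 / np.pi)
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    r_ref = np.sqrt(reference_area_mm2 / np.pi)
    if area_mm2 >= reference_area_mm2 * (1.0 - 1e-12):
        h = 2.0 * r_ref
    else:
        # invert segment area A(h) = r^2 acos((r-h)/r) - (r-h) sqrt(2rh-h^2)
        lo, hi = 0.0, 2.0 * r_ref
        for _ in range(200):
            h = 0.5 * (lo + hi)
            d = r_ref - h
            a = r_ref**2 * np.arccos(np.clip(d / r_ref, -1, 1)) - d * np.sqrt(
                max(2 * r_ref * h - h * h, 0.0)
            )
            if a < area_mm2:
                lo = h
            else:
                hi = h
        h = 0.5 * (lo + hi)
    c = h - r_ref  # chord plane y = c; lumen is the part of the circle below
    if c >= r_ref:  # full circle
        th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack([r_ref * np.cos(th), r_ref * np.sin(th)])
    half = np.sqrt(max(r_ref**2 - c * c, 0.0))
    # arc from (+half, c) clockwise through the bottom to (-half, c)
    alpha = np.arcsin(np.clip(c / r_ref, -1.0, 1.0))
    th0, th1 = alpha, -np.pi - alpha
    n_arc = max(n - max(n // 8, 2), 4)
    th = np.linspace(th0, th1, n_arc)
    arc = np.column_stack([r_ref * np.cos(th), r_ref * np.sin(th)])
    n_chord = n - n_arc
    xs = np.linspace(-half, half, n_chord + 2)[1:-1]
    chord = np.column_stack([xs, np.full_like(xs, c)])
    return np.vstack([arc, chord])


def tessellate(
    profile: AreaProfile,
    cross_section: CrossSection,
    n_sections: int = DEFAULT_SECTIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Watertight triangulated tube: (vertices [mm], triangle index array)."""
    rings = []
    for a in profile.area_mm2:
        poly = cross_section_polygon(
            float(a), profile.reference_area_mm2, cross_section, n_sections
        )
        rings.append(poly)
    n = n_sections
    verts = []
    for x, poly in zip(profile.x_mm, rings):
        verts.append(np.column_stack([np.full(n, x), poly[:, 0], poly[:, 1]]))
    vertices = np.vstack(verts)
    faces = []
    n_rings = len(rings)
    for i in range(n_rings - 1):
        base0, base1 = i * n, (i + 1) * n
        for j in range(n):
            k = (j + 1) % n
            faces.append([base0 + j, base1 + j, base1 + k])
            faces.append([base0 + j, base1 + k, base0 + k])
    # end caps as fans around ring centroids
    c0 = len(vertices)
    centroid0 = vertices[:n].mean(axis=0)
    centroid1 = vertices[-n:].mean(axis=0)
    vertices = np.vstack([vertices, centroid0, centroid1])
    last = (n_rings - 1) * n
    for j in range(n):
        k = (j + 1) % n
        faces.append([c0, k, j])  # inlet cap, outward normal -x
        faces.append([c0 + 1, last + j, last + k])
    return vertices, np.asarray(faces, dtype=int)


def _write_stl(path: Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("solid coroflow\n")
        for tri in faces:
            p0, p1, p2 = vertices[tri]
            nvec = np.cross(p1 - p0, p2 - p0)
            norm = np.linalg.norm(nvec)
            nvec = nvec / norm if norm > 0 else nvec
            fh.write(f"  facet normal {nvec[0]:.6e} {nvec[1]:.6e} {nvec[2]:.6e}\n")
            fh.write("    outer loop\n")
            for p in (p0, p1, p2):
                fh.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid coroflow\n")


def _write_vtk(path: Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncoroflow lumen surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for p in vertices:
            fh.write(f"{p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for tri in faces:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def export_surface(
    profile: AreaProfile,
    cross_section: CrossSection | str,
    path: str | Path,
    n_sections: int = DEFAULT_SECTIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Write the lumen surface to ``path`` (.stl or .vtk, by extension).

    Returns the (vertices, faces) arrays for further inspection.
    """
    cross_section = CrossSection(cross_section)
    path = Path(path)
    vertices, faces = tessellate(profile, cross_section, n_sections)
    if path.suffix.lower() == ".stl":
        _write_stl(path, vertices, faces)
    elif path.suffix.lower() == ".vtk":
        _write_vtk(path, vertices, faces)
    else:
        raise ValueError(f"unsupported surface format: {path.suffix!r}")
    return vertices, faces
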
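"""Periocular morphometry: the seven key eye distances in 2D and 3D.

The measurements mirror routine oculoplastic assessment:

* ``mrd1`` / ``mrd2`` — margin reflex distances, from the corneal light
  reflex (the "eye center" landmark) to the upper / lower eyelid margin.
  ``mrd1`` is signed: negative when the drooping upper lid has crossed
  below the light reflex, as happens in severe ptosis.
* ``inner_canthus_center`` / ``epicanthus_center`` — from the inner
  canthus / the epicanthal fold point to the eye center.
* ``canthal_distance`` — inner to outer canthus.
* ``fissure_length`` — horizontal extent of the palpebral fissure
  (the horizontal component of the canthus-to-canthus span).
* ``fissure_width`` — maximal vertical aperture between the lids,
  between two dedicated annotation points.

2D measurements are pixel distances converted to millimetres with a
fiducial-disc scale calibration (a disc of known 10 mm diameter placed on
the forehead; its measured pixel diameters give pixels-per-mm).

3D measurements are *surface* distances: the periocular region of a face
mesh is interpolated as a smooth height field (depth as a function of the
two frontal in-plane coordinates) and each distance is the length of the
shortest path between the two landmarks constrained to that surface,
evaluated by polyline lifting with iterative refinement.  A straight-chord
mode is exposed for sensitivity analysis.

Coordinate conventions
----------------------
2D images: origin top-left, x right, y **down**, units pixels.
3D meshes: x right (temporal for a right eye), y **up**, z toward the
camera, units declared per mesh via ``model_units_per_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator

from .errors import (
    CalibrationError,
    GeometryError,
    MeasurementError,
    MeshFormatError,
)

#: Landmark names required for a complete per-eye annotation set.
LANDMARK_NAMES: tuple[str, ...] = (
    "eye_center",
    "upper_lid_margin",
    "lower_lid_margin",
    "inner_canthus",
    "epicanthus",
    "outer_canthus",
    "fissure_upper",
    "fissure_lower",
)

#: The seven key distances, in a fixed reporting order.
DISTANCE_NAMES: tuple[str, ...] = (
    "mrd1",
    "mrd2",
    "inner_canthus_center",
    "epicanthus_center",
    "canthal_distance",
    "fissure_length",
    "fissure_width",
)

#: Real diameter of the fiducial calibration disc, millimetres.
DISC_DIAMETER_MM: float = 10.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class TriMesh:
    """A triangulated surface: (n, 3) float vertices, (m, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class LandmarkSet:
    """Named key points for one eye, in 2D pixels or 3D model units.

    ``points`` maps landmark names to coordinate arrays of length 2 or 3
    (all points must share one dimensionality).  ``disc_diameters_px``
    holds the fiducial-disc diameter measurements (2D sets only).
    """

    eye_id: str
    points: dict[str, np.ndarray]
    disc_diameters_px: list[float] | None = None
    side: str = "right"

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        dims = {p.shape[-1] for p in self.points.values()}
        if len(dims) > 1:
            raise MeasurementError(f"mixed coordinate dimensionality: {sorted(dims)}")
        for name, p in self.points.items():
            if not np.all(np.isfinite(p)):
                raise MeasurementError(f"non-finite coordinates for landmark {name!r}")

    @property
    def dim(self) -> int:
        return int(next(iter(self.points.values())).shape[-1])

    def is_complete(self) -> bool:
        return all(name in self.points for name in LANDMARK_NAMES)

    def require(self, *names: str) -> None:
        for name in names:
            if name not in self.points:
                raise MeasurementError(
                    f"eye {self.eye_id!r}: missing landmark {name!r}"
                )

    def __getitem__(self, name: str) -> np.ndarray:
        self.require(name)
        return self.points[name]


@dataclass(frozen=True)
class ScaleCalibration:
    """Fiducial pixel-to-mm scale: s = mean disc diameter / 10 mm."""

    s_px_per_mm: float
    di_px: float
    d_real_mm: float = DISC_DIAMETER_MM

    def __post_init__(self) -> None:
        if not (self.s_px_per_mm > 0 and np.isfinite(self.s_px_per_mm)):
            raise CalibrationError(f"non-positive scale {self.s_px_per_mm}")
        if abs(self.s_px_per_mm - self.di_px / self.d_real_mm) > 1e-9:
            raise CalibrationError("scale inconsistent with di_px / d_real_mm")


@dataclass(frozen=True)
class DistanceVector:
    """The seven key distances for one eye, millimetres."""

    mrd1: float
    mrd2: float
    inner_canthus_center: float
    epicanthus_center: float
    canthal_distance: float
    fissure_length: float
    fissure_width: float
    dimensionality: str = "2D"  # "2D" or "3D"

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        return {prefix + name: float(getattr(self, name)) for name in DISTANCE_NAMES}

    def __post_init__(self) -> None:
        for name in DISTANCE_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise MeasurementError(f"non-finite distance {name}")


# ---------------------------------------------------------------------------
# OBJ i/o


def read_obj_mesh(path: str | Path) -> TriMesh:
    """Parse a Wavefront OBJ file (``v``/``f`` records only).

    Faces use 1-based vertex indices; polygon faces are fan-triangulated
    from their first vertex.  ``v/vt/vn`` index triplets keep only the
    vertex index.  All other record types are ignored.

    Raises
    ------
    MeshFormatError
        On non-numeric vertex coordinates, malformed faces, or face
        indices outside the vertex range.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        tag = tokens[0]
        if tag == "v":
            if len(tokens) < 4:
                raise MeshFormatError(f"line {lineno}: vertex needs 3 coordinates")
            try:
                vertices.append([float(t) for t in tokens[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"line {lineno}: non-numeric vertex") from exc
        elif tag == "f":
            if len(tokens) < 4:
                raise MeshFormatError(f"line {lineno}: face needs >= 3 vertices")
            try:
                idx = [int(t.split("/")[0]) for t in tokens[1:]]
            except ValueError as exc:
                raise MeshFormatError(f"line {lineno}: non-integer face index") from exc
            if any(i < 1 for i in idx):
                raise MeshFormatError(f"line {lineno}: face indices must be >= 1")
            # fan-triangulate polygons
            for a, b in zip(idx[1:-1], idx[2:]):
                faces.append([idx[0] - 1, a - 1, b - 1])
    verts = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces_arr = np.asarray(faces, dtype=int).reshape(-1, 3)
    if faces_arr.size and faces_arr.max() >= len(verts):
        raise MeshFormatError(
            f"face index {faces_arr.max() + 1} exceeds vertex count {len(verts)}"
        )
    return TriMesh(verts, faces_arr)


def write_obj_mesh(mesh: TriMesh, path: str | Path) -> None:
    """Write a mesh as a minimal OBJ (``v`` and ``f`` records)."""
    lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in mesh.vertices]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.faces]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# calibration and 2D measurement


def calibrate_scale(disc_diameters_px: Sequence[float]) -> ScaleCalibration:
    """Average the measured disc diameters and derive pixels-per-mm.

    Multiple diameters of the (10 mm) fiducial discs, measured along
    different directions, are averaged; the scale is their mean divided
    by the real diameter.
    """
    d = np.asarray(list(disc_diameters_px), dtype=float)
    if d.size == 0:
        raise CalibrationError("no disc diameter measurements")
    if not np.all(np.isfinite(d)) or np.any(d <= 0):
        raise CalibrationError("disc diameters must be positive and finite")
    di = float(d.mean())
    return ScaleCalibration(s_px_per_mm=di / DISC_DIAMETER_MM, di_px=di)


def measure_2d(landmarks: LandmarkSet, cal: ScaleCalibration) -> DistanceVector:
    """Compute the seven key distances from 2D pixel landmarks, in mm.

    ``mrd1`` is signed by vertical order (image y grows downward): it is
    positive when the upper lid margin lies above the light reflex and
    negative when the lid has drooped below it.  ``fissure_length`` is the
    horizontal pixel separation of the canthi; all other measures are
    Euclidean pixel distances.  Every pixel quantity is divided by the
    calibrated pixels-per-mm scale.
    """
    if landmarks.dim != 2:
        raise MeasurementError("measure_2d expects 2D landmarks")
    landmarks.require(*LANDMARK_NAMES)
    s = cal.s_px_per_mm
    pt = landmarks.points

    def dist(a: str, b: str) -> float:
        return float(np.linalg.norm(pt[a] - pt[b])) / s

    mrd1 = dist("eye_center", "upper_lid_margin")
    # image y grows downward: upper lid above the reflex has smaller y
    if pt["upper_lid_margin"][1] > pt["eye_center"][1]:
        mrd1 = -mrd1
    return DistanceVector(
        mrd1=mrd1,
        mrd2=dist("eye_center", "lower_lid_margin"),
        inner_canthus_center=dist("inner_canthus", "eye_center"),
        epicanthus_center=dist("epicanthus", "eye_center"),
        canthal_distance=dist("inner_canthus", "outer_canthus"),
        fissure_length=float(abs(pt["inner_canthus"][0] - pt["outer_canthus"][0])) / s,
        fissure_width=dist("fissure_upper", "fissure_lower"),
        dimensionality="2D",
    )


# ---------------------------------------------------------------------------
# surfaces and 3D measurement


class EyeSurface:
    """A smooth height field z = f(x, y) over the periocular region.

    Built either from scattered mesh vertices (piecewise-cubic
    Clough-Tocher interpolation, C1, interpolating every vertex) or from
    an analytic function.  Evaluation outside the covered region raises
    :class:`GeometryError`.
    """

    def __init__(
        self,
        height_fn: Callable[[np.ndarray], np.ndarray],
        bounds: tuple[float, float, float, float],
    ) -> None:
        self._fn = height_fn
        self.bounds = bounds  # (xmin, xmax, ymin, ymax)

    @classmethod
    def from_mesh(cls, mesh: TriMesh) -> "EyeSurface":
        v = mesh.vertices
        if len(v) < 3:
            raise GeometryError("mesh too small to fit a surface")
        interp = CloughTocher2DInterpolator(v[:, :2], v[:, 2])

        def fn(xy: np.ndarray) -> np.ndarray:
            z = interp(xy)
            if np.any(np.isnan(z)):
                raise GeometryError("evaluation outside the fitted surface region")
            return np.asarray(z, dtype=float)

        xmin, ymin = v[:, :2].min(axis=0)
        xmax, ymax = v[:, :2].max(axis=0)
        return cls(fn, (float(xmin), float(xmax), float(ymin), float(ymax)))

    @classmethod
    def from_function(
        cls,
        fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
        bounds: tuple[float, float, float, float],
    ) -> "EyeSurface":
        """Wrap an analytic z(x, y); used by the synthetic generator and tests."""
        xmin, xmax, ymin, ymax = bounds

        def wrapped(xy: np.ndarray) -> np.ndarray:
            xy = np.atleast_2d(xy)
            x, y = xy[:, 0], xy[:, 1]
            inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
            if not np.all(inside):
                raise GeometryError("evaluation outside the surface bounds")
            return np.asarray(fn(x, y), dtype=float)

        return cls(wrapped, bounds)

    def height(self, xy: np.ndarray) -> np.ndarray:
        """Depth at in-plane points; ``xy`` is (n, 2)."""
        return self._fn(np.atleast_2d(np.asarray(xy, dtype=float)))

    def lift(self, xy: np.ndarray) -> np.ndarray:
        """Attach surface depth to in-plane points, returning (n, 3)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return np.column_stack([xy, self.height(xy)])


def fit_eye_surface(mesh: TriMesh, landmarks: LandmarkSet | None = None) -> EyeSurface:
    """Interpolate the mesh as a smooth frontal height field.

    The mesh must be a (near) graph over the frontal plane in the
    measured region.  When ``landmarks`` are given, each landmark's
    in-plane position is checked to lie inside the interpolated region.
    """
    surface = EyeSurface.from_mesh(mesh)
    if landmarks is not None:
        for name in landmarks.points:
            try:
                surface.height(landmarks.points[name][:2])
            except GeometryError as exc:
                raise GeometryError(f"landmark {name!r} outside mesh extent") from exc
    return surface


def surface_distance(
    surface: EyeSurface,
    p: np.ndarray,
    q: np.ndarray,
    n_init: int = 128,
    rel_tol: float = 1e-4,
    max_refine: int = 8,
) -> float:
    """Length of the path between p and q constrained to the surface.

    The in-plane segment from p to q is discretized (at least 100 steps),
    each sample lifted onto the height field, and the 3D polyline length
    summed; the step count is doubled until successive refinements change
    the length by less than ``rel_tol`` relative.  The result is never
    smaller than the straight 3D chord between the lifted endpoints.
    """
    p = np.asarray(p, dtype=float)[:2]
    q = np.asarray(q, dtype=float)[:2]
    if n_init < 100:
        n_init = 100

    def polyline_length(n: int) -> float:
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        xy = p[None, :] + t * (q - p)[None, :]
        pts = surface.lift(xy)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    if np.allclose(p, q):
        return 0.0
    n = n_init
    length = polyline_length(n)
    for _ in range(max_refine):
        n *= 2
        refined = polyline_length(n)
        if abs(refined - length) <= rel_tol * max(refined, 1e-12):
            length = refined
            break
        length = refined
    return length


def chord_distance(surface: EyeSurface, p: np.ndarray, q: np.ndarray) -> float:
    """Straight 3D distance between the surface-lifted endpoints."""
    pts = surface.lift(np.vstack([np.asarray(p, float)[:2], np.asarray(q, float)[:2]]))
    return float(np.linalg.norm(pts[1] - pts[0]))


#: landmark pairs behind each distance (fissure_length handled separately)
_PAIRS: dict[str, tuple[str, str]] = {
    "mrd1": ("eye_center", "upper_lid_margin"),
    "mrd2": ("eye_center", "lower_lid_margin"),
    "inner_canthus_center": ("inner_canthus", "eye_center"),
    "epicanthus_center": ("epicanthus", "eye_center"),
    "canthal_distance": ("inner_canthus", "outer_canthus"),
    "fissure_width": ("fissure_upper", "fissure_lower"),
}


def measure_3d(
    mesh: TriMesh,
    landmarks: LandmarkSet,
    model_units_per_mm: float = 1.0,
    mode: str = "surface",
) -> DistanceVector:
    """Compute the seven key distances over the fitted 3D surface, in mm.

    Each distance is the surface path between its landmark pair
    (``mode="chord"`` switches every measure to the straight 3D chord for
    sensitivity analysis).  ``fissure_length`` — defined as the
    *horizontal* extent of the fissure — is the surface path between the
    two canthi's horizontal-line projections (their x positions at the
    mean canthal height), so that a canthal tilt lengthens
    ``canthal_distance`` but not ``fissure_length``, matching the 2D
    definition.  ``mrd1`` keeps its clinical sign (negative when the
    upper lid margin sits below the light reflex; mesh y grows upward).
    """
    if landmarks.dim != 3:
        raise MeasurementError("measure_3d expects 3D landmarks")
    if not (model_units_per_mm > 0 and np.isfinite(model_units_per_mm)):
        raise MeasurementError(f"invalid model_units_per_mm {model_units_per_mm}")
    if mode not in ("surface", "chord"):
        raise MeasurementError(f"unknown mode {mode!r}")
    landmarks.require(*LANDMARK_NAMES)
    surface = fit_eye_surface(mesh, landmarks)
    pt = landmarks.points
    metric = surface_distance if mode == "surface" else chord_distance

    values: dict[str, float] = {}
    for name, (a, b) in _PAIRS.items():
        values[name] = metric(surface, pt[a], pt[b]) / model_units_per_mm

    ic, oc = pt["inner_canthus"], pt["outer_canthus"]
    y_mid = 0.5 * (ic[1] + oc[1])
    values["fissure_length"] = metric(
        surface, np.array([ic[0], y_mid]), np.array([oc[0], y_mid])
    ) / model_units_per_mm

    # mesh y grows upward: a drooped upper lid sits below the reflex
    if pt["upper_lid_margin"][1] < pt["eye_center"][1]:
        values["mrd1"] = -values["mrd1"]
    return DistanceVector(dimensionality="3D", **values)


# ---------------------------------------------------------------------------
# tabular output


def distances_to_frame(rows: Mapping[str, tuple[DistanceVector, DistanceVector]]):
    """Build a per-eye distance table: eye_id + 7 2D + 7 3D mm columns.

    ``rows`` maps eye_id to a ``(vector_2d, vector_3d)`` pair.  Values are
    reported to 4 decimals, the package-wide output precision.
    """
    import pandas as pd

    records = []
    for eye_id, (d2, d3) in rows.items():
        rec: dict[str, object] = {"eye_id": eye_id}
        rec.update({k: round(v, 4) for k, v in d2.as_dict("d2_").items()})
        rec.update({k: round(v, 4) for k, v in d3.as_dict("d3_").items()})
        records.append(rec)
    columns = ["eye_id"] + [f"d2_{n}" for n in DISTANCE_NAMES] + [f"d3_{n}" for n in DISTANCE_NAMES]
    return pd.DataFrame.from_records(records, columns=columns)
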
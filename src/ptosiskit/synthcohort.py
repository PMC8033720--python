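"""Synthetic periocular cohorts with known ground-truth anatomy.

Clinical photographs and face scans of ptosis patients are not publicly
shareable, so this module generates stand-in data with the statistical
structure the decision pipeline assumes: per-eye anatomical parameters
(:class:`PtosisPhenotype`), a triangulated periocular surface with the
eight named landmarks, a 2D frontal projection with fiducial-disc
measurements, and a surgery label derived from the standard clinical
rule — no surgery when MRD1 is adequate; otherwise levator resection
when levator function exceeds a threshold (defaulting to 4 mm, the upper
end of the usual 3-4 mm range) and frontalis suspension below it.

Geometry
--------
Each eye is a smooth height field over the frontal plane: a spherical
corneal cap (eyeball radius 10-14 mm, protruding over a 3 mm central
zone) blended by a C1 cubic into the flat lid/canthal surround.  The
right-eye convention is +x temporal, +y up, +z toward the camera; left
eyes are generated mirrored and measured identically, since all seven
distances are reflection-invariant.

Landmark placement splits the curvature stretch: a landmark at target
distance d from the eye center is placed at the in-plane offset t
solving (t + s(t))/2 = d, where s(t) is the path length along the
analytic surface.  Both the projected 2D distance (= t) and the 3D
surface distance (= s(t)) then sit within half the local surface
stretch of d — well under 1% on the default geometry — so noise-free
cohorts round-trip through *both* measurement paths.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, GeometryError
from .morphometry import (
    DISC_DIAMETER_MM,
    LANDMARK_NAMES,
    LandmarkSet,
    TriMesh,
    write_obj_mesh,
)


class SurgeryLabel(str, enum.Enum):
    """Clinical decision outcome for one eye."""

    NO_SURGERY = "no_surgery"
    LEVATOR_RESECTION = "levator_resection"
    FRONTALIS_SUSPENSION = "frontalis_suspension"


@dataclass(frozen=True)
class PtosisPhenotype:
    """Ground-truth anatomical parameters for one synthetic eye (mm).

    ``mrd1_mm`` is signed: negative when the drooped upper lid covers
    the corneal light reflex.  ``levator_function_mm`` is the levator
    excursion driving the choice of surgical technique; it is *not*
    directly observable in the photographic features.
    """

    mrd1_mm: float
    mrd2_mm: float
    levator_function_mm: float
    intercanthal_mm: float
    fissure_width_mm: float
    eyeball_radius_mm: float
    side: str = "right"

    def validate(self) -> None:
        vals = [
            self.mrd1_mm,
            self.mrd2_mm,
            self.levator_function_mm,
            self.intercanthal_mm,
            self.fissure_width_mm,
            self.eyeball_radius_mm,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ConfigurationError("phenotype has non-finite parameters")
        if self.mrd2_mm < 0 or self.levator_function_mm < 0 or self.fissure_width_mm < 0:
            raise ConfigurationError("mrd2, levator function and fissure width must be >= 0")
        if self.intercanthal_mm <= 0:
            raise ConfigurationError("intercanthal distance must be positive")
        if not (10.0 <= self.eyeball_radius_mm <= 14.0):
            raise ConfigurationError(
                f"eyeball radius {self.eyeball_radius_mm} outside [10, 14] mm"
            )
        if self.mrd1_mm >= 0 and self.fissure_width_mm > self.mrd1_mm + self.mrd2_mm + 0.5:
            raise ConfigurationError("fissure width exceeds lid aperture")
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"side must be left or right, got {self.side!r}")

    def mirrored(self) -> "PtosisPhenotype":
        return replace(self, side="left" if self.side == "right" else "right")


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a synthetic cohort.

    Defaults emulate the reference clinical cohort: 152 eyes in class
    proportions 44/61/47 (no surgery / levator resection / frontalis
    suspension), diagnosis threshold 2.5 mm on MRD1 and plan threshold
    4.0 mm on levator function.  ``noise_sd_mm`` is *annotation* noise,
    applied to landmark coordinates and disc measurements, never to the
    underlying anatomy, so labels stay consistent with the phenotype.

    Class-conditional anatomy (means +/- sd, truncated):

    * no surgery — MRD1 4.0 +/- 0.5 (>= dx threshold), levator 13 +/- 2;
    * surgical eyes — levator function bimodal around the plan
      threshold (resection 6.5 +/- 1.5 above it, suspension 2.0 +/- 1.0
      below, separated by a 0.5 mm guard band each side), with MRD1
      tied monotonically to levator function
      (mrd1 = -1.4 + 0.34 * levator + small jitter), so severity is
      expressed in the measurable lid geometry;
    * MRD2 5.0 +/- 0.5 throughout; fissure width = MRD1 + MRD2 + jitter;
      canthus-to-canthus span 29 +/- 1.5; eyeball radius 12 +/- 0.5.
    """

    n_eyes: int = 152
    class_proportions: tuple[float, float, float] = (44 / 152, 61 / 152, 47 / 152)
    noise_sd_mm: float = 0.0
    dx_threshold_mm: float = 2.5
    plan_threshold_mm: float = 4.0
    seed: int = 0
    pixels_per_mm: float = 10.0
    mesh_spacing_mm: float = 0.5

    def validate(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.size != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions must be 3 non-negative values summing to 1, got {tuple(p)}"
            )
        if self.n_eyes < 0:
            raise ConfigurationError("n_eyes must be >= 0")
        if self.noise_sd_mm < 0:
            raise ConfigurationError("noise_sd_mm must be >= 0")
        if self.pixels_per_mm <= 0:
            raise ConfigurationError("pixels_per_mm must be positive")
        if self.mesh_spacing_mm <= 0:
            raise ConfigurationError("mesh_spacing_mm must be positive")
        if not (np.isfinite(self.dx_threshold_mm) and np.isfinite(self.plan_threshold_mm)):
            raise ConfigurationError("thresholds must be finite")


@dataclass
class CohortEye:
    """One generated eye: anatomy, mesh, annotations and label."""

    eye_id: str
    phenotype: PtosisPhenotype
    mesh: TriMesh
    landmarks_3d: LandmarkSet
    landmarks_2d: LandmarkSet
    label: SurgeryLabel


# ---------------------------------------------------------------------------
# clinical labelling rule


def assign_label(phenotype: PtosisPhenotype, config: CohortConfig) -> SurgeryLabel:
    """Apply the clinical decision rule to noise-free anatomy.

    No surgery when MRD1 is at least the diagnosis threshold; otherwise
    levator resection when levator function exceeds the plan threshold,
    else frontalis suspension.
    """
    phenotype.validate()
    if phenotype.mrd1_mm >= config.dx_threshold_mm:
        return SurgeryLabel.NO_SURGERY
    if phenotype.levator_function_mm > config.plan_threshold_mm:
        return SurgeryLabel.LEVATOR_RESECTION
    return SurgeryLabel.FRONTALIS_SUSPENSION


# ---------------------------------------------------------------------------
# phenotype sampling


def _tnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Truncated normal draw by rejection (clipped after 1000 tries)."""
    if lo > hi:
        lo, hi = hi, lo
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_phenotype(
    config: CohortConfig, target_class: SurgeryLabel, rng: np.random.Generator
) -> PtosisPhenotype:
    """Draw one phenotype from the class-conditional anatomy distributions.

    By construction :func:`assign_label` on the returned (noise-free)
    phenotype equals ``target_class`` for any seed.
    """
    config.validate()
    dx, plan = config.dx_threshold_mm, config.plan_threshold_mm
    mrd2 = _tnorm(rng, 5.0, 0.5, 3.5, 6.0)
    if target_class == SurgeryLabel.NO_SURGERY:
        lo = max(dx + 0.3, 3.2)
        mrd1 = _tnorm(rng, 4.0, 0.5, lo, max(5.2, lo + 0.6))
        levator = _tnorm(rng, 13.0, 2.0, 10.0, 17.0)
    else:
        if target_class == SurgeryLabel.LEVATOR_RESECTION:
            levator = _tnorm(rng, 6.5, 1.5, plan + 0.5, max(plan + 1.0, 10.0))
        else:
            hi = max(plan - 0.5, 0.4)
            levator = _tnorm(rng, 2.0, 1.0, min(0.3, hi / 2), hi)
        jitter = _tnorm(rng, 0.0, 0.1, -0.2, 0.2)
        mrd1 = float(np.clip(-1.4 + 0.34 * levator + jitter, -2.4, min(dx - 0.3, 2.1)))
    fissure = mrd1 + mrd2 + _tnorm(rng, 0.0, 0.15, -0.4, 0.4)
    fissure = float(np.clip(fissure, 0.3, mrd1 + mrd2 + 0.45 if mrd1 >= 0 else np.inf))
    phen = PtosisPhenotype(
        mrd1_mm=round(mrd1, 4),
        mrd2_mm=round(mrd2, 4),
        levator_function_mm=round(levator, 4),
        intercanthal_mm=round(_tnorm(rng, 29.0, 1.5, 25.0, 33.0), 4),
        fissure_width_mm=round(fissure, 4),
        eyeball_radius_mm=round(_tnorm(rng, 12.0, 0.5, 10.5, 13.5), 4),
        side="left" if rng.random() < 0.5 else "right",
    )
    phen.validate()
    assert assign_label(phen, config) == target_class
    return phen


# ---------------------------------------------------------------------------
# analytic surface and landmark placement


#: in-plane radius of the spherical corneal zone / outer blend radius (mm)
_CORNEA_RADIUS = 3.0
_BLEND_RADIUS = 7.0


def height_field(eyeball_radius_mm: float) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Analytic periocular depth z(x, y), mm, centered on the eye center.

    Spherical cap of the given eyeball radius over the central corneal
    zone, C1 cubic blend (value- and slope-matched) down to the flat
    surround; the blend dips slightly below the surround plane, like the
    soft tissue around the globe.
    """
    R = float(eyeball_radius_mm)
    if R <= 0:
        raise GeometryError("eyeball radius must be positive")
    rc, rout = _CORNEA_RADIUS, _BLEND_RADIUS
    rim = float(np.sqrt(R * R - rc * rc))
    slope = -rc / rim  # cap slope at the corneal rim
    w = rout - rc

    def z(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        r = np.hypot(x, y)
        out = np.zeros_like(r)
        cap = r <= rc
        out[cap] = np.sqrt(R * R - r[cap] ** 2) - rim
        mid = (r > rc) & (r < rout)
        u = (r[mid] - rc) / w
        out[mid] = slope * w * (u**3 - 2 * u**2 + u)  # Hermite h10 blend
        return out

    return z


def _polyline_length(
    zf: Callable[[np.ndarray, np.ndarray], np.ndarray],
    p: np.ndarray,
    q: np.ndarray,
    n: int = 1024,
) -> float:
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    xy = p[None, :] + t * (q - p)[None, :]
    z = zf(xy[:, 0], xy[:, 1])
    pts = np.column_stack([xy, z])
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _split_solve(
    zf: Callable[[np.ndarray, np.ndarray], np.ndarray],
    origin: np.ndarray,
    direction: np.ndarray,
    d: float,
) -> float:
    """In-plane offset t with (t + s(t))/2 = d; s = surface path length."""
    if d < 1e-6:
        return 0.0
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)

    def f(t: float) -> float:
        return t + _polyline_length(zf, origin, origin + t * u) - 2.0 * d

    lo = 0.5 * d
    if f(lo) > 0:  # surface stretch would need > 100%; cannot happen here
        return d
    return float(brentq(f, lo, d, xtol=1e-6))


def place_landmarks(phenotype: PtosisPhenotype) -> dict[str, np.ndarray]:
    """In-plane (x, y) landmark positions in right-eye convention, mm.

    Positions are solved against the analytic surface so that both the
    frontal projection and the surface path reproduce the phenotype's
    MRD1, MRD2, fissure width and canthal span (see module docstring).
    """
    phenotype.validate()
    zf = height_field(phenotype.eyeball_radius_mm)
    p = phenotype
    center = np.array([0.0, 0.0])
    up = np.array([0.0, 1.0])
    down = np.array([0.0, -1.0])

    pts: dict[str, np.ndarray] = {"eye_center": center.copy()}
    t_up = _split_solve(zf, center, up if p.mrd1_mm >= 0 else down, abs(p.mrd1_mm))
    pts["upper_lid_margin"] = center + (up if p.mrd1_mm >= 0 else down) * t_up
    pts["lower_lid_margin"] = center + down * _split_solve(zf, center, down, p.mrd2_mm)

    # maximal aperture points, slightly temporal of the pupil axis
    x_f = 0.8
    y_mid = 0.5 * (p.mrd1_mm - p.mrd2_mm)
    fw = p.fissure_width_mm

    def f_fissure(alpha: float) -> float:
        a = np.array([x_f, y_mid + alpha * fw / 2])
        b = np.array([x_f, y_mid - alpha * fw / 2])
        return alpha * fw + _polyline_length(zf, a, b) - 2.0 * fw

    alpha = 1.0 if fw < 1e-6 or f_fissure(0.5) > 0 else float(brentq(f_fissure, 0.5, 1.0, xtol=1e-7))
    pts["fissure_upper"] = np.array([x_f, y_mid + alpha * fw / 2])
    pts["fissure_lower"] = np.array([x_f, y_mid - alpha * fw / 2])

    # canthi: mild lateral tilt, midpoint slightly temporal and above center
    ic = p.intercanthal_mm
    mid = np.array([0.5, 0.3])
    dy = 1.2
    half = np.array([np.sqrt(ic * ic - dy * dy) / 2, dy / 2])

    def f_canthi(alpha: float) -> float:
        a, b = mid - alpha * half, mid + alpha * half
        return alpha * ic + _polyline_length(zf, a, b) - 2.0 * ic

    alpha_c = 1.0 if f_canthi(0.9) > 0 else float(brentq(f_canthi, 0.9, 1.0, xtol=1e-7))
    pts["inner_canthus"] = mid - alpha_c * half
    pts["outer_canthus"] = mid + alpha_c * half
    pts["epicanthus"] = pts["inner_canthus"] + np.array([-1.3, 0.4])
    return pts


def build_eye_mesh(
    phenotype: PtosisPhenotype, mesh_spacing_mm: float = 0.5
) -> tuple[TriMesh, LandmarkSet]:
    """Triangulate the periocular surface and place the 3D landmarks.

    The mesh is a regular grid over the landmark bounding box (3.5 mm
    margin) lifted onto the analytic height field; landmarks carry their
    exact analytic depth.  Left-side phenotypes are mirrored about x = 0.
    Model units are millimetres (``model_units_per_mm = 1``).
    """
    if mesh_spacing_mm <= 0:
        raise GeometryError("mesh spacing must be positive")
    zf = height_field(phenotype.eyeball_radius_mm)
    pts = place_landmarks(phenotype)

    xy = np.vstack(list(pts.values()))
    margin = 3.5
    xmin, ymin = xy.min(axis=0) - margin
    xmax, ymax = xy.max(axis=0) + margin
    xs = np.arange(xmin, xmax + mesh_spacing_mm, mesh_spacing_mm)
    ys = np.arange(ymin, ymax + mesh_spacing_mm, mesh_spacing_mm)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gz = zf(gx.ravel(), gy.ravel())
    verts = np.column_stack([gx.ravel(), gy.ravel(), gz])

    nx, ny = len(xs), len(ys)
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v10 = ((i + 1) * ny + j).ravel()
    v01 = (i * ny + j + 1).ravel()
    v11 = ((i + 1) * ny + j + 1).ravel()
    faces = np.vstack(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )

    mirror = phenotype.side == "left"
    if mirror:
        verts = verts * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]  # keep outward orientation

    lm3d = {
        name: np.array([-q[0] if mirror else q[0], q[1], float(zf(q[:1], q[1:2])[0])])
        for name, q in pts.items()
    }
    landmarks = LandmarkSet(
        eye_id="", points=lm3d, disc_diameters_px=None, side=phenotype.side
    )
    return TriMesh(verts, faces), landmarks


def render_landmarks_2d(
    phenotype: PtosisPhenotype,
    pixels_per_mm: float,
    rng: np.random.Generator | None = None,
    noise_sd_mm: float = 0.0,
    n_disc_measurements: int = 6,
) -> LandmarkSet:
    """Orthographic frontal projection of the landmarks to pixel space.

    Image x = mm x * scale; image y = -mm y * scale (image y grows
    downward).  Two 10 mm fiducial discs are simulated by
    ``n_disc_measurements`` diameter readings taken along different
    directions; annotation noise (``noise_sd_mm``) perturbs both the
    landmark pixels and the disc readings.
    """
    if pixels_per_mm <= 0 or not np.isfinite(pixels_per_mm):
        raise ConfigurationError(f"pixels_per_mm must be positive, got {pixels_per_mm}")
    if noise_sd_mm < 0:
        raise ConfigurationError("noise_sd_mm must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    pts = place_landmarks(phenotype)
    mirror = phenotype.side == "left"
    s = pixels_per_mm
    px: dict[str, np.ndarray] = {}
    for name, q in pts.items():
        x = -q[0] if mirror else q[0]
        px[name] = np.array([x * s, -q[1] * s])
        if noise_sd_mm > 0:
            px[name] = px[name] + rng.normal(0.0, noise_sd_mm * s, size=2)
    discs = DISC_DIAMETER_MM * s + (
        rng.normal(0.0, noise_sd_mm * s, size=n_disc_measurements)
        if noise_sd_mm > 0
        else np.zeros(n_disc_measurements)
    )
    return LandmarkSet(
        eye_id="",
        points=px,
        disc_diameters_px=[float(d) for d in discs],
        side=phenotype.side,
    )


# ---------------------------------------------------------------------------
# cohort generation


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer class counts summing to n, by largest-remainder rounding."""
    p = np.asarray(proportions, dtype=float)
    quota = n * p
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts), kind="stable")
    for k in order[: n - counts.sum()]:
        counts[k] += 1
    return [int(c) for c in counts]


def generate_cohort(config: CohortConfig) -> list[CohortEye]:
    """Generate a fully reproducible synthetic cohort.

    Class counts follow largest-remainder rounding of
    ``n_eyes * class_proportions``; the class sequence is then shuffled.
    Annotation noise (``noise_sd_mm``) is added to the 3D landmark
    coordinates and, independently, to the 2D projections and disc
    readings; meshes and phenotypes stay noise-free.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = largest_remainder_counts(config.n_eyes, config.class_proportions)
    labels = (
        [SurgeryLabel.NO_SURGERY] * counts[0]
        + [SurgeryLabel.LEVATOR_RESECTION] * counts[1]
        + [SurgeryLabel.FRONTALIS_SUSPENSION] * counts[2]
    )
    labels = [labels[k] for k in rng.permutation(len(labels))]

    cohort: list[CohortEye] = []
    for i, label in enumerate(labels):
        eye_id = f"eye{i:04d}"
        phen = sample_phenotype(config, label, rng)
        mesh, lm3d = build_eye_mesh(phen, config.mesh_spacing_mm)
        lm3d.eye_id = eye_id
        if config.noise_sd_mm > 0:
            lm3d = LandmarkSet(
                eye_id=eye_id,
                points={
                    k: v + rng.normal(0.0, config.noise_sd_mm, size=3)
                    for k, v in lm3d.points.items()
                },
                side=phen.side,
            )
        lm2d = render_landmarks_2d(
            phen, config.pixels_per_mm, rng, noise_sd_mm=config.noise_sd_mm
        )
        lm2d.eye_id = eye_id
        cohort.append(CohortEye(eye_id, phen, mesh, lm3d, lm2d, label))
    return cohort


# ---------------------------------------------------------------------------
# serialization


def cohort_manifest(cohort: Sequence[CohortEye]) -> pd.DataFrame:
    """Long-format manifest: one row per landmark (2D and 3D) or disc reading."""
    rows: list[dict[str, object]] = []
    for eye in cohort:
        base = {"eye_id": eye.eye_id, "side": eye.phenotype.side, "label": eye.label.value}
        for name in LANDMARK_NAMES:
            q = eye.landmarks_3d.points[name]
            rows.append({**base, "space": "3d", "name": name,
                         "x": round(float(q[0]), 6), "y": round(float(q[1]), 6),
                         "z": round(float(q[2]), 6)})
        for name in LANDMARK_NAMES:
            q = eye.landmarks_2d.points[name]
            rows.append({**base, "space": "2d", "name": name,
                         "x": round(float(q[0]), 6), "y": round(float(q[1]), 6),
                         "z": np.nan})
        for k, d in enumerate(eye.landmarks_2d.disc_diameters_px or []):
            rows.append({**base, "space": "2d", "name": f"disc_diameter_{k + 1}",
                         "x": round(float(d), 6), "y": np.nan, "z": np.nan})
    return pd.DataFrame(rows, columns=["eye_id", "side", "label", "space", "name", "x", "y", "z"])


def write_cohort(cohort: Sequence[CohortEye], outdir: str | Path) -> None:
    """Write meshes as OBJ files plus a CSV landmark/label manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for eye in cohort:
        write_obj_mesh(eye.mesh, outdir / f"{eye.eye_id}.obj")
    cohort_manifest(cohort).to_csv(outdir / "manifest.csv", index=False)


def read_manifest(path: str | Path) -> list[dict[str, object]]:
    """Read a cohort manifest back into per-eye landmark sets and labels.

    Returns one dict per eye with keys ``eye_id``, ``side``, ``label``,
    ``landmarks_3d`` and ``landmarks_2d``.
    """
    df = pd.read_csv(path)
    eyes: list[dict[str, object]] = []
    for eye_id, grp in df.groupby("eye_id", sort=True):
        side = str(grp["side"].iloc[0])
        label = SurgeryLabel(str(grp["label"].iloc[0]))
        g3 = grp[(grp["space"] == "3d")]
        pts3 = {str(r["name"]): np.array([r["x"], r["y"], r["z"]]) for _, r in g3.iterrows()}
        g2 = grp[(grp["space"] == "2d") & (~grp["name"].str.startswith("disc_"))]
        pts2 = {str(r["name"]): np.array([r["x"], r["y"]]) for _, r in g2.iterrows()}
        discs = grp[(grp["space"] == "2d") & (grp["name"].str.startswith("disc_"))]["x"]
        eyes.append(
            {
                "eye_id": str(eye_id),
                "side": side,
                "label": label,
                "landmarks_3d": LandmarkSet(str(eye_id), pts3, side=side),
                "landmarks_2d": LandmarkSet(
                    str(eye_id), pts2, disc_diameters_px=[float(v) for v in discs], side=side
                ),
            }
        )
    return eyes
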
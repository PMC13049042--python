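"""Displacement-indicator geometry.

The measurement model: the healthy contralateral femur is mirrored across the
sagittal midplane and rigidly registered onto the affected side (head fragment
excluded from the fit, so the fracture displacement cannot bias alignment).
The femoral head center ``E`` is the center of a least-squares sphere fit to
the head surface; the fovea landmark ``C`` is annotated.  Six indicators are
computed from the two (C, E) pairs:

* ``d1``  — distance between affected and reference fovea points, mm
* ``d2``  — distance between affected and reference head centers, mm
* ``alpha`` — angle between the fovea→center lines C1→E1 and C2→E2, degrees
* ``theta_xy/theta_xz/theta_yz`` — alpha's projections onto the transverse
  (X-Y), coronal (X-Z) and sagittal (Y-Z) anatomical planes, degrees

Frame convention (right-handed): X = medial–lateral, Y = anterior–posterior,
Z = superior–inferior, so the anatomical plane names map literally onto
coordinate planes.  Angles are stored in degrees, computed in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .mesh import LABEL_HEAD, SurfaceMesh, mirror_mesh, mirror_points

PLANES = ("xy", "xz", "yz")
#: coordinate index dropped by each projection
_PLANE_DROP = {"xy": 2, "xz": 1, "yz": 0}

#: projection shorter than this fraction of the original norm is degenerate
DEGENERATE_PROJECTION_RTOL = 1e-8


class GeometryError(ValueError):
    pass


class SphereFitError(GeometryError):
    pass


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Proper rigid map ``x -> R x + t`` (no reflection)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-8 or np.linalg.det(self.rotation) < 0:
            raise GeometryError(
                "rotation must be orthonormal with determinant +1 "
                f"(orthonormality error {err:.2e}, det {np.linalg.det(self.rotation):.6f})"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, pivot=(0, 0, 0),
                        translation=(0, 0, 0)) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` through ``pivot``, then translation."""
        axis = np.asarray(axis, dtype=np.float64)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise GeometryError("rotation axis must be nonzero")
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n).as_matrix()
        pivot = np.asarray(pivot, dtype=np.float64)
        t = pivot - R @ pivot + np.asarray(translation, dtype=np.float64)
        return cls(R, t)

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        out = pts @ self.rotation.T + self.translation
        return out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def rotation_angle_deg(self) -> float:
        return float(np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))


# ---------------------------------------------------------------------------
# Sphere fitting
# ---------------------------------------------------------------------------

@dataclass
class SphereFit:
    """Least-squares sphere: center ``E``, radius, geometric RMS residual."""

    center: np.ndarray
    radius: float
    rms_residual: float
    n_points: int


def fit_sphere(points, max_iter: int = 100, step_tol: float = 1e-10) -> SphereFit:
    """Fit a sphere to >= 4 non-coplanar points.

    An algebraic (linear least-squares) fit provides the starting point; a
    Gauss–Newton refinement of the geometric objective
    ``sum((|p - c| - r)^2)`` runs until the parameter step falls below
    ``step_tol`` mm or ``max_iter`` iterations.  The reported residual is the
    geometric RMS.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise SphereFitError("sphere fit needs >= 4 points of shape (n, 3)")

    # algebraic fit:  |p|^2 = 2 p.c + (r^2 - |c|^2)
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    # coplanar points make A rank-deficient
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 4:
        raise SphereFitError(
            "degenerate input: points are coplanar (or otherwise rank-deficient); "
            "a unique sphere is not determined"
        )
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center0 = sol[:3]
    r2 = sol[3] + center0 @ center0
    radius0 = math.sqrt(max(r2, 1e-12))

    def residuals(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    res = least_squares(residuals, np.r_[center0, radius0], method="lm",
                        xtol=step_tol, ftol=1e-15, gtol=1e-15, max_nfev=100 * max_iter)
    center, radius = res.x[:3], float(abs(res.x[3]))
    rms = float(np.sqrt(np.mean(residuals(res.x) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms, n_points=len(pts))


# ---------------------------------------------------------------------------
# Landmarks and metrics
# ---------------------------------------------------------------------------

@dataclass
class LandmarkPair:
    """Fovea point ``C`` and head center ``E`` for one side, one phase."""

    C: np.ndarray
    E: np.ndarray
    side: str = "affected"  # "affected" | "mirrored-reference"
    phase: str = "pre"
    fitted_radius: float | None = None
    suspect: bool = field(default=False)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64).reshape(3)
        self.E = np.asarray(self.E, dtype=np.float64).reshape(3)
        # the fovea lies on the head surface: |C - E| should be near the
        # fitted radius; a gross violation flags a mis-annotation
        if self.fitted_radius is not None:
            d = float(np.linalg.norm(self.C - self.E))
            if not (0.5 * self.fitted_radius <= d <= 1.5 * self.fitted_radius):
                self.suspect = True


INDICATORS = ("d1", "d2", "alpha", "theta_xy", "theta_xz", "theta_yz")

#: display names used in report tables
INDICATOR_TITLES = {
    "d1": "Displacement of fovea of femoral head (mm)",
    "d2": "Displacement of center of femoral head (mm)",
    "alpha": "3D angle of femoral head (deg)",
    "theta_xy": "Projection angle on the transverse plane (X-Y) (deg)",
    "theta_xz": "Projection angle on the coronal plane (X-Z) (deg)",
    "theta_yz": "Projection angle on the sagittal plane (Y-Z) (deg)",
}


@dataclass
class DisplacementMetrics:
    d1: float
    d2: float
    alpha: float
    theta_xy: float
    theta_xz: float
    theta_yz: float
    degenerate_flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in INDICATORS}


def angle_between(u, v) -> float:
    """Angle between two nonzero vectors, degrees in [0, 180].

    The normalized dot product is clamped to [-1, 1] before arccos for
    floating-point safety near 0 and 180 degrees.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("angle undefined for zero vector")
    c = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def project_angle(u, v, plane: str) -> tuple[float, bool]:
    """Angle between the orthogonal projections of ``u`` and ``v`` onto a
    coordinate plane (``"xy"``, ``"xz"``, ``"yz"``), degrees.

    If either projection is shorter than ``1e-8`` of its original norm the
    angle is undefined: returns ``(nan, True)``.  Degenerate projections are
    propagated as missing, never as zero.
    """
    if plane not in _PLANE_DROP:
        raise GeometryError(f"unknown plane {plane!r}; expected one of {PLANES}")
    u = np.asarray(u, dtype=np.float64).copy()
    v = np.asarray(v, dtype=np.float64).copy()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("projection angle undefined for zero vector")
    drop = _PLANE_DROP[plane]
    u[drop] = 0.0
    v[drop] = 0.0
    if (np.linalg.norm(u) < DEGENERATE_PROJECTION_RTOL * nu
            or np.linalg.norm(v) < DEGENERATE_PROJECTION_RTOL * nv):
        return float("nan"), True
    return angle_between(u, v), False


def compute_metrics(affected: LandmarkPair, reference: LandmarkPair) -> DisplacementMetrics:
    """The six displacement indicators from two (C, E) pairs in one frame.

    ``d1 = |C1 - C2|``, ``d2 = |E1 - E2|``; ``alpha`` is the angle between
    ``u = E1 - C1`` and ``v = E2 - C2`` (fovea→center on both sides); the
    projection angles come from :func:`project_angle`.
    """
    C1, E1 = affected.C, affected.E
    C2, E2 = reference.C, reference.E
    u = E1 - C1
    v = E2 - C2
    if np.linalg.norm(u) < 1e-12 or np.linalg.norm(v) < 1e-12:
        raise GeometryError("fovea coincides with head center: direction undefined")
    d1 = float(np.linalg.norm(C1 - C2))
    d2 = float(np.linalg.norm(E1 - E2))
    alpha = angle_between(u, v)
    flags = {}
    thetas = {}
    for plane in PLANES:
        ang, degenerate = project_angle(u, v, plane)
        thetas[plane] = ang
        flags[f"theta_{plane}"] = degenerate
    return DisplacementMetrics(
        d1=d1, d2=d2, alpha=alpha,
        theta_xy=thetas["xy"], theta_xz=thetas["xz"], theta_yz=thetas["yz"],
        degenerate_flags=flags,
    )


# ---------------------------------------------------------------------------
# Rigid registration (trimmed ICP, principal-axes initialization)
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping point set P onto Q."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def _principal_axes_candidates(src: np.ndarray, dst: np.ndarray) -> list[RigidTransform]:
    """Centroid + PCA alignments; all four proper sign assignments are returned
    because principal axes are determined only up to sign."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    _, _, Vs = np.linalg.svd(src - cs, full_matrices=False)
    _, _, Vd = np.linalg.svd(dst - cd, full_matrices=False)
    out = []
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])  # det +1
        R = Vd.T @ S @ Vs
        if np.linalg.det(R) < 0:  # guard against reflective PCA bases
            R = Vd.T @ (-S) @ Vs
        out.append(RigidTransform(R, cd - R @ cs))
    return out


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms: float
    n_iterations: int
    converged: bool


def register_rigid(moving: SurfaceMesh, fixed: SurfaceMesh,
                   exclude: int | None = LABEL_HEAD,
                   trim_fraction: float = 0.2,
                   max_iter: int = 100, tol: float = 1e-12) -> RegistrationResult:
    """Rigidly align ``moving`` onto ``fixed`` by trimmed iterative closest
    point on the vertex clouds.

    ``exclude`` drops one labeled region (by default the femoral head, i.e.
    the fracture fragment) from both clouds so the displacement being measured
    cannot bias the alignment; the fit then locks onto the trochanter/shaft
    morphology.  Initialization is centroid + principal-axes alignment; each
    iteration keeps the best ``1 - trim_fraction`` of nearest-neighbour pairs
    and solves the Kabsch problem.
    """
    def cloud(mesh: SurfaceMesh) -> np.ndarray:
        if exclude is not None and mesh.labels is not None:
            pts = mesh.vertices[mesh.labels != exclude]
        else:
            pts = mesh.vertices
        if len(pts) == 0:
            raise GeometryError("no vertices left after excluding region")
        return pts

    src = cloud(moving)
    dst = cloud(fixed)
    tree = cKDTree(dst)
    n_keep = max(3, int(round((1.0 - trim_fraction) * len(src))))

    def mean_sq(T: RigidTransform) -> float:
        d, _ = tree.query(T.apply(src))
        return float(np.mean(np.sort(d)[:n_keep] ** 2))

    T = min(_principal_axes_candidates(src, dst), key=mean_sq)

    prev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cur = T.apply(src)
        dist, idx = tree.query(cur)
        keep = np.argsort(dist)[:n_keep]
        T = _kabsch(src[keep], dst[idx[keep]])
        ms = float(np.mean(dist[keep] ** 2))
        if abs(prev - ms) <= tol * max(1.0, prev):
            converged = True
            break
        prev = ms
    dist, _ = tree.query(T.apply(src))
    rms = float(np.sqrt(np.mean(np.sort(dist)[:n_keep] ** 2)))
    return RegistrationResult(transform=T, rms=rms, n_iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# Full per-subject measurement
# ---------------------------------------------------------------------------

@dataclass
class SubjectMeasurement:
    metrics: DisplacementMetrics
    affected: LandmarkPair
    reference: LandmarkPair
    registration: RegistrationResult
    sphere_affected: SphereFit
    sphere_reference: SphereFit


def measure_subject(affected_mesh: SurfaceMesh, contralateral_mesh: SurfaceMesh,
                    fovea_affected, fovea_contralateral, phase: str = "pre",
                    mirror_plane_point=(0.0, 0.0, 0.0),
                    mirror_plane_normal=(1.0, 0.0, 0.0),
                    registration_perturbation: RigidTransform | None = None) -> SubjectMeasurement:
    """Run the complete measurement workflow for one subject.

    Steps: mirror the healthy contralateral femur across the sagittal
    midplane; register the mirror onto the affected side with the head region
    excluded; fit spheres to both head regions; assemble landmark pairs
    (annotated fovea + fitted center) and compute the six indicators.  All
    intermediates (registration transform and RMS, sphere residuals) are
    returned for audit.

    ``registration_perturbation`` composes a small rigid error onto the
    registration result; observer simulations use it to emulate imperfect
    manual alignment (the automatic fit itself is deterministic).
    """
    if affected_mesh.labels is None or contralateral_mesh.labels is None:
        raise GeometryError("measure_subject requires head-labeled meshes")

    mirrored = mirror_mesh(contralateral_mesh, mirror_plane_point, mirror_plane_normal)
    fovea_ref = mirror_points(np.asarray(fovea_contralateral, dtype=np.float64),
                              mirror_plane_point, mirror_plane_normal)

    try:
        reg = register_rigid(mirrored, affected_mesh, exclude=LABEL_HEAD)
    except GeometryError as exc:
        raise GeometryError(f"registration stage failed: {exc}") from exc
    T = reg.transform
    if registration_perturbation is not None:
        T = registration_perturbation.compose(T)

    try:
        fit_aff = fit_sphere(affected_mesh.region_vertices(LABEL_HEAD))
        fit_ref = fit_sphere(T.apply(mirrored.region_vertices(LABEL_HEAD)))
    except SphereFitError as exc:
        raise SphereFitError(f"sphere-fit stage failed: {exc}") from exc

    affected = LandmarkPair(C=np.asarray(fovea_affected, dtype=np.float64),
                            E=fit_aff.center, side="affected", phase=phase,
                            fitted_radius=fit_aff.radius)
    reference = LandmarkPair(C=T.apply(fovea_ref), E=fit_ref.center,
                             side="mirrored-reference", phase=phase,
                             fitted_radius=fit_ref.radius)
    metrics = compute_metrics(affected, reference)
    return SubjectMeasurement(metrics=metrics, affected=affected, reference=reference,
                              registration=reg, sphere_affected=fit_aff,
                              sphere_reference=fit_ref)
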
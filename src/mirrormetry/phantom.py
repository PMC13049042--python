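"""Synthetic bilateral proximal-femur phantoms and observer-error simulation.

The phantom is the minimal geometry that exercises every pipeline stage: a
spherical femoral head carrying a fovea landmark, a cylindrical neck and
shaft, a greater-trochanter ellipsoid (an asymmetric feature for registration
to lock onto) and a posteromedial lesser-trochanter bump (breaks the
anterior–posterior mirror symmetry so principal-axes initialization is
unambiguous).  Left and right femurs are exact mirror images across the
sagittal midplane x = 0, which is the symmetry assumption the whole
contralateral-referencing method rests on.

A fracture is a rigid displacement of the head fragment (rotation about a
pivot, then translation).  Ground-truth indicator values follow in closed
form from the transform, so the full mesh pipeline can be validated against
them.  Observer error is simulated at the stage where each error physically
enters: isotropic jitter on the fovea annotation, a small random rigid
perturbation standing in for imperfect mirror registration, and jitter on
the fitted head center.

All randomness flows through explicit integer seeds; identical seeds give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .agreement import MeasurementMatrix
from .geometry import (
    INDICATORS,
    DisplacementMetrics,
    LandmarkPair,
    RigidTransform,
    compute_metrics,
)
from .mesh import LABEL_HEAD, LABEL_NECK_SHAFT, SurfaceMesh, concatenate, mirror_mesh


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mesh primitives (welded, closed)
# ---------------------------------------------------------------------------

def _uv_sphere(center, radius: float, edge_length: float) -> SurfaceMesh:
    center = np.asarray(center, dtype=np.float64)
    n_theta = max(8, int(math.ceil(math.pi * radius / edge_length)))
    n_phi = max(12, int(math.ceil(2 * math.pi * radius / edge_length)))
    verts = [center + np.array([0.0, 0.0, radius])]
    for i in range(1, n_theta):
        th = math.pi * i / n_theta
        for j in range(n_phi):
            ph = 2 * math.pi * j / n_phi
            verts.append(center + radius * np.array(
                [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]))
    verts.append(center + np.array([0.0, 0.0, -radius]))
    south = len(verts) - 1

    def ring(i, j):
        return 1 + (i - 1) * n_phi + (j % n_phi)

    faces = []
    for j in range(n_phi):
        faces.append([0, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_theta - 1):
        for j in range(n_phi):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    for j in range(n_phi):
        faces.append([south, ring(n_theta - 1, j + 1), ring(n_theta - 1, j)])
    return SurfaceMesh(np.array(verts), np.array(faces))


def _ellipsoid(center, semi_axes, edge_length: float) -> SurfaceMesh:
    semi = np.asarray(semi_axes, dtype=np.float64)
    sph = _uv_sphere((0, 0, 0), 1.0, edge_length / float(semi.max()))
    verts = sph.vertices * semi + np.asarray(center, dtype=np.float64)
    return SurfaceMesh(verts, sph.faces)


def _cylinder(p0, p1, radius: float, edge_length: float) -> SurfaceMesh:
    """Capped cylinder from p0 to p1 with outward orientation."""
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    if length < 1e-12:
        raise PhantomError("degenerate cylinder")
    z = axis / length
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    n_circ = max(12, int(math.ceil(2 * math.pi * radius / edge_length)))
    n_len = max(2, int(math.ceil(length / edge_length)))
    verts = []
    for i in range(n_len + 1):
        c = p0 + axis * (i / n_len)
        for j in range(n_circ):
            ph = 2 * math.pi * j / n_circ
            verts.append(c + radius * (math.cos(ph) * x + math.sin(ph) * y))
    base_c = len(verts)
    verts.append(p0)
    top_c = len(verts)
    verts.append(p1)

    def idx(i, j):
        return i * n_circ + (j % n_circ)

    faces = []
    for i in range(n_len):
        for j in range(n_circ):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j), idx(i + 1, j + 1)
            faces.append([a, b, c])
            faces.append([b, d, c])
    for j in range(n_circ):
        faces.append([base_c, idx(0, j + 1), idx(0, j)])
        faces.append([top_c, idx(n_len, j), idx(n_len, j + 1)])
    return SurfaceMesh(np.array(verts), np.array(faces))


# ---------------------------------------------------------------------------
# Phantom specification and construction
# ---------------------------------------------------------------------------

@dataclass
class FemurPhantomSpec:
    """Dimensions of the synthetic proximal femur (mm / degrees).

    Defaults approximate an adult femur: 24 mm head radius, 35 mm neck,
    90 mm of proximal shaft.  ``fovea_colatitude`` is measured from the
    superior pole of the head; ``fovea_longitude`` sweeps from the medial
    direction toward posterior, placing the fovea on the posteroinferior
    medial head surface.  Meshing is deterministic: the seed exists for API
    symmetry and does not affect vertex placement.
    """

    head_radius: float = 24.0
    neck_length: float = 35.0
    shaft_length: float = 90.0
    shaft_radius: float = 14.0
    fovea_colatitude: float = 100.0
    fovea_longitude: float = 10.0
    mesh_resolution: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("head_radius", "neck_length", "shaft_length",
                     "shaft_radius", "mesh_resolution"):
            if getattr(self, name) <= 0:
                raise PhantomError(f"invalid spec: {name} must be positive")

    # canonical right-femur landmark geometry (head center chosen 50 mm
    # lateral of the midline so the mirror plane x = 0 separates the sides)
    def head_center(self) -> np.ndarray:
        return np.array([50.0, 0.0, 0.0])

    def fovea_point(self) -> np.ndarray:
        th = math.radians(self.fovea_colatitude)
        ph = math.radians(self.fovea_longitude)
        u = np.array([-math.sin(th) * math.cos(ph),
                      -math.sin(th) * math.sin(ph),
                      math.cos(th)])
        return self.head_center() + self.head_radius * u


def make_femur_phantom(spec: FemurPhantomSpec) -> tuple[SurfaceMesh, SurfaceMesh, dict]:
    """Build the bilateral phantom.

    Returns ``(left, right, landmarks)`` where the right femur occupies
    x > 0, the left femur is its exact reflection across x = 0, and
    ``landmarks[side]`` holds the exact fovea point ``C`` and head-sphere
    center ``E`` in mm.
    """
    res = spec.mesh_resolution
    E = spec.head_center()
    neck_dir = np.array([1.0, 0.0, -0.6])
    neck_dir /= np.linalg.norm(neck_dir)
    neck_radius = 0.55 * spec.head_radius
    neck_start = E + 0.5 * spec.head_radius * neck_dir
    troch = E + (0.5 * spec.head_radius + spec.neck_length) * neck_dir

    head = _uv_sphere(E, spec.head_radius, res)
    head.labels = np.full(head.n_vertices, LABEL_HEAD, dtype=np.int64)
    neck = _cylinder(neck_start, troch, neck_radius, res)
    shaft = _cylinder(troch + np.array([0, 0, 6.0]),
                      troch + np.array([0, 0, -spec.shaft_length]),
                      spec.shaft_radius, res)
    greater = _ellipsoid(troch + np.array([0.5 * spec.shaft_radius, 0.0, 10.0]),
                         (10.0, 9.0, 15.0), res)
    lesser = _ellipsoid(troch + np.array([-4.0, -0.9 * spec.shaft_radius, -22.0]),
                        (6.0, 7.0, 9.0), res)
    for part in (neck, shaft, greater, lesser):
        part.labels = np.full(part.n_vertices, LABEL_NECK_SHAFT, dtype=np.int64)

    right = concatenate([head, neck, shaft, greater, lesser])
    left = mirror_mesh(right, (0.0, 0.0, 0.0), (1.0, 0.0, 0.0))

    C = spec.fovea_point()
    landmarks = {
        "right": {"C": C.copy(), "E": E.copy()},
        "left": {"C": C * np.array([-1.0, 1.0, 1.0]),
                 "E": E * np.array([-1.0, 1.0, 1.0])},
    }
    return left, right, landmarks


# ---------------------------------------------------------------------------
# Applied displacement and ground truth
# ---------------------------------------------------------------------------

@dataclass
class AppliedDisplacement:
    """Known rigid displacement of the head fragment: rotation of
    ``rotation_angle`` degrees about ``rotation_axis`` through ``pivot``,
    followed by ``translation``."""

    translation: np.ndarray
    rotation_axis: np.ndarray
    rotation_angle: float
    pivot: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.pivot = np.asarray(self.pivot, dtype=np.float64).reshape(3)
        axis = np.asarray(self.rotation_axis, dtype=np.float64).reshape(3)
        n = np.linalg.norm(axis)
        if not math.isfinite(n) or abs(n - 1.0) > 1e-6:
            if n < 1e-12:
                raise PhantomError("rotation axis must be a unit vector")
            axis = axis / n
        else:
            axis = axis / n  # renormalize to 1e-9
        self.rotation_axis = axis
        if not (0.0 <= self.rotation_angle <= 180.0):
            raise PhantomError("rotation angle must lie in [0, 180] degrees")

    @classmethod
    def identity(cls, pivot=(0, 0, 0)) -> "AppliedDisplacement":
        return cls(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0, pivot)

    def to_transform(self) -> RigidTransform:
        return RigidTransform.from_axis_angle(self.rotation_axis, self.rotation_angle,
                                              pivot=self.pivot, translation=self.translation)


def apply_displacement(mesh: SurfaceMesh, landmarks: dict,
                       disp: AppliedDisplacement) -> tuple[SurfaceMesh, dict]:
    """Rigidly displace the head fragment (head-labeled vertices plus the
    C/E landmarks); the distal region is untouched."""
    if mesh.labels is None:
        raise PhantomError("mesh carries no region labels; head fragment undefined")
    T = disp.to_transform()
    out = mesh.copy()
    head = out.labels == LABEL_HEAD
    out.vertices[head] = T.apply(out.vertices[head])
    moved = {"C": T.apply(landmarks["C"]), "E": T.apply(landmarks["E"])}
    return out, moved


def ground_truth_metrics(disp: AppliedDisplacement, C, E) -> DisplacementMetrics:
    """Closed-form indicator values for a known displacement:
    the displaced pair (T(C), T(E)) against the undisturbed reference (C, E)."""
    C = np.asarray(C, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    if np.linalg.norm(C - E) < 1e-12:
        raise PhantomError("C and E must be distinct")
    T = disp.to_transform()
    affected = LandmarkPair(C=T.apply(C), E=T.apply(E), side="affected")
    reference = LandmarkPair(C=C, E=E, side="mirrored-reference")
    return compute_metrics(affected, reference)


# ---------------------------------------------------------------------------
# Study-level simulation
# ---------------------------------------------------------------------------

@dataclass
class DisplacementDistribution:
    """Between-subject distribution of true fracture displacements.

    Translation direction is uniform on the sphere with a log-normal
    magnitude (strictly positive, right-skewed); rotation axis is uniform
    with a folded-normal angle.  Parameters are the target mean/SD on the
    natural scale (mm for translation, degrees for rotation).
    """

    translation_mean: float
    translation_sd: float
    angle_mean: float
    angle_sd: float

    @classmethod
    def preoperative(cls) -> "DisplacementDistribution":
        # typical fracture-cohort scale: head-center displacement ~13.5 ± 7.4 mm,
        # 3D angle ~27 ± 12 deg before reduction
        return cls(13.48, 7.41, 26.94, 12.12)

    @classmethod
    def postoperative(cls) -> "DisplacementDistribution":
        # residual displacement after reduction: ~5.5 ± 1.9 mm, ~13 ± 6 deg
        return cls(5.51, 1.92, 12.84, 5.57)

    def sample(self, rng: np.random.Generator, pivot) -> AppliedDisplacement:
        mu = math.log(self.translation_mean**2 /
                      math.sqrt(self.translation_mean**2 + self.translation_sd**2))
        s = math.sqrt(math.log(1.0 + (self.translation_sd / self.translation_mean) ** 2))
        magnitude = float(rng.lognormal(mu, s))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = min(abs(float(rng.normal(self.angle_mean, self.angle_sd))), 180.0)
        return AppliedDisplacement(magnitude * direction, axis, angle, pivot)


@dataclass
class ObserverModel:
    """Per-observer measurement-error model (all SDs >= 0).

    ``fovea_jitter_sd`` — isotropic error of the manual fovea annotation, mm;
    ``registration_rot_sd`` / ``registration_trans_sd`` — small random rigid
    perturbation standing in for imperfect mirror registration (degrees, mm);
    ``center_jitter_sd`` — residual error of the fitted head center, mm.
    All SDs zero reproduces ground truth exactly.
    """

    fovea_jitter_sd: float = 1.0
    registration_rot_sd: float = 1.0
    registration_trans_sd: float = 0.5
    center_jitter_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fovea_jitter_sd", "registration_rot_sd",
                     "registration_trans_sd", "center_jitter_sd"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be >= 0")


@dataclass
class SyntheticStudySpec:
    """Design of a synthetic multi-observer reliability study."""

    n_subjects: int = 100
    n_observers: int = 3
    pre: DisplacementDistribution = field(default_factory=DisplacementDistribution.preoperative)
    post: DisplacementDistribution = field(default_factory=DisplacementDistribution.postoperative)
    observer_models: list[ObserverModel] | None = None
    phantom: FemurPhantomSpec = field(default_factory=FemurPhantomSpec)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_observers < 2:
            raise PhantomError("need at least 2 subjects and 2 observers")
        if self.observer_models is None:
            self.observer_models = [ObserverModel(rng_seed=j)
                                    for j in range(self.n_observers)]
        if len(self.observer_models) != self.n_observers:
            raise PhantomError("one observer model per observer required")


def _random_small_rigid(rng: np.random.Generator, rot_sd_deg: float,
                        trans_sd_mm: float, pivot) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = float(rng.normal(0.0, rot_sd_deg)) if rot_sd_deg > 0 else 0.0
    trans = rng.normal(0.0, trans_sd_mm, size=3) if trans_sd_mm > 0 else np.zeros(3)
    return RigidTransform.from_axis_angle(axis, angle, pivot=pivot, translation=trans)


def observe_landmarks(truth_affected: LandmarkPair, truth_reference: LandmarkPair,
                      model: ObserverModel, rng: np.random.Generator) -> DisplacementMetrics:
    """One observer's noisy measurement from true landmark geometry.

    The registration perturbation acts on the mirrored-reference pair (that
    is the object registration places); fovea jitter hits both annotated
    foveae; center jitter hits both fitted centers.  With all SDs zero the
    ground-truth metrics are returned exactly.
    """
    G = _random_small_rigid(rng, model.registration_rot_sd,
                            model.registration_trans_sd, pivot=truth_reference.E)

    def jitter(sd):
        return rng.normal(0.0, sd, size=3) if sd > 0 else np.zeros(3)

    C1 = truth_affected.C + jitter(model.fovea_jitter_sd)
    E1 = truth_affected.E + jitter(model.center_jitter_sd)
    C2 = G.apply(truth_reference.C) + jitter(model.fovea_jitter_sd)
    E2 = G.apply(truth_reference.E) + jitter(model.center_jitter_sd)
    return compute_metrics(LandmarkPair(C=C1, E=E1, side="affected"),
                           LandmarkPair(C=C2, E=E2, side="mirrored-reference"))


_PHASE_CODE = {"pre": 1, "post": 2}


def sample_true_displacements(study: SyntheticStudySpec, phase: str) -> list[AppliedDisplacement]:
    """The per-subject true displacements of one phase (deterministic in the
    study seed, shared by the landmark and mesh measurement routes)."""
    if phase not in _PHASE_CODE:
        raise PhantomError(f"phase must be 'pre' or 'post', got {phase!r}")
    dist = study.pre if phase == "pre" else study.post
    E = study.phantom.head_center()
    rng = np.random.default_rng([study.rng_seed, _PHASE_CODE[phase], 101])
    return [dist.sample(rng, pivot=E) for _ in range(study.n_subjects)]


def simulate_observer_measurements(study: SyntheticStudySpec,
                                   phase: str) -> dict[str, MeasurementMatrix]:
    """Simulate the full subjects × observers measurement matrix per indicator.

    For each subject a true head-fragment displacement is drawn from the
    phase's between-subject distribution; each observer independently
    measures it through their noise model (registration perturbation, fovea
    and center jitter).  Matrices carry the generating seed and parameters in
    ``meta``.
    """
    disps = sample_true_displacements(study, phase)
    C = study.phantom.fovea_point()
    E = study.phantom.head_center()
    n, k = study.n_subjects, study.n_observers
    values = {ind: np.empty((n, k)) for ind in INDICATORS}

    reference = LandmarkPair(C=C, E=E, side="mirrored-reference", phase=phase)
    obs_rngs = [np.random.default_rng([study.rng_seed, _PHASE_CODE[phase], 211,
                                       model.rng_seed])
                for model in study.observer_models]
    for i, disp in enumerate(disps):
        T = disp.to_transform()
        truth = LandmarkPair(C=T.apply(C), E=T.apply(E), side="affected", phase=phase)
        for j, model in enumerate(study.observer_models):
            metrics = observe_landmarks(truth, reference, model, obs_rngs[j])
            for ind in INDICATORS:
                values[ind][i, j] = getattr(metrics, ind)

    meta = {"seed": study.rng_seed, "phase": phase, "mode": "landmark",
            "n_subjects": n, "n_observers": k}
    return {ind: MeasurementMatrix(values[ind], indicator=ind, phase=phase,
                                   observer_ids=list(range(1, k + 1)), meta=dict(meta))
            for ind in INDICATORS}


def simulate_matrix_from_components(n_subjects: int, n_observers: int,
                                    sigma2_s: float, sigma2_r: float, sigma2_e: float,
                                    mean: float = 0.0,
                                    rng: np.random.Generator | int | None = None,
                                    indicator: str = "", phase: str = "") -> MeasurementMatrix:
    """Matrix drawn from the additive two-way random-effects model
    ``y_ij = mean + s_i + r_j + e_ij`` with known variance components, for
    which the theoretical ICC(A,k) is exactly
    ``sigma2_s / (sigma2_s + sigma2_r/k + sigma2_e/k)``."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = rng.normal(0.0, math.sqrt(sigma2_s), size=(n_subjects, 1))
    r = rng.normal(0.0, math.sqrt(sigma2_r), size=(1, n_observers))
    e = rng.normal(0.0, math.sqrt(sigma2_e), size=(n_subjects, n_observers))
    return MeasurementMatrix(mean + s + r + e, indicator=indicator, phase=phase,
                             meta={"sigma2_s": sigma2_s, "sigma2_r": sigma2_r,
                                   "sigma2_e": sigma2_e, "mode": "components"})


def components_for_icc_avg(target_icc: float, k: int,
                           sigma2_r: float = 0.2, sigma2_e: float = 0.8) -> tuple[float, float, float]:
    """Choose a subject variance so that ICC(A,k) at the given noise
    components equals ``target_icc`` exactly."""
    if not (0 < target_icc < 1):
        raise PhantomError("target ICC must lie strictly between 0 and 1")
    sigma2_s = target_icc * (sigma2_r + sigma2_e) / (k * (1.0 - target_icc))
    return sigma2_s, sigma2_r, sigma2_e
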
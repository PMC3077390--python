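"""Synthetic diffusion phantoms and cohorts with known ground truth.

The real study this pipeline emulates acquired 15 diffusion-weighted volumes
at b = 800 s/mm^2 plus one b = 0 baseline in 33 patients with schizophrenia
and 31 matched controls, and measured FA/RD/AD along limbic bundles.  Here
every downstream stage is validated against phantoms: curved tubes of
anisotropic tensors embedded in an isotropic background, pushed through the
forward signal model ``S = S0 * exp(-b g^T D g)`` with Rician noise, for
cohorts whose group effect is confined to a known arc-length segment and
whose clinical scores are coupled to the tract's FA at a known locus.

Two cohort generators are provided:

* :func:`make_cohort` - image level: per-subject tensor fields and DWI
  volumes, for end-to-end pipeline runs.
* :func:`simulate_profile_cohort` - profile level: per-subject 30-point
  metric profiles drawn directly from the generative model (subject-level
  random intercept plus independent pointwise measurement noise), for the
  replicated error-rate and power simulations where simulating images would
  add nothing but runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ImageGrid, TensorVolume, matrices_to_tensor_coeffs

__all__ = [
    "GradientScheme",
    "PhantomSpec",
    "CohortSpec",
    "Cohort",
    "default_scheme",
    "make_phantom",
    "simulate_dwi",
    "make_cohort",
    "simulate_profile_cohort",
    "straight_centerline",
    "arc_centerline",
    "save_dwi",
    "load_dwi",
    "TABLE1_COVARIATES",
    "PANSS_DISTRIBUTIONS",
]

# Fixed 15-direction set obtained by electrostatic (antipodally symmetric)
# repulsion on the sphere; minimum pairwise angle 36.9 deg.  The acquisition
# being emulated used a vendor scheme that was never published, so a
# reproducible hard-coded set is used instead.
_DIRECTIONS_15 = np.array(
    [
        (+0.72955180, +0.68202708, +0.05092373),
        (+0.34795457, -0.93151880, +0.10583167),
        (-0.97364973, +0.06483911, +0.21863691),
        (+0.81934014, -0.50362456, +0.27394166),
        (+0.09076111, +0.93170850, +0.35168408),
        (-0.24979967, -0.89104250, +0.37900314),
        (+0.91154702, +0.12066266, +0.39309357),
        (-0.59946065, +0.68167301, +0.41948640),
        (-0.69501223, -0.46154612, +0.55130135),
        (+0.50362690, +0.56055319, +0.65737361),
        (+0.30403216, -0.65012523, +0.69634879),
        (-0.62184981, +0.15286857, +0.76807162),
        (+0.46940814, -0.05777851, +0.88108890),
        (-0.07723221, +0.45424232, +0.88752414),
        (-0.16469056, -0.28744680, +0.94353132),
    ]
)

#: Group-wise covariate distributions (mean, SD) mirroring the demographics
#: of the emulated study sample: 31 controls, 33 patients.
TABLE1_COVARIATES = {
    "age": {"control": (35.4, 8.82), "patient": (39.4, 8.82)},
    "education": {"control": (13.9, 2.50), "patient": (11.6, 2.40)},
    "duration": {"control": (0.0, 0.0), "patient": (12.7, 8.99)},
}

#: PANSS subscale and GAF distributions (mean, SD) for the patient group.
PANSS_DISTRIBUTIONS = {
    "panss_positive": (10.1, 3.28),
    "panss_negative": (8.7, 2.68),
    "panss_general": (19.9, 4.17),
    "gaf": (53.6, 17.5),
}
# PANSS total, when it must be generated directly (because a coupling targets
# it), uses the sum of the subscale means and the independent-sum SD.
_PANSS_TOTAL_MEAN = sum(PANSS_DISTRIBUTIONS[k][0] for k in
                        ("panss_positive", "panss_negative", "panss_general"))
_PANSS_TOTAL_SD = float(np.sqrt(sum(PANSS_DISTRIBUTIONS[k][1] ** 2 for k in
                                    ("panss_positive", "panss_negative", "panss_general"))))


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: unit directions and b-values per volume."""

    directions: np.ndarray  # (n, 3)
    bvalues: np.ndarray  # (n,), s/mm^2

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if d.shape != (b.size, 3):
            raise ValueError("directions must be (n, 3) matching n b-values")
        dw = b > 0
        if dw.sum() < 6:
            raise ValueError("need at least 6 diffusion-weighted directions")
        if (~dw).sum() < 1:
            raise ValueError("need at least one b=0 baseline volume")
        norms = np.linalg.norm(d[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit-norm")
        # non-collinearity: the 6-parameter tensor design must have full rank
        if np.linalg.matrix_rank(design_matrix(d[dw], b[dw])) < 6:
            raise ValueError("diffusion directions are collinear; tensor not identifiable")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)

    @property
    def n_volumes(self) -> int:
        return int(self.bvalues.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    def save(self, bvec_path, bval_path) -> None:
        """Write FSL-style bvec (3 rows) / bval (1 row) text files."""
        np.savetxt(str(bvec_path), self.directions.T, fmt="%.8f")
        np.savetxt(str(bval_path), self.bvalues[None, :], fmt="%.1f")

    @classmethod
    def load(cls, bvec_path, bval_path) -> "GradientScheme":
        d = np.loadtxt(str(bvec_path)).T
        b = np.atleast_1d(np.loadtxt(str(bval_path)))
        return cls(directions=d, bvalues=b)


def design_matrix(directions: np.ndarray, bvalues: np.ndarray) -> np.ndarray:
    """Rows ``b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)`` so that
    ``row . coeffs = b * g^T D g`` for the 6-coefficient tensor layout."""
    g = np.atleast_2d(directions)
    b = np.atleast_1d(bvalues)
    return b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def default_scheme(bvalue: float = 800.0) -> GradientScheme:
    """The emulated acquisition: 1 baseline + 15 directions at b = 800 s/mm^2."""
    dirs = np.vstack([np.zeros(3), _DIRECTIONS_15])
    bvals = np.concatenate([[0.0], np.full(15, float(bvalue))])
    return GradientScheme(directions=dirs, bvalues=bvals)


# ---------------------------------------------------------------------------
# phantoms


def straight_centerline(start, stop, n: int = 200) -> np.ndarray:
    """Straight polyline between two world-mm points."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(start, float) + t * (np.asarray(stop, float) - np.asarray(start, float))


def arc_centerline(center, radius: float, theta0: float, theta1: float,
                   plane: str = "xy", offset: float = 0.0, n: int = 400) -> np.ndarray:
    """Circular-arc polyline (e.g. a C-shaped cingulum-like course)."""
    th = np.linspace(theta0, theta1, n)
    c = np.asarray(center, float)
    pts = np.full((n, 3), offset)
    ax = {"xy": (0, 1, 2), "yz": (1, 2, 0), "xz": (0, 2, 1)}[plane]
    pts[:, ax[0]] = c[ax[0]] + radius * np.cos(th)
    pts[:, ax[1]] = c[ax[1]] + radius * np.sin(th)
    pts[:, ax[2]] = c[ax[2]] + offset
    return pts


@dataclass
class PhantomSpec:
    """A curved-tube tensor phantom with an optional localized patient effect.

    ``effect_segment`` is the arc-length fraction interval of the centerline
    where affected subjects get ``effect_delta`` added to the two minor
    eigenvalues (radial diffusivity up, FA down, axial diffusivity
    unchanged), mirroring the fornix signature the pipeline is built to
    detect.
    """

    grid_shape: tuple[int, int, int] = (40, 16, 16)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    centerline: np.ndarray = None  # type: ignore[assignment]
    tube_radius: float = 4.0
    inside_eigenvalues: tuple[float, float, float] = (1.5e-3, 0.3e-3, 0.3e-3)
    outside_eigenvalue: float = 0.7e-3
    effect_segment: tuple[float, float] = (0.4, 0.6)
    effect_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.centerline is None:
            # default: straight tube along x through the grid centre
            gs, vs = np.asarray(self.grid_shape), np.asarray(self.voxel_size)
            mid = gs * vs / 2.0
            pad = self.tube_radius + 1.5 * vs[0]
            self.centerline = straight_centerline(
                [pad, mid[1], mid[2]], [gs[0] * vs[0] - pad, mid[1], mid[2]]
            )
        self.centerline = np.asarray(self.centerline, dtype=float)
        l1, l2, l3 = self.inside_eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("inside eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        lo, hi = self.effect_segment
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("effect_segment must be 0 <= lo < hi <= 1")
        if l2 + self.effect_delta > l1:
            raise ValueError("effect_delta would push the minor eigenvalue above the major one")
        if l3 + self.effect_delta <= 0:
            raise ValueError("effect_delta would make an eigenvalue non-positive")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(shape=tuple(self.grid_shape), voxel_size=tuple(self.voxel_size))


def _centerline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _centerline_tangents(points: np.ndarray) -> np.ndarray:
    tang = np.gradient(points, axis=0)
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    return tang / np.where(norms > 0, norms, 1.0)


def make_phantom(spec: PhantomSpec, effect_delta: float | None = None,
                 radial_shift: float = 0.0):
    """Rasterise a tube phantom into a tensor field.

    Voxels whose centre lies within ``tube_radius`` of the centerline get a
    tensor with eigenvalues ``inside_eigenvalues`` and principal axis along
    the local centerline tangent; all other voxels are isotropic with
    ``outside_eigenvalue``.  ``effect_delta`` (defaults to the spec's value)
    plus ``radial_shift`` (a subject-level offset applied tube-wide) are
    added to the minor eigenvalues; the delta applies only inside
    ``effect_segment``.

    Returns ``(TensorVolume, tube mask, dict of centerline ground truth)``.
    """
    if effect_delta is None:
        effect_delta = spec.effect_delta
    grid = spec.grid
    cl = spec.centerline
    arc = _centerline_arclength(cl)
    if arc[-1] <= 0:
        raise ValueError("centerline has zero length")
    frac = arc / arc[-1]
    tang = _centerline_tangents(cl)

    ext = grid.extent
    margin = np.minimum(cl.min(axis=0) - ext[:, 0], ext[:, 1] - cl.max(axis=0))
    if np.any(margin < spec.tube_radius):
        raise ValueError("tube exits the grid; enlarge the grid or shrink the tube")

    centers = grid.voxel_centers().reshape(-1, 3)
    tree = cKDTree(cl)
    dist, nearest = tree.query(centers)
    # flat end caps: voxels that project onto a centerline endpoint belong to
    # the (spherical) overhang beyond the tube ends and are excluded, so the
    # tube's extent matches the ground-truth centerline
    inside = (dist <= spec.tube_radius) & (nearest > 0) & (nearest < cl.shape[0] - 1)
    vox_frac = frac[nearest]

    l1, l2, l3 = spec.inside_eigenvalues
    lo, hi = spec.effect_segment
    in_segment = inside & (vox_frac >= lo) & (vox_frac <= hi)

    lam2 = np.full(centers.shape[0], l2) + radial_shift
    lam3 = np.full(centers.shape[0], l3) + radial_shift
    lam2[in_segment] += effect_delta
    lam3[in_segment] += effect_delta
    if np.any(lam2[inside] > l1) or np.any(lam3[inside] <= 0):
        raise ValueError("eigenvalue perturbation violates l1 >= l2 >= l3 > 0")

    # build tensors: D = l1 t t^T + l2 u u^T + l3 v v^T with (t, u, v) an
    # orthonormal frame whose first axis is the local tangent
    t = tang[nearest]
    helper = np.tile(np.array([0.0, 0.0, 1.0]), (centers.shape[0], 1))
    parallel = np.abs(np.einsum("ij,ij->i", t, helper)) > 0.9
    helper[parallel] = [0.0, 1.0, 0.0]
    u = np.cross(t, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(t, u)

    D = (
        l1 * np.einsum("ni,nj->nij", t, t)
        + lam2[:, None, None] * np.einsum("ni,nj->nij", u, u)
        + lam3[:, None, None] * np.einsum("ni,nj->nij", v, v)
    )
    D[~inside] = spec.outside_eigenvalue * np.eye(3)

    coeffs = matrices_to_tensor_coeffs(D).reshape(*grid.shape, 6)
    mask = inside.reshape(grid.shape)
    truth = {
        "centerline": cl,
        "arc_fraction": frac,
        "tangents": tang,
        "voxel_arc_fraction": vox_frac.reshape(grid.shape),
        "effect_segment": (lo, hi),
    }
    return TensorVolume(coeffs=coeffs, grid=grid), mask, truth


# ---------------------------------------------------------------------------
# forward signal model


def simulate_dwi(tensors: TensorVolume, scheme: GradientScheme, s0: float = 1000.0,
                 noise_sigma: float = 0.0, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward-simulate the acquisition: ``S = S0 exp(-b g^T D g)``.

    ``noise_sigma`` is the Rician noise level as a fraction of ``s0``; when
    positive the magnitude signal becomes ``sqrt((S + e1)^2 + e2^2)`` with
    ``e1, e2 ~ N(0, (noise_sigma * s0)^2)``.  Returns a 4D (x, y, z, volume)
    array.
    """
    if s0 < 0:
        raise ValueError("baseline signal s0 must be nonnegative")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    B = design_matrix(scheme.directions, scheme.bvalues)  # (n, 6)
    q = np.einsum("...c,nc->...n", tensors.coeffs, B)  # b * g^T D g
    signal = s0 * np.exp(-q)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        sd = noise_sigma * s0
        e1 = rng.normal(0.0, sd, size=signal.shape)
        e2 = rng.normal(0.0, sd, size=signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2 ** 2)
    return signal


def save_dwi(path, data: np.ndarray, grid: ImageGrid) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine), str(path))


def load_dwi(path):
    img = nib.load(str(path))
    from .core import grid_from_affine

    data = np.asanyarray(img.dataobj, dtype=float)
    return data, grid_from_affine(data.shape, img.affine)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortSpec:
    """Study-cohort description: group sizes, covariates, noise, couplings.

    ``panss_coupling`` maps a clinical-score column to the target correlation
    between that score and the subject's true FA at the designated locus
    (image level) or to the target raw-profile partial correlation at the
    locus (profile level); negative values encode "lower FA, worse symptoms".
    """

    n_control: int = 31
    n_patient: int = 33
    covariate_distributions: dict = field(default_factory=lambda: TABLE1_COVARIATES)
    panss_coupling: dict = field(default_factory=dict)
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_patient < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def _draw_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    dists = spec.covariate_distributions
    for group, n in (("control", spec.n_control), ("patient", spec.n_patient)):
        for i in range(n):
            rec = {"id": f"{group[:3]}{i:03d}", "group": group}
            for cov in ("age", "education", "duration"):
                mean, sd = dists[cov][group]
                rec[cov] = max(0.0, rng.normal(mean, sd)) if sd > 0 else mean
            rows.append(rec)
    return pd.DataFrame(rows)


def _coupled_scores(spec: CohortSpec, latent_std: np.ndarray,
                    rng: np.random.Generator, attenuation: float = 1.0) -> pd.DataFrame:
    """Generate patient clinical scores, optionally coupled to a standardized
    latent FA deviation.  ``attenuation`` converts the requested coupling
    (stated against an observable that carries extra noise) into the latent
    correlation: latent rho = coupling / attenuation, requiring |rho| <= 1."""
    n = latent_std.size
    scores = {}
    subscales = ("panss_positive", "panss_negative", "panss_general")
    for name in subscales + ("gaf",):
        mean, sd = PANSS_DISTRIBUTIONS[name]
        c = spec.panss_coupling.get(name, 0.0)
        rho = c / attenuation
        if abs(rho) > 1:
            raise ValueError(f"coupling {c} for {name} is unattainable (needs |rho| <= 1)")
        z = rng.normal(size=n)
        scores[name] = mean + sd * (rho * latent_std + np.sqrt(1 - rho ** 2) * z)
    if "panss_total" in spec.panss_coupling:
        c = spec.panss_coupling["panss_total"]
        rho = c / attenuation
        if abs(rho) > 1:
            raise ValueError("coupling for panss_total is unattainable (needs |rho| <= 1)")
        z = rng.normal(size=n)
        scores["panss_total"] = _PANSS_TOTAL_MEAN + _PANSS_TOTAL_SD * (
            rho * latent_std + np.sqrt(1 - rho ** 2) * z
        )
    else:
        scores["panss_total"] = (
            scores["panss_positive"] + scores["panss_negative"] + scores["panss_general"]
        )
    return pd.DataFrame(scores)


def _true_fa(l1: float, l2: float, l3: float) -> float:
    lam = np.array([l1, l2, l3])
    mean = lam.mean()
    denom = np.sum(lam ** 2)
    return float(np.sqrt(1.5 * np.sum((lam - mean) ** 2) / denom)) if denom > 0 else 0.0


@dataclass
class Cohort:
    """An image-level synthetic cohort.

    Per-subject DWI volumes are realised lazily (:meth:`subject_dwi`) so that
    large cohorts of records can be drawn without materialising images.
    """

    phantom: PhantomSpec
    spec: CohortSpec
    scheme: GradientScheme
    subjects: pd.DataFrame
    truth: dict
    s0: float = 1000.0
    #: SD of the subject-level tube-wide perturbation of the minor
    #: eigenvalues (mm^2/s); the source of between-subject FA variation.
    radial_jitter_sd: float = 0.02e-3

    def subject_tensors(self, subject_id: str) -> TensorVolume:
        row = self.subjects.set_index("id").loc[subject_id]
        delta = self.phantom.effect_delta if row["group"] == "patient" else 0.0
        tensors, _, _ = make_phantom(self.phantom, effect_delta=delta,
                                     radial_shift=row["radial_shift"])
        return tensors

    def subject_dwi(self, subject_id: str) -> np.ndarray:
        row = self.subjects.set_index("id").loc[subject_id]
        tensors = self.subject_tensors(subject_id)
        return simulate_dwi(tensors, self.scheme, s0=self.s0,
                            noise_sigma=self.spec.noise_sigma,
                            seed=int(row["noise_seed"]))


def make_cohort(phantom: PhantomSpec, cohort: CohortSpec,
                scheme: GradientScheme | None = None, s0: float = 1000.0,
                radial_jitter_sd: float = 0.02e-3) -> Cohort:
    """Draw an image-level cohort around a phantom.

    Controls carry the phantom's nominal eigenvalues; patients additionally
    get ``effect_delta`` added to the minor eigenvalues inside
    ``effect_segment`` (RD up, FA down, AD unchanged there).  Every subject
    receives a tube-wide Gaussian perturbation of the minor eigenvalues
    (``radial_jitter_sd``), the source of between-subject FA variation to
    which clinical scores may be coupled.  The coupling locus is the
    centerline point at the midpoint of ``effect_segment``.
    """
    if scheme is None:
        scheme = default_scheme()
    rng = np.random.default_rng(cohort.seed)
    subjects = _draw_covariates(cohort, rng)
    n = len(subjects)

    l1, l2, l3 = phantom.inside_eigenvalues
    # clip jitter so eigenvalue ordering survives for every subject
    max_shift = 0.49 * (l1 - (l2 + phantom.effect_delta))
    shifts = np.clip(rng.normal(0.0, radial_jitter_sd, size=n), -0.9 * l3, max_shift)
    subjects["radial_shift"] = shifts
    subjects["noise_seed"] = rng.integers(0, 2 ** 31 - 1, size=n)

    lo, hi = phantom.effect_segment
    locus_frac = 0.5 * (lo + hi)
    is_patient = (subjects["group"] == "patient").to_numpy()
    fa_locus = np.array(
        [
            _true_fa(l1,
                     l2 + s + (phantom.effect_delta if pat else 0.0),
                     l3 + s + (phantom.effect_delta if pat else 0.0))
            for s, pat in zip(shifts, is_patient)
        ]
    )
    subjects["fa_locus_true"] = fa_locus

    # couple patient clinical scores to the standardized true locus FA
    pat_fa = fa_locus[is_patient]
    sd = pat_fa.std(ddof=1)
    latent = (pat_fa - pat_fa.mean()) / sd if sd > 0 else np.zeros(pat_fa.size)
    pat_scores = _coupled_scores(cohort, latent, rng)
    for col in pat_scores.columns:
        subjects[col] = np.nan
        subjects.loc[is_patient, col] = pat_scores[col].to_numpy()

    arc = _centerline_arclength(phantom.centerline)
    locus_idx = int(np.searchsorted(arc / arc[-1], locus_frac))
    truth = {
        "effect_segment": (lo, hi),
        "effect_delta": phantom.effect_delta,
        "locus_arc_fraction": locus_frac,
        "locus_world": phantom.centerline[locus_idx].tolist(),
    }
    return Cohort(phantom=phantom, spec=cohort, scheme=scheme, subjects=subjects,
                  truth=truth, s0=s0, radial_jitter_sd=radial_jitter_sd)


def write_cohort(cohort: Cohort, outdir, write_images: bool = True) -> dict:
    """Write the cohort to disk: per-subject 4D NIfTI + bvec/bval, subject
    table CSV, ground truth JSON.  Returns a manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.scheme.save(outdir / "dwi.bvec", outdir / "dwi.bval")
    public = cohort.subjects.drop(columns=["radial_shift", "noise_seed", "fa_locus_true"])
    public.to_csv(outdir / "subjects.csv", index=False)
    manifest = {"n_subjects": len(cohort.subjects), "images": []}
    if write_images:
        grid = cohort.phantom.grid
        for sid in cohort.subjects["id"]:
            p = outdir / f"dwi_{sid}.nii.gz"
            save_dwi(p, cohort.subject_dwi(sid), grid)
            manifest["images"].append(p.name)
    truth = dict(cohort.truth)
    truth["subject_hidden"] = cohort.subjects[["id", "radial_shift", "fa_locus_true"]].to_dict(
        orient="list"
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# profile-level cohorts for replicated simulations


def simulate_profile_cohort(
    cohort: CohortSpec,
    n_points: int = 30,
    baseline: float = 0.7698,
    sigma_total: float = 0.04,
    subject_icc: float = 0.4,
    effect_points: tuple[int, int] = (12, 18),
    effect_d: float = 0.0,
    effect_direction: int = -1,
    locus: int = 15,
    metric: str = "fa",
    bundle: str = "fornix_L",
):
    """Draw per-subject along-tract profiles directly from the generative model.

    The raw profile of subject *i* at arc-length point *j* is::

        y_ij = baseline + group_i * delta_j + u_i + e_ij

    with ``u_i ~ N(0, icc * sigma^2)`` a subject-level (tract-wide) deviation,
    ``e_ij ~ N(0, (1 - icc) * sigma^2)`` independent pointwise measurement
    noise, and ``delta_j = -d * sigma`` on ``effect_points`` (inclusive) for
    patients — FA lower in the affected segment.  ``effect_d`` is the
    pointwise Cohen's d of the raw (unsmoothed) group difference.

    Clinical couplings in ``cohort.panss_coupling`` are stated as the target
    partial correlation between the *raw* profile value at ``locus`` and the
    score; the coupling acts through the latent ``u_i``, so the correlation
    against the latent is ``coupling / sqrt(icc)``.

    Returns ``(profiles, subjects, truth)`` where ``profiles`` is a long
    DataFrame (subject, bundle, metric, point, value, smoothed).
    """
    if not (0 < subject_icc < 1):
        raise ValueError("subject_icc must be in (0, 1)")
    lo, hi = effect_points
    if not (0 <= lo <= hi < n_points):
        raise ValueError("effect_points out of range")
    rng = np.random.default_rng(cohort.seed)
    subjects = _draw_covariates(cohort, rng)
    n = len(subjects)
    is_patient = (subjects["group"] == "patient").to_numpy()

    sigma_u = sigma_total * np.sqrt(subject_icc)
    sigma_e = sigma_total * np.sqrt(1.0 - subject_icc)
    u = rng.normal(0.0, sigma_u, size=n)
    e = rng.normal(0.0, sigma_e, size=(n, n_points))
    # sign convention: -1 = metric lower in patients (the FA signature),
    # +1 = higher (the RD signature)
    delta = np.zeros(n_points)
    delta[lo: hi + 1] = effect_direction * effect_d * sigma_total
    y = baseline + is_patient[:, None] * delta[None, :] + u[:, None] + e

    # clinical scores: couple through the latent u so that the raw-profile
    # correlation at the locus equals the requested coupling
    latent = (u[is_patient] - u[is_patient].mean())
    s = latent.std(ddof=1)
    latent = latent / s if s > 0 else latent
    pat_scores = _coupled_scores(cohort, latent, rng,
                                 attenuation=np.sqrt(subject_icc))
    for col in pat_scores.columns:
        subjects[col] = np.nan
        subjects.loc[is_patient, col] = pat_scores[col].to_numpy()

    profiles = pd.DataFrame(
        {
            "subject": np.repeat(subjects["id"].to_numpy(), n_points),
            "bundle": bundle,
            "metric": metric,
            "point": np.tile(np.arange(n_points), n),
            "value": y.ravel(),
            "smoothed": False,
        }
    )
    truth = {
        "effect_points": (lo, hi),
        "effect_d": effect_d,
        "locus": locus,
        "sigma_total": sigma_total,
        "subject_icc": subject_icc,
    }
    return profiles, subjects, truth
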
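"""End-to-end orchestration: configuration, stage caching, and the full
simulate -> fit -> track -> extract -> curve -> profile -> statistics run.

Stages write their outputs under ``output_dir`` and record a content hash of
their inputs and parameters; an unchanged stage is skipped on re-run, and
deleting an intermediate file triggers recomputation of that stage only.

Tracking runs once on the tensor field fitted to the *averaged control DWIs*
(the bundle geometry is defined on the cohort-mean data); per-subject
metrics are then sampled along the shared mean curve from each subject's
own scalar maps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, stats, tensor, tracking
from .core import ImageGrid, ScalarMap, save_scalar_map
from .synthetic import (CohortSpec, GradientScheme, PhantomSpec, default_scheme,
                        load_dwi, make_cohort, make_phantom, save_dwi, write_cohort)
from .tracking import Bundle, RoiSpec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_full", "load_roi_protocol"]


def load_roi_protocol(path=None) -> dict:
    """The multi-ROI delineation protocol for atlas-space data (slice
    indices of the fornix/cingulum ROIs); ships with the package."""
    if path is None:
        path = Path(__file__).parent / "data" / "mori_roi_protocol.yaml"
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; round-trips through YAML."""

    output_dir: str = "results/pipeline"
    seed: int = 0
    # phantom / cohort
    grid_shape: tuple = (40, 16, 16)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    tube_radius: float = 4.0
    effect_segment: tuple = (0.4, 0.6)
    effect_delta: float = 0.0
    n_control: int = 31
    n_patient: int = 33
    noise_sigma: float = 0.03
    panss_coupling: dict = field(default_factory=dict)
    s0: float = 1000.0
    # tracking
    fa_thresh: float = 0.15
    angle_thresh: float = 50.0
    min_length: float = 10.0
    # bundle selection: planar ROIs at these arc fractions of the tube axis
    roi_fractions: tuple = (0.25, 0.75)
    bundle_name: str = "fornix_L"
    # profiles
    n_points: int = 30
    smooth: bool = True
    # statistics
    alpha: float = 0.05
    bonferroni_family: int = 30

    def __post_init__(self) -> None:
        if not (0 < self.fa_thresh < 1):
            raise ValueError("fa_thresh must be in (0, 1)")
        if not (0 < self.angle_thresh <= 90):
            raise ValueError("angle_thresh must be in (0, 90]")
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("grid_shape", "voxel_size", "effect_segment", "roi_fractions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(
            grid_shape=tuple(self.grid_shape), voxel_size=tuple(self.voxel_size),
            tube_radius=self.tube_radius, effect_segment=tuple(self.effect_segment),
            effect_delta=self.effect_delta,
        )

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_control=self.n_control, n_patient=self.n_patient,
            panss_coupling=dict(self.panss_coupling),
            noise_sigma=self.noise_sigma, seed=self.seed,
        )


# ---------------------------------------------------------------------------
# stage caching


def _hash_parts(parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, int, float, bool, type(None))):
            h.update(repr(p).encode())
        elif isinstance(p, Path):
            p = Path(p)
            h.update(p.name.encode())
            if p.exists():
                h.update(p.read_bytes())
        else:
            h.update(repr(p).encode())
    return h.hexdigest()


def _stage(outdir: Path, name: str, key_parts, outputs, fn):
    """Run ``fn`` unless the stage's key matches and all outputs exist."""
    marker = outdir / f".stage_{name}.json"
    key = _hash_parts(key_parts)
    outputs = [outdir / o for o in outputs]
    if marker.exists() and all(o.exists() for o in outputs):
        try:
            if json.loads(marker.read_text())["key"] == key:
                logger.info("stage %s: cached", name)
                return
        except Exception:
            pass
    logger.info("stage %s: running", name)
    fn()
    missing = [str(o) for o in outputs if not o.exists()]
    if missing:
        raise RuntimeError(f"stage {name} did not produce: {missing}")
    marker.write_text(json.dumps({"key": key, "outputs": [o.name for o in outputs]}))


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic cohort on disk (DWIs, gradients, subject table,
    ground truth, manifest)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(config.phantom_spec(), config.cohort_spec(),
                         default_scheme(), s0=config.s0)

    def do():
        write_cohort(cohort, outdir / "cohort", write_images=True)
        config.to_yaml(outdir / "config_used.yaml")

    _stage(outdir, "simulate",
           [dataclasses.asdict(config)],
           ["cohort/subjects.csv", "cohort/truth.json", "cohort/manifest.json",
            "cohort/dwi.bvec", "cohort/dwi.bval"],
           do)
    return outdir / "cohort"


def _roi_specs(config: PipelineConfig, grid: ImageGrid):
    """Planar selection ROIs transverse to the tube's long axis (x)."""
    n = grid.shape[0]
    rois = []
    for frac in config.roi_fractions:
        rois.append(RoiSpec(kind="sagittal", slice_index=int(round(frac * (n - 1))),
                            name=f"plane_{frac}"))
    return rois


def run_full(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of key result paths.

    Order: simulate -> average control DWIs -> fit tracking tensor ->
    scalar maps -> FACT -> multi-ROI bundle -> mean curve -> per-subject
    maps and profiles -> smoothing -> ROI and tract-based statistics ->
    clinical correlations.
    """
    outdir = Path(config.output_dir)
    cohort_dir = run_simulate(config)
    scheme = GradientScheme.load(cohort_dir / "dwi.bvec", cohort_dir / "dwi.bval")
    subjects = pd.read_csv(cohort_dir / "subjects.csv")
    grid = config.phantom_spec().grid

    # --- mean DWI over controls, tracking tensor field and maps
    control_ids = subjects.loc[subjects["group"] == "control", "id"].tolist()
    mean_path = outdir / "mean_dwi.nii.gz"

    def do_mean():
        acc = None
        for sid in control_ids:
            data, _ = load_dwi(cohort_dir / f"dwi_{sid}.nii.gz")
            acc = data if acc is None else acc + data
        save_dwi(mean_path, acc / len(control_ids), grid)

    _stage(outdir, "mean_dwi",
           [config.seed, config.noise_sigma, *(cohort_dir / f"dwi_{s}.nii.gz" for s in control_ids)],
           ["mean_dwi.nii.gz"], do_mean)

    def do_fit():
        data, g = load_dwi(mean_path)
        tv = tensor.fit_tensor(data, scheme, grid=g)
        maps = tensor.scalar_maps(tv)
        for m in ("fa", "rd", "ad"):
            save_scalar_map(outdir / f"mean_{m}.nii.gz", maps[m])
        np.save(outdir / "mean_e1.npy", tensor.principal_directions(tv))

    _stage(outdir, "fit_tensor", [mean_path],
           ["mean_fa.nii.gz", "mean_rd.nii.gz", "mean_ad.nii.gz", "mean_e1.npy"], do_fit)

    # --- tracking + bundle extraction + mean curve
    from .core import load_scalar_map

    def do_track():
        fa = load_scalar_map(outdir / "mean_fa.nii.gz", "fa")
        e1 = np.load(outdir / "mean_e1.npy")
        lines = tracking.track_all(fa, e1, fa_thresh=config.fa_thresh,
                                   angle_thresh=config.angle_thresh,
                                   min_length=config.min_length)
        save_streamlines_tck(outdir / "all_streamlines.tck", lines)

    _stage(outdir, "track",
           [outdir / "mean_fa.nii.gz", config.fa_thresh, config.angle_thresh,
            config.min_length],
           ["all_streamlines.tck"], do_track)

    def do_extract():
        lines = load_streamlines_tck(outdir / "all_streamlines.tck")
        rois = _roi_specs(config, grid)
        bundle = tracking.select_by_rois(lines, rois, grid, name=config.bundle_name)
        if len(bundle) == 0:
            raise RuntimeError("bundle extraction kept no streamlines")
        bundle = geometry.orient_bundle(bundle, rois[0], grid)
        save_streamlines_tck(outdir / "bundle.tck", bundle.streamlines)
        curve = geometry.mean_curve(bundle, n=config.n_points,
                                    orientation_tag="origin_to_end")
        curve.to_json(outdir / "mean_curve.json")

    _stage(outdir, "extract",
           [outdir / "all_streamlines.tck", config.roi_fractions, config.n_points],
           ["bundle.tck", "mean_curve.json"], do_extract)

    # --- per-subject profiles
    def do_profiles():
        curve = geometry.MeanCurve.from_json(outdir / "mean_curve.json")
        rows = []
        for sid in subjects["id"]:
            data, g = load_dwi(cohort_dir / f"dwi_{sid}.nii.gz")
            maps = tensor.scalar_maps(tensor.fit_tensor(data, scheme, grid=g))
            for metric in ("fa", "rd", "ad"):
                raw = geometry.extract_profile(maps[metric], curve)
                sm = geometry.smooth_profile(raw, n=config.n_points) if config.smooth else raw
                for j in range(config.n_points):
                    rows.append({"subject": sid, "bundle": config.bundle_name,
                                 "metric": metric, "point": j, "raw": raw[j],
                                 "value": sm[j], "smoothed": bool(config.smooth)})
        pd.DataFrame(rows).to_csv(outdir / "profiles.tsv", sep="\t", index=False)

    _stage(outdir, "profiles",
           [outdir / "mean_curve.json", cohort_dir / "subjects.csv", config.smooth,
            config.seed, config.noise_sigma],
           ["profiles.tsv"], do_profiles)

    # --- statistics
    def do_stats():
        profiles = pd.read_csv(outdir / "profiles.tsv", sep="\t")
        means = (profiles.groupby(["subject", "bundle", "metric"])["raw"]
                 .mean().rename("value").reset_index())
        roi_table = stats.roi_analysis(means, subjects)
        roi_table.to_csv(outdir / "roi_stats.tsv", sep="\t", index=False)

        res = stats.tractwise_analysis(profiles, subjects, alpha=config.alpha,
                                       family=config.bonferroni_family,
                                       n_points=config.n_points)
        pd.concat([r.to_frame() for r in res.values()]).to_csv(
            outdir / "pointwise_stats.tsv", sep="\t", index=False)
        summary = {
            f"{b}/{m}": {"n_significant": int(r.significant.sum()),
                         "min_p": float(r.p_values.min())}
            for (b, m), r in res.items()
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))

    _stage(outdir, "stats",
           [outdir / "profiles.tsv", config.alpha, config.bonferroni_family],
           ["roi_stats.tsv", "pointwise_stats.tsv", "summary.json"], do_stats)

    # --- clinical correlations (patients only)
    def do_correlate():
        profiles = pd.read_csv(outdir / "profiles.tsv", sep="\t")
        res = stats.clinical_correlation(profiles, subjects, alpha=config.alpha,
                                         family=config.bonferroni_family,
                                         n_points=config.n_points)
        pd.concat([r.to_frame() for r in res.values()]).to_csv(
            outdir / "clinical_correlations.tsv", sep="\t", index=False)

    _stage(outdir, "correlate",
           [outdir / "profiles.tsv", cohort_dir / "subjects.csv", config.alpha],
           ["clinical_correlations.tsv"], do_correlate)

    return {
        "cohort": cohort_dir,
        "profiles": outdir / "profiles.tsv",
        "roi_stats": outdir / "roi_stats.tsv",
        "pointwise_stats": outdir / "pointwise_stats.tsv",
        "clinical": outdir / "clinical_correlations.tsv",
        "summary": outdir / "summary.json",
    }


# ---------------------------------------------------------------------------
# streamline IO (TCK)


def save_streamlines_tck(path, streamlines) -> None:
    import nibabel as nib

    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(nib.streamlines.TckFile(tractogram), str(path))


def load_streamlines_tck(path):
    import nibabel as nib

    tck = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tck.streamlines]


def save_streamlines_trk(path, streamlines, grid: ImageGrid) -> None:
    """TRK keeps the grid-to-world transform in its header."""
    import nibabel as nib

    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "voxel_to_rasmm": grid.affine.astype(np.float32),
        "voxel_sizes": np.asarray(grid.voxel_size, dtype=np.float32),
        "dimensions": np.asarray(grid.shape, dtype=np.int16),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(nib.streamlines.TrkFile(tractogram, header), str(path))


def load_streamlines_trk(path):
    import nibabel as nib

    trk = nib.streamlines.load(str(path))  # nibabel maps points to world mm
    return [np.asarray(s, dtype=float) for s in trk.streamlines]
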
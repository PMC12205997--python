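"""End-to-end orchestration: simulate -> sweep -> fit.

Thin, deterministic drivers over the library modules.  Every command takes
a :class:`PipelineConfig`, writes plain-text artifacts (CSV/JSON) into an
output directory, and records provenance (config echo, seeds, package
version, output checksums) in a manifest.  The ``analysis/`` scripts and
the ``cortexscales`` console script both call these functions.
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

from . import __version__
from .brain_age import BrainAgeConfig, bootstrap_adjusted_r2, fit_brain_age
from .coarse_grain import scale_ladder
from .mesh import CorticalSurfacePair
from .mesh_io import read_surface, read_vertex_labels, write_surface, write_vertex_labels
from .morphometrics import SweepConfig, run_scale_sweep
from .synthetic import (
    SyntheticCortexSpec,
    lifespan_cohort_spec,
    make_cohort,
    make_folded_sphere_pair,
    make_quadrant_labels,
)
from .trajectories import (
    TrajectoryConfig,
    fit_normative_model,
    trajectory_band,
)

log = logging.getLogger("cortexscales")

GEOMETRY_PRESETS = {
    "smooth-sphere": dict(base_radius=30.0, fold_amplitude=0.0, fold_degree=0, thickness=2.5),
    "folded-sphere": dict(base_radius=30.0, fold_amplitude=3.0, fold_degree=12, thickness=2.5),
}
COHORT_PRESETS = ("lifespan",)


@dataclass
class PipelineConfig:
    """Defaults follow the pipeline's standard constants: scale ladder
    base 10^-0.5 with multiplicative step 10^0.07 (k_max=14 spans 0.32 to
    3.02 mm), a 15 mm closing ball, hull-based hemisphere exposed area and
    1,000 bootstrap replicates."""

    k_max: int = 14
    closing_diameter: float = 15.0
    ae_mode: str = "hull"
    smooth_sigma: float = 0.8
    mesh_subdivisions: int = 4
    cohort_n: int = 800
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    brain_age: BrainAgeConfig = field(default_factory=BrainAgeConfig)
    bootstrap_B: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trajectory"]["smoothing"] = {
            k: v for k, v in d["trajectory"]["smoothing"].items()
        }
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig, files: list[Path], extra=None):
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {f.name: _sha256(f) for f in files},
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def cmd_simulate(preset: str, outdir, config: PipelineConfig | None = None, n: int | None = None):
    """Write synthetic surfaces/labels or a cohort CSV for a named preset."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    if preset in GEOMETRY_PRESETS:
        spec = SyntheticCortexSpec(
            mesh_subdivisions=config.mesh_subdivisions,
            seed=config.seed,
            **GEOMETRY_PRESETS[preset],
        )
        pair = make_folded_sphere_pair(spec)
        pair.labels = make_quadrant_labels(pair)
        for name, mesh in (("pial", pair.pial), ("white", pair.white)):
            f = outdir / f"{preset}.{name}.surf"
            write_surface(mesh, f, fmt="freesurfer")
            files.append(f)
        f = outdir / f"{preset}.labels.csv"
        write_vertex_labels(pair.labels, f, fmt="csv")
        files.append(f)
        log.info("simulate: wrote %s geometry to %s", preset, outdir)
    elif preset in COHORT_PRESETS:
        spec = lifespan_cohort_spec(n=n or config.cohort_n, seed=config.seed)
        table = make_cohort(spec)
        f = outdir / "cohort.csv"
        table.to_csv(f, index=False)
        files.append(f)
        log.info("simulate: wrote cohort (n=%d) to %s", len(table), f)
    else:
        known = sorted(GEOMETRY_PRESETS) + list(COHORT_PRESETS)
        raise ValueError(f"unknown preset {preset!r}; choose from {known}")
    _write_manifest(outdir, config, files, {"preset": preset})
    return files


def load_pair(pial_path, white_path, labels_path=None, fmt="freesurfer") -> CorticalSurfacePair:
    pial = read_surface(pial_path, fmt)
    white = read_surface(white_path, fmt)
    labels = None
    if labels_path is not None:
        label_fmt = "annot" if str(labels_path).endswith(".annot") else "csv"
        labels = read_vertex_labels(labels_path, label_fmt, pial)
    return CorticalSurfacePair(pial=pial, white=white, labels=labels)


def cmd_sweep(
    pair: CorticalSurfacePair,
    outdir,
    config: PipelineConfig | None = None,
    subject_id: str = "subject",
) -> pd.DataFrame:
    """Run the multiscale sweep for one surface pair and write the table."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if pair.labels is None:
        log.warning("no vertex labels: lobe metrics skipped, hemisphere only")
    sweep_cfg = SweepConfig(
        closing_diameter=config.closing_diameter,
        ae_mode=config.ae_mode,
        smooth_sigma=config.smooth_sigma,
        lobe_metrics=pair.labels is not None,
        subject_id=subject_id,
    )
    table = run_scale_sweep(pair, scale_ladder(config.k_max), sweep_cfg)
    # display column: the conventional 2-dp scale labels; full precision stays the key
    table["lambda_display"] = [
        v if v == "native" else f"{float(v):.2f}" for v in table["lambda"]
    ]
    f = outdir / f"{subject_id}.multiscale.csv"
    table.to_csv(f, index=False)
    _write_manifest(outdir, config, [f], {"subject_id": subject_id})
    log.info("sweep: %d rows -> %s", len(table), f)
    return table


def cmd_fit_trajectories(
    cohort: pd.DataFrame,
    metric_cols: list[str],
    outdir,
    config: PipelineConfig | None = None,
) -> dict:
    """Fit a normative trajectory model per metric column; write models/bands."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = {}
    files = []
    ages = np.linspace(*config.trajectory.age_range, 83)
    report = []
    for col in metric_cols:
        model = fit_normative_model(cohort, col, config.trajectory, metric_id=col)
        models[col] = model
        stem = col.replace("@", "_at_")
        fj = outdir / f"{stem}.model.json"
        fj.write_text(model.to_json())
        band = trajectory_band(model, ages)
        fb = outdir / f"{stem}.band.csv"
        pd.DataFrame(
            {"age": ages, "q25": band.lower, "q50": band.center, "q75": band.upper}
        ).to_csv(fb, index=False)
        files += [fj, fb]
        report.append(
            f"{col}: family={model.family_name} converged={model.converged} "
            f"deviance={model.deviance_path[-1]:.2f} iters={len(model.deviance_path) - 1}"
        )
    (outdir / "trajectory_report.txt").write_text(
        "\n".join(report + ["", f"config: {config.to_dict()}"])
    )
    files.append(outdir / "trajectory_report.txt")
    _write_manifest(outdir, config, files)
    return models


def cmd_fit_brainage(
    cohort: pd.DataFrame,
    outdir,
    config: PipelineConfig | None = None,
    B: int | None = None,
) -> dict:
    """Fit the three brain-age models, bootstrap adjusted R^2, write results."""
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    B = B if B is not None else config.bootstrap_B
    result = bootstrap_adjusted_r2(
        cohort, ("m1", "m2", "m3"), B=B, seed=config.seed, config=config.brain_age
    )
    fb = outdir / "bootstrap_adj_r2.csv"
    result.to_frame().to_csv(fb, index=False)
    full = {mid: fit_brain_age(cohort, mid, config.brain_age) for mid in ("m1", "m2", "m3")}
    summary = {
        "B": B,
        "seed": config.seed,
        "full_fit_adj_r2": {m: full[m].adj_r2 for m in full},
        "edf": {m: full[m].edf for m in full},
        "bootstrap_median": {
            m: float(np.nanmedian(result.samples[m])) for m in result.samples
        },
        "flagged_replicates": result.flagged,
    }
    fj = outdir / "brain_age_summary.json"
    fj.write_text(json.dumps(summary, indent=1))
    (outdir / "brain_age_report.txt").write_text(
        "\n".join(
            [f"{m}: adjR2={full[m].adj_r2:.3f} edf={full[m].edf:.1f}" for m in full]
            + ["", f"config: {config.to_dict()}"]
        )
    )
    _write_manifest(outdir, config, [fb, fj], {"B": B})
    return {"full": full, "bootstrap": result}
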
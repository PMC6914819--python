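"""End-to-end orchestration: simulate/load -> normalize -> preprocess ->
PCA/trajectories -> effects -> contrasts, with a provenance manifest.

A single :class:`PipelineConfig` (YAML-loadable) drives the run.  Spinal
cord segments are processed fully independently after normalization, as
the study analyzed the two batches separately.  All randomness descends
from one global seed fanned out to per-stage child seeds, PCA signs are
deterministic and tables are written with fixed formatting, so re-running
an identical config + seed is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .data_model_io import (
    MetaboliteMatrix,
    StudyDesign,
    assemble_matrix,
    read_design,
    read_metabolite_table,
    write_table,
)
from .effect_models import effect_table, two_group_tests
from .pca_trajectory import (
    align_trajectories,
    build_trajectories,
    fit_pca,
    pc_variance_attribution,
    trajectory_geometry,
)
from .preprocessing import log_transform, normality_report, uv_scale
from .qc_normalization import correct_drift, fit_drift, qc_report
from .synthetic import SimulationConfig, simulate_study

__all__ = ["PipelineConfig", "run_pipeline", "child_seed"]

log = logging.getLogger("metabotraj")

_KNOWN_KEYS = {
    "intensity_path", "design_path", "simulate", "zero_policy", "min_qc",
    "smoothing", "K", "pcs_for_trajectories", "contrast_scheme", "fdr_alpha",
    "output_dir", "seed", "log_level",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending entity."""


def child_seed(seed: int, index: int) -> int:
    """Counter-based child seed below 2**31, stable across runs."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of one pipeline run.

    Provide either ``intensity_path`` + ``design_path`` or a ``simulate``
    block (SimulationConfig fields).  ``pcs_for_trajectories`` maps
    segment -> 1-based PC indices; the study used PC2/PC3 for the lumbar
    and PC2/PC4 for the thoracic segment, chosen from the variance
    attribution table.  Unknown keys are rejected up front.
    """

    output_dir: str = "results"
    seed: int = 0
    intensity_path: str | None = None
    design_path: str | None = None
    simulate: dict[str, Any] | None = None
    zero_policy: str = "error"
    min_qc: int = 4
    smoothing: str | float = "cv"
    K: int | None = 10
    pcs_for_trajectories: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {"lumbar": (2, 3), "thoracic": (2, 4)}
    )
    contrast_scheme: str = "per_cell"
    fdr_alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.intensity_path is not None and self.design_path is not None
        if not has_files and self.simulate is None:
            raise ValueError(
                "config needs either intensity_path+design_path or a simulate block"
            )

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        if "pcs_for_trajectories" in d:
            d["pcs_for_trajectories"] = {
                k: tuple(v) for k, v in d["pcs_for_trajectories"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical(self) -> str:
        """Analysis-relevant fields only: where outputs land and how much
        is logged do not change what is computed."""
        d = asdict(self)
        d.pop("output_dir")
        d.pop("log_level")
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", child_seed(config.seed, 0))
        if "drift_spec" in sim_kwargs:
            sim_kwargs["drift_spec"] = {
                k: tuple(v) for k, v in sim_kwargs["drift_spec"].items()
            }
        sim = SimulationConfig(**sim_kwargs)
        matrix, design, truth = simulate_study(sim)
        return matrix, design, truth
    values = read_metabolite_table(config.intensity_path)
    design = read_design(config.design_path)
    return assemble_matrix(values, design), design, None


def _stage(name: str, outdir: Path):
    """Context wrapper converting stage errors into PipelineError."""
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write all products under ``output_dir``.

    Returns a result bundle: in-memory objects per segment plus the
    manifest dict (also written as ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    bundle: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    with _stage("load", outdir):
        matrix, design, truth = _load_inputs(config)
        if config.simulate is not None:
            write_table(matrix.values, outdir / "intensity_raw.csv")
            write_table(design.table.set_index("sample_id"), outdir / "design.csv")
            write_table(truth.variance_fractions, outdir / "truth_variance_fractions.csv")
        manifest["stages"]["load"] = {
            "n_samples": design.n_samples,
            "n_metabolites": len(matrix.metabolite_ids),
            "n_study_groups": len(design.study_groups()),
            "batches": design.batches,
        }
    bundle["raw"] = matrix
    bundle["design"] = design
    bundle["truth"] = truth

    with _stage("normalize", outdir):
        drift = fit_drift(matrix, design, min_qc=config.min_qc, smoothing=config.smoothing)
        normalized = correct_drift(matrix, drift)
        rsd = qc_report(matrix, normalized, design)
        write_table(rsd.set_index(["segment", "metabolite"]), outdir / "qc_rsd.csv")
        manifest["stages"]["normalize"] = {
            "n_qc": drift.n_qc_points,
            "median_rsd_before": float(np.nanmedian(rsd["rsd_before"])),
            "median_rsd_after": float(np.nanmedian(rsd["rsd_after"])),
        }
    bundle["normalized"] = normalized
    bundle["qc_rsd"] = rsd

    segments: dict[str, dict[str, Any]] = {}
    for seg in design.batches:
        segdir = outdir / seg
        segdir.mkdir(exist_ok=True)
        in_seg = (design.table["segment"] == seg).to_numpy()
        seg_all = normalized.subset_samples(in_seg)
        seg_study = seg_all.subset_samples(seg_all.design.is_study())
        res: dict[str, Any] = {}

        with _stage(f"preprocess[{seg}]", segdir):
            logged = log_transform(seg_study, zero_policy=config.zero_policy)
            norm_rep = normality_report(seg_study, logged)
            write_table(norm_rep, segdir / "normality.csv")
            scaled, scaling = uv_scale(logged)
            write_table(scaled.values, segdir / "scaled.csv")
        res.update(logged=logged, scaled=scaled, scaling=scaling, normality=norm_rep)

        with _stage(f"pca[{seg}]", segdir):
            n, p = scaled.values.shape
            K = min(config.K or min(n - 1, p), n - 1, p)
            pca = fit_pca(scaled, K=K)
            attribution = pc_variance_attribution(pca, scaled.design)
            write_table(pca.scores, segdir / "pca_scores.csv")
            write_table(pca.loadings, segdir / "pca_loadings.csv")
            write_table(attribution, segdir / "pc_variance_attribution.csv")
        res.update(pca=pca, attribution=attribution)

        with _stage(f"trajectory[{seg}]", segdir):
            pcs = config.pcs_for_trajectories.get(seg, (2, 3))
            traj = build_trajectories(pca, scaled.design, pcs=pcs)
            aligned = align_trajectories(traj)
            geometry = trajectory_geometry(aligned)
            write_table(traj, segdir / "trajectories.csv")
            write_table(aligned, segdir / "trajectories_aligned.csv")
            write_table(geometry.segments.set_index(["group", "segment"]),
                        segdir / "trajectory_segments.csv")
            write_table(geometry.pairs.set_index(["group_a", "group_b", "segment"]),
                        segdir / "trajectory_geometry.csv")
        res.update(trajectories=traj, aligned=aligned, geometry=geometry)

        with _stage(f"effects[{seg}]", segdir):
            effects = effect_table(logged)
            write_table(effects.table.set_index(["feature", "term"]),
                        segdir / "effect_table.csv")
            write_table(effects.wide_r2(), segdir / "effect_r2_wide.csv")
        res["effects"] = effects

        with _stage(f"contrasts[{seg}]", segdir):
            contrasts = two_group_tests(logged, scheme=config.contrast_scheme)
            write_table(contrasts.table.set_index(["feature", "contrast"]),
                        segdir / "contrasts.csv")
        res["contrasts"] = contrasts

        manifest["stages"][seg] = {
            "n_study_samples": int(seg_study.design.n_samples),
            "n_terms_per_metabolite": len(
                res["effects"].table["term"].unique()
            ) - 1,
            "pcs_for_trajectories": list(config.pcs_for_trajectories.get(seg, (2, 3))),
            "n_contrasts": int(res["contrasts"].table["contrast"].nunique()),
        }
        segments[seg] = res

    bundle["segments"] = segments
    bundle["manifest"] = manifest
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
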
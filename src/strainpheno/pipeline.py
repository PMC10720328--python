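"""End-to-end orchestration: QC -> align -> features -> cluster -> explain -> outcomes.

A :class:`PipelineConfig` (YAML-serializable) fixes every knob and every
seed, so a rerun with the same config is bit-identical for the deterministic
stages.  Each run writes an append-only artifact directory:

* ``features.csv`` — the subjects x 6 feature matrix
* ``model.json`` — the fitted mixture (weights, means, covariances, the
  training standardization, alignment grid and metadata)
* ``assignments.csv`` — hard labels and posterior probabilities
* ``bic_curve.csv``, ``radar_profile.csv``, ``shapley_mean_abs.csv``,
  ``forest_importance.csv``
* ``incidence_<outcome>.csv``, ``km_<outcome>_cluster<i>.csv``,
  ``cox_<outcome>.csv``
* ``run_log.txt`` — per-stage timings, config hash and seeds
* ``figures/`` — presentation SVGs

``apply_external`` re-runs the frozen model (stored scaling and alignment
grid, no refitting) on an external cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plots
from .cluster import (
    GmmModel,
    assign,
    assignments_to_frame,
    load_model,
    relabel_canonical,
    save_model,
    select_k,
)
from .explain import forest_importance, radar_profile, shapley_values
from .features import build_feature_matrix
from .io import read_cohort_table, read_trace, write_feature_matrix
from .outcomes import (
    DEFAULT_COX_COVARIATES,
    compare_clusters,
    cox_cluster_hr,
    incidence_rates,
    km_cumulative_incidence,
)
from .preprocess import align_and_resample, cluster_centroids, qc_filter
from .synthetic import default_config, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "apply_external"]


@dataclass
class PipelineConfig:
    """All pipeline knobs; every random operation has an explicit seed."""

    input_dir: str = ""
    output_dir: str = "artifacts"
    min_frame_rate: float = 45.0
    n_knots: int = 5
    plateau_threshold: float = 10.0
    k_range: tuple[int, int] = (1, 8)
    n_init: int = 10
    elbow_fraction: float = 0.25
    seed: int = 0
    shap_background: int = 100
    shap_permutations: int = 50
    shap_subjects: int = 150
    forest_trees: int = 500
    cox_covariates: tuple[str, ...] = tuple(DEFAULT_COX_COVARIATES)
    outcomes: tuple[str, ...] = ("cv", "cardiac")
    make_figures: bool = True

    def validate(self) -> None:
        if not self.input_dir:
            raise ValueError("input_dir is required (run `simulate` first)")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if self.min_frame_rate <= 0 or self.n_knots < 1:
            raise ValueError("invalid QC/segmentation settings")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "cox_covariates", "outcomes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    output_dir: Path
    chosen_k: int
    model: GmmModel
    features: pd.DataFrame
    assignments: pd.DataFrame
    n_kept: int
    n_excluded: int
    files: dict[str, Path] = field(default_factory=dict)


class _RunLog:
    def __init__(self, path: Path, header: dict):
        self.path = path
        self.t0 = time.time()
        lines = [f"{k}: {v}" for k, v in header.items()]
        path.write_text("\n".join(lines) + "\n")

    def stage(self, name: str, **info) -> None:
        dt = time.time() - self.t0
        extra = " ".join(f"{k}={v}" for k, v in info.items())
        with self.path.open("a") as fh:
            fh.write(f"[{dt:8.2f}s] {name}: {extra}\n")


def _load_traces(input_dir: Path):
    trace_dir = input_dir / "traces"
    if not trace_dir.is_dir():
        raise FileNotFoundError(f"no traces/ directory under {input_dir}")
    traces = [read_trace(p) for p in sorted(trace_dir.glob("*.tsv"))]
    if not traces:
        raise ValueError(f"no trace files found in {trace_dir}")
    table_path = input_dir / "cohort.csv"
    table = read_cohort_table(table_path) if table_path.exists() else None
    return traces, table


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages on the cohort under ``config.input_dir``."""
    config.validate()
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    log = _RunLog(
        out / "run_log.txt",
        {"config_hash": config.config_hash(), "seed": config.seed,
         "input_dir": str(input_dir)},
    )
    config.to_yaml(out / "config.yaml")

    try:
        traces, table = _load_traces(input_dir)
        log.stage("load", n_traces=len(traces))

        kept, excluded = qc_filter(traces, min_frame_rate=config.min_frame_rate)
        if not kept:
            raise RuntimeError("qc: no traces passed quality control")
        pd.DataFrame(
            [{"subject_id": tr.subject_id, "reason": r} for tr, r in excluded]
        ).to_csv(out / "qc_excluded.csv", index=False)
        files["qc_excluded"] = out / "qc_excluded.csv"
        log.stage("qc", kept=len(kept), excluded=len(excluded))

        aligned, rejected = align_and_resample(kept)
        if not aligned:
            raise RuntimeError("align: all traces rejected")
        log.stage("align", aligned=len(aligned), rejected=len(rejected),
                  length=aligned[0].n_samples)
        seg_lengths = [
            aligned[0].boundaries[1] + 1,
            aligned[0].boundaries[2] - aligned[0].boundaries[1] + 1,
            aligned[0].n_samples - aligned[0].boundaries[2],
        ]

        feats = build_feature_matrix(
            aligned, n_knots=config.n_knots, plateau_threshold=config.plateau_threshold
        )
        files["features"] = write_feature_matrix(feats, out / "features.csv")
        log.stage("features", n=len(feats), degenerate=int(feats.degenerate_flag.sum()))

        ks = range(config.k_range[0], config.k_range[1] + 1)
        chosen_k, bic_curve, models = select_k(
            feats, k_range=ks, seed=config.seed,
            elbow_fraction=config.elbow_fraction, n_init=config.n_init,
        )
        bic_curve.to_csv(out / "bic_curve.csv", index=False)
        files["bic_curve"] = out / "bic_curve.csv"
        model = models[chosen_k]
        model.metadata["alignment_segment_lengths"] = seg_lengths
        assignments = assign(model, feats)
        model, assignments = relabel_canonical(model, assignments)
        files["model"] = save_model(model, out / "model.json")
        adf = assignments_to_frame(assignments)
        adf.to_csv(out / "assignments.csv", index=False)
        files["assignments"] = out / "assignments.csv"
        log.stage("cluster", chosen_k=chosen_k, bic=f"{model.bic:.1f}")

        labels = adf["label"].to_numpy()
        profile = radar_profile(model)
        profile.to_csv(out / "radar_profile.csv")
        files["radar_profile"] = out / "radar_profile.csv"
        if model.k >= 2:
            fi = forest_importance(
                feats, labels, n_trees=config.forest_trees, seed=config.seed
            )
            fi.as_series().rename("importance").to_csv(out / "forest_importance.csv")
            files["forest_importance"] = out / "forest_importance.csv"
            n_expl = min(config.shap_subjects, len(feats))
            rng = np.random.default_rng(config.seed)
            expl_idx = np.sort(rng.choice(len(feats), size=n_expl, replace=False))
            shap = shapley_values(
                model,
                feats.iloc[expl_idx],
                background=feats,
                background_size=config.shap_background,
                n_permutations=config.shap_permutations,
                seed=config.seed,
            )
            mean_abs = pd.DataFrame(
                np.abs(shap.values).mean(axis=0),
                index=[f"cluster_{c + 1}" for c in range(model.k)],
                columns=shap.feature_names,
            )
            mean_abs.to_csv(out / "shapley_mean_abs.csv")
            files["shapley_mean_abs"] = out / "shapley_mean_abs.csv"
            log.stage("explain", shap_subjects=n_expl,
                      oob_agreement=f"{fi.oob_agreement:.3f}")
        else:
            shap = None
            log.stage("explain", skipped="single cluster")

        if table is not None and "event_cv" in table.columns:
            table = table.set_index("subject_id").loc[adf["subject_id"]].reset_index()
            for outcome in config.outcomes:
                inc = incidence_rates(table, labels, outcome=outcome)
                inc.to_csv(out / f"incidence_{outcome}.csv", index=False)
                files[f"incidence_{outcome}"] = out / f"incidence_{outcome}.csv"
                km = km_cumulative_incidence(table, labels, outcome=outcome)
                for lab, df in km.items():
                    df.to_csv(out / f"km_{outcome}_cluster{lab}.csv", index=False)
                if model.k >= 2 and inc.loc[inc.cluster == "overall", "events"].iloc[0] >= 10:
                    cox = cox_cluster_hr(
                        table, labels, covariates=config.cox_covariates,
                        outcome=outcome,
                    )
                    cox.cluster_effects.to_csv(out / f"cox_{outcome}.csv", index=False)
                    files[f"cox_{outcome}"] = out / f"cox_{outcome}.csv"
            if model.k >= 2:
                comparison = compare_clusters(
                    table.drop(columns=["true_cluster"], errors="ignore"), labels
                )
                comparison.summary.to_csv(out / "cluster_characteristics.csv", index=False)
                comparison.pairwise.to_csv(out / "cluster_pairwise_tests.csv", index=False)
            log.stage("outcomes", outcomes=",".join(config.outcomes))

        if config.make_figures:
            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            plots.bic_curve_plot(bic_curve, chosen_k, figdir / "bic_curve.svg")
            centroids = cluster_centroids(aligned, labels)
            plots.centroid_plot(centroids, figdir / "centroids.svg")
            plots.radar_chart(profile, figdir / "radar.svg")
            if shap is not None:
                plots.shap_summary(shap, figdir / "shap_summary.svg")
            log.stage("figures", dir=str(figdir))
    except Exception as exc:  # noqa: BLE001 - annotate stage context and re-raise
        log.stage("ABORTED", error=type(exc).__name__, detail=str(exc)[:200])
        raise

    log.stage("done")
    return PipelineResult(
        output_dir=out,
        chosen_k=chosen_k,
        model=model,
        features=feats,
        assignments=adf,
        n_kept=len(kept),
        n_excluded=len(excluded) + len(rejected),
        files=files,
    )


def apply_external(
    model_path: str | Path,
    external_dir: str | Path,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Apply a frozen model to an external cohort (no refitting).

    The model's stored feature standardization is reused; the external
    traces are aligned onto the training alignment grid when the model
    records it.  The same report structure as :func:`run_pipeline` is
    written (without model refitting or k selection).
    """
    config = config or PipelineConfig()
    model = load_model(model_path)
    external_dir = Path(external_dir)
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    log = _RunLog(
        out / "run_log.txt",
        {"mode": "apply_external", "model": str(model_path),
         "config_hash": config.config_hash(), "seed": config.seed},
    )

    traces, table = _load_traces(external_dir)
    if not traces:
        raise ValueError("empty external cohort")
    kept, excluded = qc_filter(traces, min_frame_rate=config.min_frame_rate)
    if not kept:
        raise RuntimeError("qc: no external traces passed quality control")
    target = model.metadata.get("alignment_segment_lengths")
    aligned, rejected = align_and_resample(kept, target_lengths=target)
    feats = build_feature_matrix(
        aligned, n_knots=config.n_knots, plateau_threshold=config.plateau_threshold
    )
    if list(feats.columns[1:7]) != model.feature_names:
        raise ValueError("feature schema mismatch between model and cohort")
    files["features"] = write_feature_matrix(feats, out / "features.csv")
    assignments = assign(model, feats)
    adf = assignments_to_frame(assignments)
    adf.to_csv(out / "assignments.csv", index=False)
    files["assignments"] = out / "assignments.csv"
    labels = adf["label"].to_numpy()
    log.stage("apply", n=len(adf), k=model.k)

    if table is not None and "event_cv" in table.columns:
        table = table.set_index("subject_id").loc[adf["subject_id"]].reset_index()
        for outcome in config.outcomes:
            inc = incidence_rates(table, labels, outcome=outcome)
            inc.to_csv(out / f"incidence_{outcome}.csv", index=False)
            files[f"incidence_{outcome}"] = out / f"incidence_{outcome}.csv"
        log.stage("outcomes", outcomes=",".join(config.outcomes))
    log.stage("done")
    return PipelineResult(
        output_dir=out,
        chosen_k=model.k,
        model=model,
        features=feats,
        assignments=adf,
        n_kept=len(kept),
        n_excluded=len(excluded) + len(rejected),
        files=files,
    )


def simulate_cohort(
    n_subjects: int, seed: int, directory: str | Path, overwrite: bool = False,
    **generator_overrides,
) -> Path:
    """Generate and write a synthetic demo cohort (thin wrapper)."""
    cfg = default_config(n_subjects=n_subjects, seed=seed, **generator_overrides)
    subjects = generate_cohort(cfg)
    return write_cohort(subjects, directory, overwrite=overwrite)
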
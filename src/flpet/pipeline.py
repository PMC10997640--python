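"""End-to-end orchestration: segment → features → analyze.

A single structured config (YAML) drives the run; every under-specified
variant (surface method, Dmax mode, medEDGE/itErosion definitions, POD24
convention) is echoed into the run manifest so results stay interpretable.
Outputs are plain CSV plus optional PNG plots, written to one results
directory together with ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureConfig, feature_panel
from .io import (
    FEATURE_COLUMNS,
    read_cohort_csv,
    read_mask_volume,
    read_suv_volume,
    validate_cohort,
    write_cohort_csv,
)
from .segmentation import SegmentationConfig, lesion_set_from_labels, segment_lesions
from .stats import (
    SCORE_FEATURES,
    combined_score,
    cox_univariate,
    derive_pod24,
    km_logrank,
    roc_table,
    spearman_correlogram,
)
from .synthetic import CohortSpec, LesionSpec, PhantomSpec, make_cohort, make_phantom, simulate_outcomes

log = logging.getLogger("flpet.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and (when known) the patient."""

    def __init__(self, stage: str, message: str, patient_id: str | None = None):
        self.stage = stage
        self.patient_id = patient_id
        who = f" [patient {patient_id}]" if patient_id else ""
        super().__init__(f"stage {stage!r}{who}: {message}")


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulate_patients(cfg: dict, seg_cfg: SegmentationConfig, feat_cfg: FeatureConfig, seed: int) -> pd.DataFrame:
    """Phantom-per-patient simulation: build, segment and featurize volumes."""
    rng = np.random.default_rng(seed)
    n = int(cfg.get("n_patients", 20))
    rows = []
    for i in range(n):
        pid = f"SIM{i:04d}"
        n_lesions = int(rng.integers(1, 4))
        lesions = []
        for _ in range(n_lesions):
            r = float(rng.uniform(8.0, 16.0))
            center = rng.uniform(r + 4.0, np.array([94.0, 94.0, 94.0]) - r - 4.0)
            lesions.append(
                LesionSpec(shape="sphere", center_mm=tuple(center), size_mm=r,
                           peak_suv=float(rng.uniform(5.0, 15.0)))
            )
        spec = PhantomSpec(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                           background_suv=0.5, noise_sd=0.1, lesions=lesions,
                           seed=int(rng.integers(0, 2**31 - 1)))
        vol, _, _ = make_phantom(spec)
        _, lesion_set = segment_lesions(vol, seg_cfg)
        if len(lesion_set) == 0:
            log.warning("patient %s: nROI = 0, excluded from feature table", pid)
            continue
        panel = feature_panel(vol, lesion_set, feat_cfg)
        rows.append({"patient_id": pid, **panel.as_dict()})
    return pd.DataFrame(rows)


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages and return the results directory.

    The config may describe (a) a fully simulated run (``simulate`` section,
    phantom or cohort mode), (b) an image run (``inputs.volumes`` +
    ``inputs.cohort_csv`` outcomes), or (c) an analyze-only run
    (``inputs.cohort_csv`` with feature columns). Idempotent for a fixed
    seed and inputs.
    """
    input_hashes: dict[str, str] = {}
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        if not config_path.exists():
            raise PipelineError("config", f"missing config file: {config_path}")
        config = yaml.safe_load(config_path.read_text())
        input_hashes[str(config_path)] = _file_sha256(config_path)
    config = dict(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "results"))
    out.mkdir(parents=True, exist_ok=True)

    seg_cfg = SegmentationConfig(**config.get("segment", {}))
    feat_cfg = FeatureConfig(**config.get("features", {}))
    analyze_cfg = dict(config.get("analyze", {}))
    score_features = tuple(analyze_cfg.get("score_features", SCORE_FEATURES))
    endpoint = analyze_cfg.get("endpoint", "pfs24")

    # ------------------------------------------------------------------ inputs
    sim = config.get("simulate")
    inputs = config.get("inputs", {})
    if sim is not None and sim.get("mode", "phantoms") == "phantoms":
        features = _simulate_patients(sim, seg_cfg, feat_cfg, seed)
        if features.empty:
            raise PipelineError("simulate", "no patient produced any lesion")
        cutoffs_truth = {c: float(features[c].median()) for c in score_features}
        rng = np.random.default_rng(seed + 1)
        cohort = simulate_outcomes(
            features, cutoffs_truth,
            sim.get("hazard_ratios", {c: 4.0 for c in score_features}),
            prevalence=sim.get("pod24_prevalence", 0.3),
            censoring_fraction=sim.get("censoring_fraction", 0.25), rng=rng,
        )
    elif sim is not None:
        spec = CohortSpec(seed=seed, **{k: v for k, v in sim.items() if k != "mode"})
        cohort, _ = make_cohort(spec)
    elif "volumes" in inputs:
        rows = []
        for entry in inputs["volumes"]:
            pid = entry.get("id", Path(entry["vol"]).stem)
            vol_path = Path(entry["vol"])
            if not vol_path.exists():
                raise PipelineError("segment", f"missing volume file: {vol_path}", pid)
            input_hashes[str(vol_path)] = _file_sha256(vol_path)
            vol = read_suv_volume(vol_path)
            exclusion = None
            if entry.get("exclusion"):
                exclusion = read_mask_volume(entry["exclusion"], vol)
                input_hashes[str(entry["exclusion"])] = _file_sha256(Path(entry["exclusion"]))
            if entry.get("mask"):
                mask = read_mask_volume(entry["mask"], vol)
                input_hashes[str(entry["mask"])] = _file_sha256(Path(entry["mask"]))
                lesion_set = lesion_set_from_labels(mask.labels, vol.spacing, vol.values)
            else:
                _, lesion_set = segment_lesions(vol, seg_cfg, exclusion)
            if len(lesion_set) == 0:
                log.warning("patient %s: nROI = 0, excluded from feature table", pid)
                continue
            panel = feature_panel(vol, lesion_set, feat_cfg)
            rows.append({"patient_id": pid, **panel.as_dict()})
        features = pd.DataFrame(rows)
        if "cohort_csv" in inputs:
            outcomes = read_cohort_csv(inputs["cohort_csv"], require_features=False)
            input_hashes[str(inputs["cohort_csv"])] = _file_sha256(Path(inputs["cohort_csv"]))
            cohort = features.merge(
                outcomes[[c for c in outcomes.columns if c not in FEATURE_COLUMNS]],
                on="patient_id",
            )
        else:
            cohort = features
    elif "cohort_csv" in inputs:
        path = Path(inputs["cohort_csv"])
        if not path.exists():
            raise PipelineError("analyze", f"missing cohort file: {path}")
        input_hashes[str(path)] = _file_sha256(path)
        cohort = read_cohort_csv(path)
    else:
        raise PipelineError("config", "config must provide a 'simulate' section or 'inputs'")

    write_cohort_csv(cohort[["patient_id"] + [c for c in FEATURE_COLUMNS if c in cohort.columns]],
                     out / "features.csv")

    # ----------------------------------------------------------------- analyze
    analysis_done = False
    if {"pfs_time_months", "pfs_event"}.issubset(cohort.columns):
        validate_cohort(cohort)
        pod24 = cohort["pod24"] if "pod24" in cohort.columns else derive_pod24(cohort)
        try:
            corr = spearman_correlogram(cohort)
            pd.DataFrame(corr.rho, index=corr.features, columns=corr.features).to_csv(out / "correlogram.csv")
            pd.Series(corr.clusters, name="cluster").rename_axis("feature").to_csv(out / "clusters.csv")
            roc = roc_table(cohort, pod24)
            roc.to_csv(out / "roc_table.csv", index=False, float_format="%.12g")
            cutoffs = dict(zip(roc["feature"], roc["cutoff"]))
            cox_rows = []
            for col in [c for c in FEATURE_COLUMNS if c in cohort.columns]:
                ind = (cohort[col] >= cutoffs[col]).astype(int)
                ind.name = col
                try:
                    fit = cox_univariate(cohort, ind, endpoint=endpoint)[0]
                    cox_rows.append({"feature": col, "cutoff": cutoffs[col],
                                     **{k: v for k, v in vars(fit).items() if k != "variable"}})
                except Exception as exc:  # non-identifiable level: report, don't drop
                    cox_rows.append({"feature": col, "cutoff": cutoffs[col], "hazard_ratio": np.nan,
                                     "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                                     "logrank_p": np.nan, "error": str(exc)})
            pd.DataFrame(cox_rows).to_csv(out / "cox_table.csv", index=False, float_format="%.12g")
            try:
                score = combined_score(cohort, cutoffs, features=score_features, pod24=pod24, endpoint=endpoint)
                table = score.group_counts.copy()
                table.to_csv(out / "score_table.csv")
                score_fits = pd.DataFrame([vars(f) for f in score.group_fits])
                score_fits["sensitivity_ge2"] = score.sensitivity
                score_fits["specificity_ge2"] = score.specificity
                score_fits.to_csv(out / "score_cox.csv", index=False, float_format="%.12g")
            except Exception as exc:
                log.warning("combined score Cox fits unavailable: %s", exc)
                score = combined_score(cohort, cutoffs, features=score_features, pod24=pod24, fit_cox=False)
                score.group_counts.to_csv(out / "score_table.csv")
            if config.get("plots", True):
                _write_plots(cohort, pod24, corr, cutoffs, score_features, out, endpoint)
            analysis_done = True
        except ValueError as exc:
            raise PipelineError("analyze", str(exc)) from exc

    manifest = {
        "tool": "flpet",
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": _jsonable(config),
        "segmentation": dataclasses.asdict(seg_cfg),
        "features": feat_cfg.as_dict(),
        "analysis_done": analysis_done,
        "input_hashes": input_hashes,
        "n_patients": int(len(cohort)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_plots(cohort, pod24, corr, cutoffs, score_features, out: Path, endpoint: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.rho, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.features)), corr.features, rotation=90)
    ax.set_yticks(range(len(corr.features)), corr.features)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(out / "correlogram.png", dpi=100)
    plt.close(fig)

    from lifelines import KaplanMeierFitter

    horizon = 24.0 if endpoint == "pfs24" else None
    for col in score_features:
        fig, ax = plt.subplots(figsize=(5, 4))
        high = cohort[col] >= cutoffs[col]
        for sel, lab in ((~high, "low"), (high, "high")):
            if sel.sum() == 0:
                continue
            t = cohort.loc[sel, "pfs_time_months"].clip(upper=horizon) if horizon else cohort.loc[sel, "pfs_time_months"]
            e = cohort.loc[sel, "pfs_event"].where(cohort.loc[sel, "pfs_time_months"] <= (horizon or np.inf), 0)
            KaplanMeierFitter(label=f"{col} {lab}").fit(t, e).plot_survival_function(ax=ax)
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("months")
        ax.set_ylabel("PFS probability")
        fig.tight_layout()
        fig.savefig(out / f"km_{col}.png", dpi=100)
        plt.close(fig)
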
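"""End-to-end orchestration: simulate or ingest, score, extract, model, report.

Group comparison uses all subjects; importance, selection and leave-one-out
prediction are restricted to the patient subgroup. Every artifact written
by :func:`run_pipeline` is stamped with the config hash and seed, and a
rerun with the same config reproduces all numeric outputs exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cop as cop_mod
from . import coupling, gaze as gaze_mod, io as io_mod, stats as stats_mod, synthetic
from .types import CohortConfig, FEATURE_NAMES, InvalidInputError, PATIENT

log = logging.getLogger("oculopost")


@dataclass
class PipelineConfig:
    # input: either file paths or a simulation config
    gaze_csv: str | None = None
    cop_csv: str | None = None
    clinical_csv: str | None = None
    simulate: CohortConfig | None = None
    out_dir: str = "run"
    seed: int = 0
    # CoP processing
    cop_rate: float = 25.0
    swarii_window: float = 0.04
    window_len: float = 1.0
    keep_last: float = 25.0
    # gaze event detection / features
    ivt_threshold: float = 30.0
    min_fixation_ms: float = 60.0
    max_gap_ms: float = 75.0
    gaze_window_len: float = 1.0
    ellipse_coverage: float = 0.95
    # modeling
    forest: coupling.ForestConfig = field(default_factory=coupling.ForestConfig)
    n_importance_runs: int = 5
    importance_threshold: float = 0.1
    make_plots: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = CohortConfig(**d["simulate"])
        if d.get("forest") is not None:
            d["forest"] = coupling.ForestConfig(**d["forest"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_cohort(config: PipelineConfig):
    """Return (gaze dict, cop dict, clinical frame), simulating if requested."""
    if config.simulate is not None:
        cohort = synthetic.generate_cohort(config.simulate)
        clinical = cohort.truth[["subject_id", "group", "attention_subscore"]].copy()
        return cohort.gaze, cohort.cop, clinical, cohort
    if not (config.gaze_csv and config.cop_csv and config.clinical_csv):
        raise InvalidInputError("provide gaze_csv, cop_csv and clinical_csv, or a simulate block")
    gaze = io_mod.read_gaze_csv(config.gaze_csv)
    cop = io_mod.read_cop_csv(config.cop_csv)
    clinical = io_mod.read_clinical_csv(config.clinical_csv)
    return gaze, cop, clinical, None


def score_cohort(
    cop: dict,
    subject_ids: list[str],
    rate: float = 25.0,
    swarii_window: float = 0.04,
    window_len: float = 1.0,
    keep_last: float = 25.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, cop_mod.QuietUnquietModel]:
    """SWARII-resample, window, fit the pooled quiet/unquiet mixture, score."""
    desc: dict[tuple[str, str], cop_mod.WindowDescriptorSet] = {}
    for sid in subject_ids:
        for cond in ("EO", "EC"):
            sig = cop_mod.swarii_resample(cop[(sid, cond)], rate=rate, window=swarii_window)
            desc[(sid, cond)] = cop_mod.window_descriptors(sig, window_len, keep_last)
    pooled = np.vstack([d.descriptors for d in desc.values()])
    model = cop_mod.fit_quiet_unquiet_model(pooled, seed=seed)
    rows = []
    for sid in subject_ids:
        ps = cop_mod.compute_postural_score(model, desc[(sid, "EO")], desc[(sid, "EC")], sid)
        rows.append(
            {"subject_id": sid, "score": ps.score, "f_EO": ps.f_eo, "f_EC": ps.f_ec}
        )
    return pd.DataFrame(rows), model


def extract_cohort_features(
    gaze: dict,
    subject_ids: list[str],
    ivt_threshold: float = 30.0,
    min_fixation_ms: float = 60.0,
    max_gap_ms: float = 75.0,
    window_len: float = 1.0,
    coverage: float = 0.95,
) -> pd.DataFrame:
    rows = []
    for sid in subject_ids:
        rec = gaze[sid]
        events = gaze_mod.detect_events_ivt(rec, ivt_threshold, min_fixation_ms, max_gap_ms)
        feats = gaze_mod.extract_feature_vector(rec, events, window_len, coverage)
        feats["subject_id"] = sid
        rows.append(feats)
    df = pd.DataFrame(rows)
    return df[["subject_id", *FEATURE_NAMES, "EllAxisH", "EllAxisV", "n_fixations", "n_saccades"]]


def impute_median(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Replace missing cells with the cohort median; return log of imputed cells."""
    notes = []
    X = X.copy()
    for col in X.columns:
        bad = ~np.isfinite(X[col].to_numpy(dtype=float))
        if bad.any():
            med = float(X.loc[~bad, col].median())
            X.loc[bad, col] = med
            for sid in X.index[bad]:
                notes.append(f"imputed {col} for {sid} with cohort median {med:.4g}")
    return X, notes


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the whole replica; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.config_hash()} seed={config.seed}"
    gaze, cop, clinical, cohort = load_cohort(config)
    subject_ids = io_mod.cross_match(gaze, cop, clinical)
    if not subject_ids:
        raise InvalidInputError("no subject has complete gaze + CoP + clinical data")
    clinical = clinical.set_index("subject_id").loc[subject_ids].reset_index()

    if cohort is not None:
        gaze_df, cop_df, truth_df = synthetic.cohort_frames(cohort)
        inputs = out / "inputs"
        io_mod.write_stamped_csv(gaze_df, inputs / "gaze.csv", stamp)
        io_mod.write_stamped_csv(cop_df, inputs / "cop.csv", stamp)
        io_mod.write_stamped_csv(truth_df, inputs / "truth.csv", stamp)

    scores, _model = score_cohort(
        cop,
        subject_ids,
        rate=config.cop_rate,
        swarii_window=config.swarii_window,
        window_len=config.window_len,
        keep_last=config.keep_last,
        seed=config.seed,
    )
    io_mod.write_stamped_csv(scores, out / "scores.csv", stamp)

    features = extract_cohort_features(
        gaze,
        subject_ids,
        ivt_threshold=config.ivt_threshold,
        min_fixation_ms=config.min_fixation_ms,
        max_gap_ms=config.max_gap_ms,
        window_len=config.gaze_window_len,
        coverage=config.ellipse_coverage,
    )
    io_mod.write_stamped_csv(features, out / "features.csv", stamp)

    merged = features.merge(scores, on="subject_id").merge(clinical, on="subject_id")
    patients = merged[merged["group"] == PATIENT].reset_index(drop=True)
    imputation_log: list[str] = []
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    if len(patients) >= 5:
        Xp = patients.set_index("subject_id")[list(FEATURE_NAMES)]
        Xp, imputation_log = impute_median(Xp)
        y = patients["score"].to_numpy(dtype=float)
        cfg = dataclasses.replace(config.forest, seed=config.seed)
        imp = coupling.oob_permutation_importance(
            Xp, y, cfg, n_runs=config.n_importance_runs, threshold=config.importance_threshold
        )
        io_mod.write_stamped_csv(imp.to_frame(), out / "importance.csv", stamp)
        selected = imp.selected_names()
        pred_all = coupling.loo_predict(Xp, y, cfg, subject_ids=list(Xp.index))
        io_mod.write_stamped_csv(pred_all.to_frame(), out / "predictions_all.csv", stamp)
        report["selected_features"] = selected
        report["rmse_norm_all"] = pred_all.rmse_norm
        report["rmse_norm_all_excl"] = pred_all.rmse_norm_excl
        report["excluded_subject_all"] = pred_all.excluded_subject
        if selected:
            pred_sel = coupling.loo_predict(
                Xp, y, cfg, feature_subset=selected, subject_ids=list(Xp.index)
            )
            io_mod.write_stamped_csv(pred_sel.to_frame(), out / "predictions_selected.csv", stamp)
            report["rmse_norm_selected"] = pred_sel.rmse_norm
            report["rmse_norm_selected_excl"] = pred_sel.rmse_norm_excl
    else:
        warnings.warn("fewer than 5 patients: importance/prediction skipped", stacklevel=2)

    # cohort statistics on all subjects
    pat_scores = merged.loc[merged["group"] == PATIENT, "score"].to_numpy()
    ctl_scores = merged.loc[merged["group"] != PATIENT, "score"].to_numpy()
    if len(pat_scores) and len(ctl_scores):
        test = stats_mod.wilcoxon_rank_sum(pat_scores, ctl_scores)
        report["group_test"] = dataclasses.asdict(test)
        report["patient_median_score"] = float(np.median(pat_scores))
        report["control_median_score"] = float(np.median(ctl_scores))
    if "attention_subscore" in patients.columns and len(patients) >= 3:
        att = patients["attention_subscore"].to_numpy(dtype=float)
        sc = patients["score"].to_numpy(dtype=float)
        if np.ptp(att) > 0 and np.ptp(sc) > 0:
            corr = stats_mod.pearson_correlation(att, sc)
            report["attention_correlation"] = dataclasses.asdict(corr)
    report["imputation_log"] = imputation_log
    report["n_subjects"] = len(subject_ids)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config_hash": config.config_hash(), "seed": config.seed}, fh, indent=2)
        fh.write("\n")
    if config.make_plots:
        _make_plots(merged, report, out)
    return out


def _make_plots(merged: pd.DataFrame, report: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    groups = [g for g, _ in merged.groupby("group")]
    ax.boxplot(
        [grp["score"].to_numpy() for _, grp in merged.groupby("group")],
        tick_labels=groups,
        whis=1.5,
    )
    ax.set_ylabel("postural score")
    fig.tight_layout()
    fig.savefig(out / "score_boxplot.png", dpi=100)
    plt.close(fig)

    pred_path = out / "predictions_all.csv"
    if pred_path.exists():
        pred = io_mod.read_table(pred_path)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(pred["observed"], pred["predicted"])
        lim = [0, 100]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel("observed score")
        ax.set_ylabel("LOO predicted score")
        fig.tight_layout()
        fig.savefig(out / "prediction_scatter.png", dpi=100)
        plt.close(fig)

    imp_path = out / "importance.csv"
    if imp_path.exists():
        imp = io_mod.read_table(imp_path)
        run_cols = [c for c in imp.columns if c.startswith("imp_run")]
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.boxplot(imp[run_cols].to_numpy().T, tick_labels=imp["feature"], whis=1.5)
        ax.axhline(0.1, color="r", lw=0.8, ls=":")
        ax.tick_params(axis="x", rotation=90)
        ax.set_ylabel("importance")
        fig.tight_layout()
        fig.savefig(out / "importance_boxplot.png", dpi=100)
        plt.close(fig)
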
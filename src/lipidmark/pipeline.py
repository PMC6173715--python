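"""Pipeline configuration and orchestration.

One call (or ``lipidmark run-all``) executes the five-step flow:
generate (or load) the cohort → preprocess (outlier scan, age/sex
correction, transforms) → unsupervised structure mapping → nested
feature selection → symbolic-classifier building → evaluation. Every
stage materializes its outputs to CSV in the report directory so any
stage can be re-run in isolation, and a run log records the effective
configuration and all derived stage seeds.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .benchmark import compare_learners
from .cohort import (
    default_config,
    diagnosis_vector,
    generate_cohort,
    marker_columns,
    read_cohort,
    write_cohort,
)
from .evaluation import performance_report, sex_balance_chisq, stratified_split
from .preprocess import (
    ConfoundCorrector,
    percent_normalize,
    residual_confound_check,
    scan_outliers,
    zero_invariant_log,
)
from .rules import RuleSumClassifier, save_classifier
from .selection import RepeatedPanelSelector
from .structure import (
    ToroidalSOM,
    compute_umatrix,
    diagnosis_agreement,
    umatrix_two_cluster_labels,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published settings
    (50×80 grid, 20 epochs, 500 trees per selection run with up to 6
    candidate features, 1,000 selection runs, k = 5, 500 boosting
    iterations, 1,000 forest trees, 2/3 split, 1,000 bootstraps)."""

    cohort_in: str | None = None
    outdir: str = "lipidmark_report"
    seed: int = 0
    # cohort generation
    n_patients: int = 102
    n_controls: int = 301
    # preprocessing
    grubbs_alpha: float = 0.05
    controls_only_correction: bool = True
    # structure mapping
    som_rows: int = 50
    som_cols: int = 80
    som_epochs: int = 20
    basin_quantile: float = 0.6
    # feature selection
    n_runs: int = 1000
    n_trees: int = 500
    max_features: int = 6
    exclusion_list: list[str] = field(default_factory=list)
    # classifier
    M_max: int = 3
    priors: str = "prevalence"
    # evaluation
    train_fraction: float = 2 / 3
    n_bootstrap: int = 1000
    compare: bool = False

    def smoke(self) -> "PipelineConfig":
        """Reduced-repetition copy for fast end-to-end runs."""
        return dataclasses.replace(
            self,
            som_rows=20,
            som_cols=30,
            som_epochs=10,
            n_runs=20,
            n_trees=100,
            n_bootstrap=200,
        )


def load_config(source) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected with a suggestion,
    missing keys fall back to the defaults."""
    if isinstance(source, (str, Path)) and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    valid = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    for key in data:
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise KeyError(f"unknown config key {key!r}{suffix}")
    config = PipelineConfig(**data)
    for f in dataclasses.fields(PipelineConfig):
        value = getattr(config, f.name)
        if value is None or f.name in ("cohort_in", "outdir", "exclusion_list", "priors"):
            continue
        if isinstance(value, bool) != (f.type == "bool"):
            raise TypeError(f"config key {f.name!r}: expected {f.type}, got {type(value).__name__}")
        if f.type in ("int", "float") and not isinstance(value, (int, float)):
            raise TypeError(f"config key {f.name!r}: expected {f.type}, got {type(value).__name__}")
    return config


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    """Deterministically derive per-stage seeds from one master seed."""
    return [int(s) for s in np.random.default_rng(master).integers(0, 2**31, size=n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow and write the report bundle.

    Returns a dict of the headline quantities (also written as
    ``summary.json``): sex-balance χ², cluster/diagnosis agreement,
    selection summary, rule table and test performance.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log: list[str] = [f"effective config: {dataclasses.asdict(config)}", f"stage seeds: {seeds}"]
    t0 = time.time()

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- generate / load ---------------------------------------------------
    try:
        if config.cohort_in:
            cohort = read_cohort(config.cohort_in)
        else:
            cfg = dataclasses.replace(
                default_config(seed=seeds[0]),
                n_patients=config.n_patients,
                n_controls=config.n_controls,
            )
            cohort = generate_cohort(cfg)
            log.append(f"generated cohort, clamped values: {cohort.attrs.get('n_clamped')}")
        write_cohort(cohort, outdir / "cohort.csv")
    except Exception as exc:  # noqa: BLE001
        fail("generate", exc)

    y = diagnosis_vector(cohort)
    male = cohort["sex"].to_numpy() == "m"
    chi2, df, p = sex_balance_chisq(
        int(male[y == 1].sum()),
        int((~male[y == 1]).sum()),
        int(male[y == 0].sum()),
        int((~male[y == 0]).sum()),
    )
    log.append(f"sex balance: chi2={chi2:.4f}, df={df}, p={p:.4f}")

    # -- preprocess --------------------------------------------------------
    try:
        screened, reports = scan_outliers(cohort, alpha=config.grubbs_alpha)
        n_removed = sum(r.removed for r in reports)
        log.append(f"grubbs scan: {n_removed} value(s) replaced")
        corrector = ConfoundCorrector(controls_only=config.controls_only_correction)
        corrector.fit(screened)
        corrected = corrector.transform(screened)
        corrector.to_frame().to_csv(outdir / "correction_model.csv", index=False)
        write_cohort(corrected, outdir / "cohort_corrected.csv")
        residual = residual_confound_check(corrected)
        residual.to_csv(outdir / "residual_confounds.csv")
    except Exception as exc:  # noqa: BLE001
        fail("preprocess", exc)

    # -- structure mapping -------------------------------------------------
    try:
        X_struct = percent_normalize(zero_invariant_log(corrected, clip=True))[
            marker_columns(corrected)
        ].to_numpy(float)
        som = ToroidalSOM(
            rows=config.som_rows,
            cols=config.som_cols,
            epochs=config.som_epochs,
            random_state=seeds[1],
        ).fit(X_struct)
        umatrix = compute_umatrix(som)
        np.savetxt(outdir / "umatrix.csv", umatrix, delimiter=",")
        pd.DataFrame(
            {
                "subject_id": cohort["subject_id"],
                "row": som.bmus_[:, 0],
                "col": som.bmus_[:, 1],
            }
        ).to_csv(outdir / "bmus.csv", index=False)
        cluster_labels = umatrix_two_cluster_labels(
            umatrix, som.bmus_, quantile=config.basin_quantile
        )
        agreement = diagnosis_agreement(cluster_labels, y)
        log.append(f"U-matrix two-cluster diagnosis agreement: {agreement:.2f}%")
    except Exception as exc:  # noqa: BLE001
        fail("structure", exc)

    # -- split + selection -------------------------------------------------
    try:
        train, test = stratified_split(
            corrected, train_fraction=config.train_fraction, seed=seeds[2]
        )
        selector = RepeatedPanelSelector(
            n_runs=config.n_runs,
            n_trees=config.n_trees,
            max_features=config.max_features,
            exclusion_list=tuple(config.exclusion_list),
            random_state=seeds[3],
        ).fit(train)
        summary = selector.summary_
        pd.DataFrame(
            sorted(summary.size_histogram.items()), columns=["size", "count"]
        ).to_csv(outdir / "selection_sizes.csv", index=False)
        pd.DataFrame(
            {
                "marker": summary.membership_counts.index,
                "setA_count": summary.membership_counts.to_numpy(),
                "mean_importance": summary.mean_importance.to_numpy(),
            }
        ).to_csv(outdir / "selection_membership.csv", index=False)
        (outdir / "panel.txt").write_text("\n".join(selector.panel_) + "\n")
        log.append(
            f"selection: modal size {summary.final_size}, panel {selector.panel_}, "
            f"median OOB error {np.median(summary.oob_errors):.3f}"
        )
    except Exception as exc:  # noqa: BLE001
        fail("select", exc)

    # -- classifier build --------------------------------------------------
    try:
        panel = selector.panel_
        clf = RuleSumClassifier(
            M_max=config.M_max, priors=config.priors, random_state=seeds[4]
        )
        clf.fit(train[panel], diagnosis_vector(train))
        save_classifier(clf, outdir / "classifier.csv")
        log.append(
            "rules: "
            + "; ".join(
                f"{r.marker}{r.direction}{r.threshold_ng_ml:.2f} ng/ml" for r in clf.rules_
            )
            + f"; t={clf.t_}"
        )
    except Exception as exc:  # noqa: BLE001
        fail("build", exc)

    # -- evaluation --------------------------------------------------------
    try:
        y_test = diagnosis_vector(test)
        predicted = clf.predict(test[panel])
        sf = clf.decision_function(test[panel]).astype(float)
        report = performance_report(
            y_test, predicted, sf, n_bootstrap=config.n_bootstrap, seed=seeds[5]
        )
        frame = report.to_frame()
        frame.insert(0, "seed", config.seed)
        frame.to_csv(outdir / "performance.csv", index=False)
        log.append(f"test performance: {report.point}")
        if config.compare:
            table = compare_learners(
                corrected,
                panel,
                seed=seeds[6],
                train_fraction=config.train_fraction,
                n_bootstrap=config.n_bootstrap,
                M_max=config.M_max,
            )
            table.to_csv(outdir / "learner_comparison.csv")
    except Exception as exc:  # noqa: BLE001
        fail("evaluate", exc)

    log.append(f"total runtime: {time.time() - t0:.1f} s")
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    result = {
        "sex_balance_chi2": chi2,
        "sex_balance_p": p,
        "cluster_diagnosis_agreement_pct": agreement,
        "final_panel_size": len(panel),
        "final_panel": list(panel),
        "rule_sum_threshold_t": int(clf.t_),
        "test_performance_pct": report.point,
    }
    (outdir / "summary.json").write_text(json.dumps(result, indent=2) + "\n")
    return result
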
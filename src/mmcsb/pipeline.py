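"""One reproducible end-to-end study: simulate -> detect -> classify -> report.

``run_study`` mirrors the published validation protocol on a synthetic
cohort: generate a labelled recording, score it with the rule-based
detector, split the segments 50/50, train logistic and CART classifiers
(with repeated k-fold cross-validation on the training half) and test on
the held-out half.  Every artefact needed to recompute the report —
configuration, seeds, library versions — is written to a run manifest, and
repeated runs with the same manifest are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    LogisticFit,
    TreeModel,
    cross_validate,
    evaluate,
    fit_cart,
    fit_logistic,
    predict,
    split_train_test,
)
from .events import DetectorConfig, extract_features
from .exceptions import FitError, StageError
from .io import AnnotationSet, MMSignal, write_annotations, write_mm_edf
from .simulate import SimConfig, simulate_recording

__all__ = ["RunConfig", "run_study", "load_run_config"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Composite configuration of a full study run."""

    n_segments: int = 200
    csb_prevalence: float = 0.538  # ~= 1060/1970, the cohort the models are judged on
    segment_length_s: float = 180.0
    split_fraction: float = 0.5
    cv_repeats: int = 10
    cv_folds: int = 10
    ci_level: float = 0.95
    model: str = "both"  # "logistic" | "cart" | "both"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)

    def __post_init__(self):
        if self.model not in ("logistic", "cart", "both"):
            raise ValueError("model must be 'logistic', 'cart' or 'both'")

    def model_kinds(self) -> tuple[str, ...]:
        return ("logistic", "cart") if self.model == "both" else (self.model,)


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file.

    Top-level keys map to RunConfig fields; nested ``sim`` and
    ``detector`` mappings feed :class:`SimConfig` and
    :class:`DetectorConfig`.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**raw.pop("sim", {}))
    det_kwargs = raw.pop("detector", {})
    for key in ("breath_duration_bounds_s", "period_band_s"):
        if key in det_kwargs:
            det_kwargs[key] = tuple(det_kwargs[key])
    detector = DetectorConfig(**det_kwargs)
    return RunConfig(sim=sim, detector=detector, **raw)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _logistic_block(fit: LogisticFit) -> dict:
    return _jsonable(
        {
            "names": list(fit.names),
            "coefficients": fit.coefficients,
            "standard_errors": fit.standard_errors,
            "coef_cis": fit.coef_cis,
            "odds_ratios": fit.odds_ratios,
            "or_cis": fit.or_cis,
            "p_values": fit.p_values,
            "ci_level": fit.ci_level,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "converged": fit.converged,
            "separation_flag": fit.separation_flag,
        }
    )


def _tree_block(tree: TreeModel) -> dict:
    return _jsonable(
        {
            "rules": tree.rules(),
            "leaves": [
                {
                    "label": leaf.label,
                    "error_rate": leaf.error_rate,
                    "n": leaf.n,
                    "p_pos": leaf.p_pos,
                }
                for leaf in tree.leaves()
            ],
        }
    )


def classify_segments(
    features: pd.DataFrame,
    run_config: RunConfig | None = None,
) -> dict:
    """Train/validate/test the classifiers on a labelled feature table.

    ``features`` must contain ``lpm_present``, ``spm_present`` and
    ``csb_label`` columns.  Returns the report block: per model the
    training-CV aggregate, the held-out-test confusion matrix and metric
    suite, plus the model summary (logistic coefficient table or tree
    rules).
    """
    cfg = run_config or RunConfig()
    if "csb_label" not in features.columns:
        raise FitError("feature table has no csb_label column")
    labels = features["csb_label"]
    if labels.isna().any():
        raise FitError("csb_label contains missing values")
    if labels.astype(bool).all() or not labels.astype(bool).any():
        raise FitError("segment labels contain a single class; nothing to classify")

    table = features[["lpm_present", "spm_present", "csb_label"]].astype(bool)
    table = table.rename(columns={"lpm_present": "lpm", "spm_present": "spm"})
    train, test = split_train_test(table, cfg.split_fraction, seed=cfg.seed)
    log.info("classify: %d training / %d test segments", len(train), len(test))

    block: dict = {
        "n_train": len(train),
        "n_test": len(test),
        "models": {},
    }
    for kind in cfg.model_kinds():
        cv = cross_validate(
            train[["lpm", "spm"]],
            train["csb_label"],
            model_kind=kind,
            repeats=cfg.cv_repeats,
            folds=cfg.cv_folds,
            seed=cfg.seed + 1,
        )
        if kind == "logistic":
            model = fit_logistic(train[["lpm", "spm"]], train["csb_label"], cfg.ci_level)
            summary = {"logistic": _logistic_block(model)}
        else:
            model = fit_cart(train[["lpm", "spm"]], train["csb_label"])
            summary = {"tree": _tree_block(model)}
        cm, ms = evaluate(model, test[["lpm", "spm"]], test["csb_label"], cfg.ci_level)
        block["models"][kind] = {
            "cv": {
                "repeats": cv.repeats,
                "folds": cv.folds,
                "n_fold_records": cv.n_fold_records,
                "mean": _jsonable(cv.mean),
                "std": _jsonable(cv.std),
            },
            "test_confusion": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            "test_metrics": _jsonable(ms.as_dict()),
            **summary,
        }
    return block


def run_study(run_config: RunConfig | None = None, out_dir=None) -> dict:
    """Execute the full study and write its artefacts.

    Writes ``recording.edf``, ``annotations.csv`` (+ events),
    ``features.csv``, ``report.json`` and ``manifest.json`` to ``out_dir``
    (if given) and returns the report dict.  A failing stage raises
    :class:`~mmcsb.exceptions.StageError` naming the stage; artefacts of
    completed stages are retained.
    """
    cfg = run_config or RunConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: simulate -------------------------------------------------
    try:
        signal, annotations = simulate_recording(
            cfg.n_segments,
            cfg.csb_prevalence,
            cfg.sim,
            seed=cfg.seed,
            segment_length_s=cfg.segment_length_s,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc
    log.info(
        "simulate: %d segments (%d CSB), %.0f s recording",
        cfg.n_segments,
        int(annotations.segments["true_csb"].sum()),
        signal.duration_s,
    )
    if out is not None:
        write_mm_edf(signal, out / "recording.edf")
        write_annotations(annotations, out / "annotations.csv", out / "events.csv")

    # --- stage 2: detect ---------------------------------------------------
    try:
        features = extract_features(
            signal, cfg.detector, cfg.segment_length_s, annotations=annotations
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("detect", str(exc)) from exc
    log.info(
        "detect: %d segments scored, %d LPM-positive, %d SPM-positive",
        len(features),
        int(features["lpm_present"].sum()),
        int(features["spm_present"].sum()),
    )
    if out is not None:
        features.to_csv(out / "features.csv", index=False)

    # --- stage 3: classify -------------------------------------------------
    try:
        classify_block = classify_segments(features, cfg)
    except FitError as exc:
        raise StageError("classify", str(exc)) from exc

    # --- stage 4: report ---------------------------------------------------
    detection_agreement = {
        "lpm_accuracy": float(
            (features["lpm_present"] == annotations.segments["true_lpm"]).mean()
        ),
        "spm_accuracy": float(
            (features["spm_present"] == annotations.segments["true_spm"]).mean()
        ),
    }
    report = {
        "simulate": {
            "n_segments": cfg.n_segments,
            "n_csb": int(annotations.segments["true_csb"].sum()),
            "duration_s": signal.duration_s,
            "n_events": len(annotations.events),
        },
        "detect": {
            "n_segments": len(features),
            "n_lpm_positive": int(features["lpm_present"].sum()),
            "n_spm_positive": int(features["spm_present"].sum()),
            "detection_agreement": detection_agreement,
        },
        "classify": classify_block,
        "manifest": _manifest(cfg),
    }
    report = _jsonable(report)
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(report["manifest"], fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def _manifest(cfg: RunConfig) -> dict:
    import scipy
    import sklearn
    import statsmodels

    d = dataclasses.asdict(cfg)
    return _jsonable(
        {
            "config": d,
            "seeds": {
                "simulate": cfg.seed,
                "split": cfg.seed,
                "cross_validation": cfg.seed + 1,
            },
            "versions": {
                "mmcsb": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "statsmodels": statsmodels.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
    )
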
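"""End-to-end orchestration: data prep → three modeling arms → validation.

For each requested endpoint and split repeat the three arms (2D MLR,
hologram PLS, 3D field PLS) are fit on the training set and assessed on the
external set; every arm emits the same validation block — R², SE, q²,
SE_LOO, external r_t², δ with assessment sign and prediction range, and the
rm² family for training (LOO predictions) and test — laid out one column
per model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import SplitPlan, split_train_test
from .descriptors import compute_descriptors
from .field3d import (align_to_template, common_core_map, compute_fields,
                      embed_and_minimize, q2_matrix, FieldQSAR, GridSpec)
from .hologram import HologramQSAR
from .model2d import ForwardSelectionMLR
from .synthetic import CompoundRecord
from .validation import assess, predictive_r2, rm_metrics

__all__ = ["RunConfig", "run_pipeline", "predict_application_set"]


@dataclass
class RunConfig:
    endpoints: list
    n_repeats: int = 1
    split_fraction: float = 0.8
    seed: int = 0
    arms: tuple = ("2d", "hologram", "3d")
    max_descriptors: int = 10
    n_subsets_kept: int = 3
    hologram_lengths: tuple = (53, 97, 151)
    hologram_ranges: tuple = ((4, 7), (1, 7))
    max_components: int = 6
    field_filters: tuple = (1, 2, 3, 4, 5)
    out_dir: str | None = None
    level: float = 0.95
    extra: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        for key in ("arms", "hologram_lengths", "field_filters"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "hologram_ranges" in kwargs:
            kwargs["hologram_ranges"] = tuple(
                tuple(r) for r in kwargs["hologram_ranges"])
        return cls(**kwargs)


def _validation_block(y_tr, fit_tr, loo_tr, y_te, pred_te, level):
    # band from cross-validated training predictions (calibration-faithful);
    # training rm² from fitted values (the printed-table convention)
    a = assess((y_tr, loo_tr), (y_te, pred_te), level=level)
    rt2, q2f1 = predictive_r2(y_te, pred_te)
    rm_tr = rm_metrics(y_tr, fit_tr)
    rm_te = rm_metrics(y_te, pred_te)
    n_te = len(y_te)
    return {
        "r_t2": rt2, "Q2F1": q2f1,
        "SE_external": float(np.sqrt(np.sum((y_te - pred_te) ** 2) / n_te)),
        "delta": a.delta_reported, "delta_raw": a.delta,
        "assessment": a.sign,
        "range_lo": a.prediction_range[0], "range_hi": a.prediction_range[1],
        "train_coverage": a.train_coverage,
        "external_coverage": a.external_coverage,
        "rm2": rm_tr.rm2, "rm2_prime": rm_tr.rm2_prime,
        "rm2_bar": rm_tr.rm2_bar, "rm2_delta": rm_tr.rm2_delta,
        "rm2_test": rm_te.rm2, "rm2_prime_test": rm_te.rm2_prime,
        "rm2_bar_test": rm_te.rm2_bar, "rm2_delta_test": rm_te.rm2_delta,
    }


def _loo_predictions_2d(model: ForwardSelectionMLR, X, y):
    from .pls import ols_loo_residuals
    Xs = np.asarray(X[model.selected_], dtype=float)
    return y - ols_loo_residuals(Xs, y)


def _fit_arm_2d(recs_tr, y_tr, recs_te, cfg):
    X_tr = compute_descriptors([r.mol for r in recs_tr],
                               ids=[r.id for r in recs_tr])
    est = ForwardSelectionMLR(max_descriptors=cfg.max_descriptors,
                              n_subsets_kept=cfg.n_subsets_kept,
                              seed=cfg.seed).fit(X_tr, y_tr)
    X_te = compute_descriptors([r.mol for r in recs_te],
                               ids=[r.id for r in recs_te])
    stats = {
        "R2": est.model_.r2, "SE": est.model_.se_train,
        "q2": est.model_.q2, "SE_LOO": est.model_.se_loo,
        "model_pvalue": est.model_.model_pvalue,
        "n_descriptors": len(est.selected_),
        "max_descriptor_pvalue": est.model_.max_descriptor_pvalue,
    }
    loo_tr = _loo_predictions_2d(est, X_tr, y_tr)
    return est, est.predict(X_tr), loo_tr, est.predict(X_te), stats


def _fit_arm_hologram(recs_tr, y_tr, recs_te, cfg):
    est = HologramQSAR(lengths=cfg.hologram_lengths,
                       ranges=cfg.hologram_ranges,
                       max_components=cfg.max_components)
    est.fit([r.mol for r in recs_tr], y_tr)
    from .pls import loo_predictions_pls
    H = est._holograms([r.mol for r in recs_tr])
    loo_tr = loo_predictions_pls(H, y_tr, est.best_.n_components)[:, -1]
    stats = {
        "R2": est.best_.r2, "SE": est.best_.se_train,
        "q2": est.best_.q2, "SE_LOO": est.best_.se_loo,
        "hologram_length": est.best_.length,
        "n_components": est.best_.n_components,
        "atom_range": f"{est.best_.atom_range[0]}-{est.best_.atom_range[1]}",
    }
    return (est, est.fitted_, loo_tr,
            est.predict([r.mol for r in recs_te]), stats)


def _fit_arm_3d(recs_tr, y_tr, recs_te, cfg):
    confs = {}
    for rec in recs_tr + recs_te:
        confs[rec.id] = embed_and_minimize(rec.mol, seed=cfg.seed,
                                           compound_id=rec.id)
    template = confs[recs_tr[0].id]
    aligned = {}
    for cid, c in confs.items():
        if c is template:
            aligned[cid] = c
            continue
        cm = common_core_map(c, template)
        aligned[cid], _ = align_to_template(c, template, cm)
    all_confs = list(aligned.values())
    grid = GridSpec.from_conformers(all_confs)
    block_tr = compute_fields([aligned[r.id] for r in recs_tr], grid)
    block_te = compute_fields([aligned[r.id] for r in recs_te], grid)
    qm = q2_matrix(block_tr, y_tr, filters=cfg.field_filters,
                   max_components=cfg.max_components)
    label, thr, k = qm.attrs["best"]
    fields = ("fa", "fe") if label == "CoMFA" else tuple(label.split("."))
    est = FieldQSAR(fields=fields, sigma_threshold=thr, n_components=k)
    est.fit(block_tr, y_tr)
    from .pls import loo_predictions_pls
    sub = block_tr.select_fields(fields).matrix[:, est.keep_]
    loo_tr = loo_predictions_pls(sub, y_tr, k)[:, -1]
    fit_tr = est.predict(block_tr)
    pred_te = est.predict(block_te)
    from .pls import press_q2
    q2, se_loo = press_q2(y_tr, loo_tr)
    ss = float(np.sum((y_tr - fit_tr) ** 2))
    stats = {
        "R2": est.r2_,
        "SE": float(np.sqrt(ss / max(len(y_tr) - k - 1, 1))),
        "q2": q2, "SE_LOO": se_loo,
        "field_subset": label, "column_filter": thr, "n_components": k,
    }
    return est, fit_tr, loo_tr, pred_te, stats, qm


_ARM_FITTERS = {"2d": _fit_arm_2d, "hologram": _fit_arm_hologram,
                "3d": _fit_arm_3d}


def run_pipeline(config: RunConfig, records: list[CompoundRecord],
                 activities: pd.DataFrame) -> dict:
    """Fit and assess every requested arm per endpoint and split repeat.

    Returns a manifest dict with a tidy report table under ``"report"``
    (one row per endpoint × repeat × arm); fitted models are under
    ``"models"``.  A failing stage is logged and skipped, preserving the
    rows already produced.
    """
    missing = [e for e in config.endpoints if e not in activities.columns]
    if missing:
        raise ValueError(f"endpoints not in activity table: {missing}")
    by_id = {r.id: r for r in records}
    rows, models, failures, q2_matrices = [], {}, [], {}
    for endpoint in config.endpoints:
        avail = activities[endpoint].dropna()
        recs = [by_id[i] for i in avail.index]
        y_all = avail
        plans = split_train_test(recs, fraction=config.split_fraction,
                                 n_repeats=config.n_repeats, seed=config.seed)
        for plan in plans:
            recs_tr = [by_id[i] for i in plan.train_ids]
            recs_te = [by_id[i] for i in plan.test_ids]
            y_tr = y_all.loc[plan.train_ids].to_numpy()
            y_te = y_all.loc[plan.test_ids].to_numpy()
            for arm in config.arms:
                try:
                    res = _ARM_FITTERS[arm](recs_tr, y_tr, recs_te, config)
                except Exception as exc:  # preserve partial results
                    failures.append({"endpoint": endpoint,
                                     "repeat": plan.repeat, "arm": arm,
                                     "error": f"{type(exc).__name__}: {exc}"})
                    continue
                est, fit_tr, loo_tr, pred_te, stats = res[:5]
                if arm == "3d":
                    q2_matrices[(endpoint, plan.repeat)] = res[5]
                row = {"endpoint": endpoint, "repeat": plan.repeat,
                       "arm": arm, "n_train": len(y_tr), "n_test": len(y_te)}
                row.update(stats)
                row.update(_validation_block(y_tr, fit_tr, loo_tr, y_te,
                                             pred_te, config.level))
                rows.append(row)
                models[(endpoint, plan.repeat, arm)] = est
    report = pd.DataFrame(rows)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "endpoints": list(config.endpoints),
        "n_repeats": config.n_repeats,
        "report": report,
        "models": models,
        "failures": failures,
        "q2_matrices": q2_matrices,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv", index=False)
        meta = {k: manifest[k] for k in ("version", "seed", "endpoints",
                                         "n_repeats")}
        meta["failures"] = failures
        (out / "manifest.json").write_text(json.dumps(meta, indent=2))
        for (endpoint, rep), qm in q2_matrices.items():
            qm.to_csv(out / f"q2_matrix_{endpoint}_r{rep}.csv")
    return manifest


def predict_application_set(models: dict, records: list[CompoundRecord],
                            assessments: dict | None = None) -> pd.DataFrame:
    """Consensus predictions for new structures from fitted arm models.

    ``models`` maps arm name → fitted estimator (2D estimators receive a
    descriptor matrix, hologram estimators molecules).  Each arm's
    prediction is flagged against the arm's training prediction range when
    ``assessments`` (arm → BandAssessment) is given; compounds outside
    every range stay in the table, flagged.  Ranking is by the unweighted
    mean of the arm predictions.
    """
    mols = [r.mol for r in records]
    preds = {}
    for arm, est in models.items():
        if isinstance(est, tuple):  # (FieldQSAR, FieldBlock) for the 3D arm
            est, block = est
            preds[arm] = est.predict(block)
        elif isinstance(est, ForwardSelectionMLR):
            X = compute_descriptors(mols, ids=[r.id for r in records])
            preds[arm] = est.predict(X)
        else:
            preds[arm] = est.predict(mols)
    df = pd.DataFrame(preds, index=[r.id for r in records])
    if assessments:
        for arm, a in assessments.items():
            lo, hi = a.prediction_range
            df[f"{arm}_in_range"] = (df[arm] >= lo) & (df[arm] <= hi)
    arm_cols = list(models)
    df["consensus"] = df[arm_cols].mean(axis=1)
    return df.sort_values("consensus", ascending=False)
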
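"""End-to-end orchestration: preprocess -> extract -> split -> standardize ->
LASSO -> supervised train -> pseudo-label -> fine-tune -> evaluate
(+ optional survival), with a replayable run record.

The run record keeps the patient-id ledgers (train / test / unlabeled); their
pairwise disjointness is asserted before any training happens, so leakage is
structurally impossible rather than merely discouraged.
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
from .config import RunConfig, config_to_dict
from .evaluation import evaluate_cohort, group_compare, operating_point
from .features.extract import ExtractionConfig, extract_cohort
from .filters import FilterBankConfig
from .io import CohortManifest, write_feature_table
from .model import (Standardizer, lasso_select, pseudo_label, self_train,
                    split_cohort, train_supervised)
from .preprocess import WindowParams, preprocess
from .survival import cox_ph, km_estimate, logrank_test, select_cutoff

logger = logging.getLogger(__name__)


@dataclass
class RunRecord:
    config_hash: str
    version: str
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    unlabeled_ids: list[str] = field(default_factory=list)
    pseudo_labeled_ids: list[str] = field(default_factory=list)
    n_features_extracted: int = 0
    n_features_selected: int = 0
    decision_threshold: float = 0.5
    survival_cutoff: float | None = None
    metrics: dict = field(default_factory=dict)

    def assert_disjoint(self) -> None:
        tr, te, un = (set(self.train_ids), set(self.test_ids),
                      set(self.unlabeled_ids))
        for a, b, names in ((tr, te, "train/test"), (tr, un,
                            "train/unlabeled"), (te, un, "test/unlabeled")):
            inter = a & b
            if inter:
                raise ValueError(
                    f"patient-id ledgers overlap ({names}): "
                    f"{sorted(inter)[:5]}")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def extract_from_manifest(manifest: CohortManifest,
                          cfg: RunConfig) -> pd.DataFrame:
    """Preprocess and extract features for every manifest row."""
    pp = cfg.preprocess
    window = WindowParams(pp.window_level, pp.window_width)
    ext_cfg = ExtractionConfig(
        filters=FilterBankConfig(cfg.filters.log_sigmas_mm,
                                 cfg.filters.wavelet_name),
        bin_width_hu=cfg.extraction.bin_width_hu,
        gldm_alpha=cfg.extraction.gldm_alpha)
    vols = []
    for pid in manifest.table["patient_id"]:
        try:
            vol = manifest.load_volume(pid)
            vols.append(preprocess(vol, pp.target_spacing_mm, window,
                                   pp.crop_margin_voxels))
        except Exception as err:
            raise RuntimeError(
                f"stage=preprocess patient={pid}: {err}") from err
    return extract_cohort(vols, ext_cfg)


def run_pipeline(cfg: RunConfig, manifest: CohortManifest,
                 out_dir=None,
                 features: pd.DataFrame | None = None) -> RunRecord:
    """Execute the full pipeline; returns the run record.

    ``features`` may carry a precomputed feature table (patient_id index)
    to skip the imaging stages, e.g. when replaying a run.
    """
    record = RunRecord(_config_hash(cfg), __version__)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if features is None:
        features = extract_from_manifest(manifest, cfg)
        if out is not None:
            write_feature_table(features, out / "features.csv")
    record.n_features_extracted = features.shape[1]

    table = manifest.table.set_index("patient_id")
    labeled_ids = manifest.labeled_ids
    unlabeled_ids = manifest.unlabeled_ids
    y_labeled = table.loc[labeled_ids, "pdl1_class"].astype(int)

    train_ids, test_ids = split_cohort(labeled_ids, y_labeled,
                                       cfg.train_fraction, cfg.split_seed)
    record.train_ids = list(map(str, train_ids))
    record.test_ids = list(map(str, test_ids))
    record.unlabeled_ids = list(map(str, unlabeled_ids))
    record.assert_disjoint()

    X_train = features.loc[train_ids]
    y_train = y_labeled.loc[train_ids].to_numpy()
    X_test = features.loc[test_ids]
    y_test = y_labeled.loc[test_ids].to_numpy()

    net_cfg = cfg.model.to_transformer_config()
    st = cfg.self_training
    if st.enabled and unlabeled_ids:
        model = self_train(X_train, y_train, features.loc[unlabeled_ids],
                           net_cfg, st.tau_lo, st.tau_hi,
                           test_ids=test_ids,
                           fine_tune_lr_factor=st.fine_tune_lr_factor,
                           pseudo_weight=st.pseudo_weight)
        if model.pseudo_label_record is not None:
            record.pseudo_labeled_ids = list(
                map(str, model.pseudo_label_record.ids))
    else:
        model = train_supervised(X_train, y_train, net_cfg)
    record.n_features_selected = len(model.selection.support)

    train_scores = model.predict_scores(X_train)
    test_scores = model.predict_scores(X_test)
    thr = operating_point(train_scores, y_train,
                          cfg.evaluation.target_sensitivity)
    model.decision_threshold = thr
    record.decision_threshold = float(thr)

    report = evaluate_cohort(test_scores, y_test, thr,
                             n_boot=cfg.evaluation.n_boot,
                             seed=cfg.evaluation.seed)
    p_mw, cohens_d = group_compare(test_scores, y_test)
    record.metrics = {
        "test_auc": report.auc,
        "test_auc_ci": (list(report.auc_ci)
                        if report.auc_ci is not None else None),
        "test_brier": report.brier, "test_accuracy": report.accuracy,
        "test_recall": report.recall, "test_specificity": report.specificity,
        "mann_whitney_p": p_mw, "cohens_d": cohens_d,
    }

    if cfg.survival.enabled and "time_months" in table.columns:
        tr_t = table.loc[train_ids, "time_months"].to_numpy(float)
        tr_e = table.loc[train_ids, "event"].to_numpy(int)
        te_t = table.loc[test_ids, "time_months"].to_numpy(float)
        te_e = table.loc[test_ids, "event"].to_numpy(int)
        try:
            cut = select_cutoff(train_scores, tr_t, tr_e,
                                cfg.survival.min_group_fraction)
            record.survival_cutoff = float(cut)
            hi = test_scores >= cut
            if 0 < hi.sum() < hi.size:
                chi2, p = logrank_test(te_t[hi], te_e[hi],
                                       te_t[~hi], te_e[~hi])
                km_hi = km_estimate(te_t[hi], te_e[hi])
                km_lo = km_estimate(te_t[~hi], te_e[~hi])
                record.metrics.update({
                    "logrank_p": p,
                    "median_pfs_high": km_hi.median,
                    "median_pfs_low": km_lo.median,
                })
        except ValueError as err:
            logger.warning("stage=survival skipped: %s", err)

    if out is not None:
        scores = pd.DataFrame({
            "patient_id": list(train_ids) + list(test_ids),
            "score": np.concatenate([train_scores, test_scores]),
            "cohort_tag": ["train"] * len(train_ids) + ["test"] * len(test_ids),
        })
        scores.to_csv(out / "scores.csv", index=False)
        record.to_json(out / "run_record.json")
    return record
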
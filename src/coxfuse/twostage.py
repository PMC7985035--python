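"""Two-stage model fusion.

First-stage networks are trained per data modality (e.g. histopathology
image features, gene expression). Their hidden-node activations —
low-dimensional "surrogate features" summarizing each modality — are
concatenated into a fused feature matrix on which a second-stage network
is trained with the same hyperparameter-selection strategy. The whole
two-stage procedure runs inside each training split, so no held-out
information reaches any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    CoxnnetModel,
    HoldoutPlan,
    TrainConfig,
    _fit,
    _holdout_split,
    grid_search_cv,
)
from .survival import (
    SurvivalDataset,
    apply_threshold,
    c_index,
    log_rank_test,
)

__all__ = ["extract_hidden", "fuse_and_train", "TwoStageModel",
           "two_stage_holdout"]


def extract_hidden(model: CoxnnetModel, X) -> np.ndarray:
    """Hidden-node activations (n x h) of a trained model, dropout off."""
    return model.hidden(X)


@dataclass
class TwoStageModel:
    """Self-contained fused model: stage-1 extractors plus the stage-2 net.

    ``predict`` takes one feature matrix per modality (in the order the
    stage-1 models were given) and returns the fused prognostic index, so
    a saved archive needs no external stage-1 files.
    """

    stage1: list            # list of CoxnnetModel
    stage2: CoxnnetModel
    provenance: list        # (modality index, hidden-node index) per fused column

    def fuse(self, X_list) -> np.ndarray:
        if len(X_list) != len(self.stage1):
            raise ValueError(
                f"expected {len(self.stage1)} modalities, got {len(X_list)}"
            )
        return np.hstack([extract_hidden(m, X)
                          for m, X in zip(self.stage1, X_list)])

    def predict(self, X_list) -> np.ndarray:
        return self.stage2.predict(self.fuse(X_list))


def fuse_and_train(models_and_X, data: SurvivalDataset, cfg: TrainConfig,
                   l2: float = None) -> TwoStageModel:
    """Concatenate stage-1 hidden activations and train the stage-2 net.

    ``models_and_X`` is a list of ``(CoxnnetModel, X)`` pairs, one per
    modality, with every ``X`` row-aligned to ``data``. Each stage-1 model
    must have been fitted only on ``data``'s samples (leakage guard). The
    fused matrix gets its own sqrt-width hidden layer and, unless ``l2``
    is given, its own grid-search CV.
    """
    if len(models_and_X) < 2:
        raise ValueError("fusion needs at least two modalities")
    ids = set(data.sample_ids)
    blocks, provenance = [], []
    for mod_idx, (model, X) in enumerate(models_and_X):
        if model.train_ids is not None and not ids <= set(model.train_ids):
            extra = sorted(ids - set(model.train_ids))[:5]
            raise ValueError(
                "stage-1 model was not trained on all stage-2 training "
                f"samples (information leak); e.g. {extra}"
            )
        H = extract_hidden(model, X)
        if H.shape[0] != data.n:
            raise ValueError("modality rows not aligned with survival data")
        blocks.append(H)
        provenance.extend((mod_idx, j) for j in range(H.shape[1]))
    H = np.hstack(blocks)
    fused = SurvivalDataset(
        data.sample_ids, H, data.T, data.d,
        feature_names=[f"m{m}_h{j}" for m, j in provenance],
    )
    if l2 is None:
        l2, _ = grid_search_cv(fused, cfg)
    stage2 = _fit(fused, cfg, l2)
    return TwoStageModel(stage1=[m for m, _ in models_and_X],
                         stage2=stage2, provenance=provenance)


def two_stage_holdout(datasets, plan: HoldoutPlan, cfg: TrainConfig,
                      modality_names=None) -> pd.DataFrame:
    """Repeated hold-out of the full two-stage pipeline.

    ``datasets`` is a list of :class:`SurvivalDataset`, one per modality,
    sharing sample ids, times and event indicators row for row. Each
    repetition retrains everything — stage-1 grid searches included —
    inside the training split, then reports per-modality and fused test
    C-indexes plus the fused test log-rank p-value (train-median split).
    """
    base = datasets[0]
    for ds in datasets[1:]:
        if ds.sample_ids != base.sample_ids:
            raise ValueError("modalities must share an identical sample set")
        if not (np.array_equal(ds.T, base.T) and np.array_equal(ds.d, base.d)):
            raise ValueError("modalities must share survival outcomes")
    if modality_names is None:
        modality_names = [f"modality_{i}" for i in range(len(datasets))]
    rows = []
    for rep, seed in enumerate(plan.seeds):
        tr_idx, te_idx = _holdout_split(base, plan.train_fraction, seed)
        rep_cfg = replace(cfg, seed=seed)
        row = {"repetition": rep, "seed": seed}
        stage1_pairs = []
        for name, ds in zip(modality_names, datasets):
            d_tr, d_te = ds.subset(tr_idx), ds.subset(te_idx)
            l2, _ = grid_search_cv(d_tr, rep_cfg)
            m = _fit(d_tr, rep_cfg, l2)
            row[f"test_c_index_{name}"] = c_index(
                m.predict(d_te.X), d_te.T, d_te.d
            )
            stage1_pairs.append((m, d_tr.X))
        surv_tr, surv_te = base.subset(tr_idx), base.subset(te_idx)
        ts = fuse_and_train(stage1_pairs, surv_tr, rep_cfg)
        eta_tr = ts.predict([ds.subset(tr_idx).X for ds in datasets])
        eta_te = ts.predict([ds.subset(te_idx).X for ds in datasets])
        row["train_c_index_fused"] = c_index(eta_tr, surv_tr.T, surv_tr.d)
        row["test_c_index_fused"] = c_index(eta_te, surv_te.T, surv_te.d)
        groups = apply_threshold(eta_te, float(np.median(eta_tr)))
        try:
            _, row["test_logrank_p_fused"] = log_rank_test(
                surv_te.T, surv_te.d, groups
            )
        except ValueError:
            row["test_logrank_p_fused"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
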
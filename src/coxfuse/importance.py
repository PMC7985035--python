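"""Mean-substitution (drop-out) feature importance.

Each input feature's importance is the drop in model partial
log-likelihood when that feature's column is replaced everywhere by its
mean: score_j = ll(X) - ll(X with column j set to mean_j). A feature the
model ignores scores exactly zero; informative features score positive.
Computed with the deterministic forward pass (no dropout).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CoxnnetModel
from .survival import SurvivalDataset, cox_partial_log_likelihood

__all__ = ["feature_importance", "top_k"]


def feature_importance(model: CoxnnetModel, data: SurvivalDataset,
                       means: np.ndarray = None) -> pd.DataFrame:
    """Importance table (feature, score, rank), sorted descending by score.

    ``means`` defaults to the column means of ``data.X`` — pass the
    training-split means explicitly when scoring on other data. Ties in
    score are broken lexicographically by feature name so the ranking is
    deterministic.
    """
    X = data.X
    if X.shape[1] != model.p:
        raise ValueError(
            f"feature-count mismatch: model expects {model.p}, got {X.shape[1]}"
        )
    if means is None:
        means = X.mean(axis=0)
    means = np.asarray(means, dtype=float).ravel()
    base_ll = cox_partial_log_likelihood(model.predict(X), data.T, data.d)
    scores = np.empty(model.p)
    Xw = X.copy()
    for j in range(model.p):
        col = Xw[:, j].copy()
        Xw[:, j] = means[j]
        scores[j] = base_ll - cox_partial_log_likelihood(
            model.predict(Xw), data.T, data.d
        )
        Xw[:, j] = col
    table = pd.DataFrame({"feature": data.feature_names, "score": scores})
    table = table.sort_values(
        ["score", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_k(table: pd.DataFrame, k: int) -> list:
    """Names of the k highest-importance features."""
    if k > len(table):
        raise ValueError(f"k={k} exceeds number of features {len(table)}")
    return table["feature"].head(k).tolist()
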
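"""Neural-network Cox proportional-hazards model.

A two-layer network: one fully connected hidden layer (width = floor of
the square root of the input width, tanh by default) feeding a linear
proportional-hazards output with no bias (the PI is shift-invariant).
Training maximizes the Breslow partial log-likelihood, averaged over
events, by full-batch gradient ascent with inverted dropout on the hidden
layer and an L2 penalty selected by grid search under k-fold
cross-validation. Evaluation uses repeated 80/20 hold-out.

All gradients are analytic; ``_objective_and_grads`` is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from .survival import (
    SurvivalDataset,
    apply_threshold,
    c_index,
    cox_partial_log_likelihood,
    dichotomize_by_median,
    log_rank_test,
)

__all__ = ["CoxnnetModel", "TrainConfig", "HoldoutPlan", "train",
           "grid_search_cv", "repeated_holdout", "hidden_width"]

DEFAULT_L2_GRID = tuple(np.logspace(-4, 0, 5))


def hidden_width(p: int) -> int:
    """Hidden-layer width: floor(sqrt(p)), at least 1."""
    return max(1, int(np.floor(np.sqrt(p))))


@dataclass
class TrainConfig:
    """Training and model-selection settings.

    Defaults follow the reference training recipe: full-batch gradient
    ascent at learning rate 0.01 for 500 epochs, dropout 0.7 on the hidden
    layer, L2 penalty chosen by grid search under 5-fold CV.
    """

    learning_rate: float = 0.01
    epochs: int = 500
    dropout_rate: float = 0.7
    l2_grid: tuple = DEFAULT_L2_GRID
    cv_folds: int = 5
    seed: int = 0
    activation: str = "tanh"
    momentum: float = 0.0  # off by default for reproducibility
    standardize: bool = True
    hidden: int = None     # override the sqrt rule (e.g. h = p for linear-PH)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class HoldoutPlan:
    """Repeated random train/test split plan: 80/20 x 20 by default."""

    train_fraction: float = 0.8
    repetitions: int = 20
    seeds: tuple = None

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.seeds is None:
            self.seeds = tuple(range(self.repetitions))
        if len(self.seeds) != self.repetitions:
            raise ValueError("need one seed per repetition")


_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(float)),
}


@dataclass
class CoxnnetModel:
    """Trained network: hidden weights, output coefficients, scaler state.

    Prediction is deterministic (dropout is a training-time device only):
    ``eta = beta . act(W^T x_std + b)`` with ``x_std`` the z-scored input
    using training-split statistics stored on the model.
    """

    W: np.ndarray            # (p, h)
    b: np.ndarray            # (h,)
    beta: np.ndarray         # (h,)
    activation: str = "tanh"
    dropout_rate: float = 0.7
    x_mean: np.ndarray = None
    x_std: np.ndarray = None
    l2: float = 0.0
    feature_names: list = None
    train_ids: tuple = None  # sample ids the model saw during fitting
    loss_trace: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.W.shape[1] != len(self.b) or len(self.b) != len(self.beta):
            raise ValueError("inconsistent hidden-layer dimensions")
        if self.x_mean is None:
            self.x_mean = np.zeros(self.W.shape[0])
        if self.x_std is None:
            self.x_std = np.ones(self.W.shape[0])

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def h(self) -> int:
        return self.W.shape[1]

    def _standardized(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(
                f"feature-count mismatch: model expects {self.p}, got {X.shape[1]}"
            )
        return (X - self.x_mean) / self.x_std

    def hidden(self, X) -> np.ndarray:
        """Hidden-node activations (n x h), dropout off."""
        act, _ = _ACTIVATIONS[self.activation]
        return act(self._standardized(X) @ self.W + self.b)

    def predict(self, X) -> np.ndarray:
        """Prognostic index (log hazard ratio) per sample."""
        return self.hidden(X) @ self.beta

    # alias used throughout the docs
    forward = predict


def _init_params(p, h, rng):
    """Glorot-style scaled-uniform initialization."""
    lim_w = np.sqrt(6.0 / (p + h))
    W = rng.uniform(-lim_w, lim_w, size=(p, h))
    b = np.zeros(h)
    lim_b = np.sqrt(6.0 / (h + 1))
    beta = rng.uniform(-lim_b, lim_b, size=h)
    return W, b, beta


def _pll_grad_eta(eta, sort_cache):
    """Gradient of the event-averaged Breslow partial log-likelihood wrt eta.

    ``sort_cache`` carries time-only structures from :func:`_sort_structures`:
    the ascending-time order, each sorted position's tie-group start (risk-set
    denominator index) and end, and the sorted event indicator.
    """
    order, denom_index, group_last, d_sorted = sort_cache
    n_events = d_sorted.sum()
    eta_s = eta[order]
    shift = eta_s.max()
    # divergence (non-finite objective) is detected and reported by the
    # caller, so numeric warnings on that path are suppressed here
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        es = np.exp(eta_s - shift)
        rev_cum = np.cumsum(es[::-1])[::-1]
        denom = rev_cum[denom_index]
        ll = np.sum(d_sorted * ((eta_s - shift) - np.log(denom))) / n_events
        # A_k = sum over events i with T_i <= T_k of 1/S_i; ties share
        # events, so each position reads the cumsum at its tie-group end
        cum = np.cumsum(d_sorted / denom)
        A = cum[group_last]
        g_sorted = (d_sorted - es * A) / n_events
    g = np.empty_like(g_sorted)
    g[order] = g_sorted
    return ll, g


def _sort_structures(T, d):
    T = np.asarray(T, dtype=float)
    d = np.asarray(d)
    order = np.argsort(T, kind="stable")
    Ts = T[order]
    n = len(T)
    first = np.ones(n, dtype=bool)
    first[1:] = Ts[1:] != Ts[:-1]
    denom_index = np.maximum.accumulate(np.where(first, np.arange(n), 0))
    last = np.ones(n, dtype=bool)
    last[:-1] = Ts[1:] != Ts[:-1]
    group_last = np.minimum.accumulate(
        np.where(last, np.arange(n), n - 1)[::-1]
    )[::-1]
    return order, denom_index, group_last, d[order].astype(float)


def _objective_and_grads(W, b, beta, Xs, l2, mask, keep_prob,
                         act_name, sort_cache):
    """Penalized, event-averaged objective and its analytic gradients.

    ``mask / keep_prob`` implements inverted dropout on the hidden
    activations; pass an all-ones mask with keep_prob 1 for the
    deterministic objective.
    """
    act, dact = _ACTIVATIONS[act_name]
    Z = Xs @ W + b
    a = act(Z)
    a_drop = a * (mask / keep_prob)
    eta = a_drop @ beta
    ll, g_eta = _pll_grad_eta(eta, sort_cache)
    obj = ll - l2 * (np.sum(W * W) + np.sum(beta * beta))
    g_beta = a_drop.T @ g_eta - 2.0 * l2 * beta
    g_a = (g_eta[:, None] * beta[None, :]) * (mask / keep_prob)
    g_z = g_a * dact(a)
    g_W = Xs.T @ g_z - 2.0 * l2 * W
    g_b = g_z.sum(axis=0)
    return obj, g_W, g_b, g_beta


def train(data: SurvivalDataset, cfg: TrainConfig, l2: float = None) -> CoxnnetModel:
    """Fit the network on a full dataset.

    If ``l2`` is None the penalty is chosen by :func:`grid_search_cv`
    first; otherwise the model is fit directly at the given penalty.
    """
    if l2 is None:
        best, _ = grid_search_cv(data, cfg)
        l2 = best
    return _fit(data, cfg, l2)


def _fit(data: SurvivalDataset, cfg: TrainConfig, l2: float) -> CoxnnetModel:
    if data.n_events == 0:
        raise ValueError("cannot train with zero observed events")
    rng = np.random.default_rng(cfg.seed)
    X = data.X
    if cfg.standardize:
        x_mean = X.mean(axis=0)
        x_std = X.std(axis=0)
        x_std[x_std == 0] = 1.0
    else:
        x_mean = np.zeros(data.p)
        x_std = np.ones(data.p)
    Xs = (X - x_mean) / x_std
    p = data.p
    h = cfg.hidden if cfg.hidden is not None else hidden_width(p)
    W, b, beta = _init_params(p, h, rng)
    keep_prob = 1.0 - cfg.dropout_rate
    sort_cache = _sort_structures(data.T, data.d)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    vbeta = np.zeros_like(beta)
    trace = np.empty(cfg.epochs)
    n = data.n
    for epoch in range(cfg.epochs):
        if cfg.dropout_rate > 0:
            mask = (rng.random((n, h)) < keep_prob).astype(float)
        else:
            mask = np.ones((n, h))
        obj, g_W, g_b, g_beta = _objective_and_grads(
            W, b, beta, Xs, l2, mask, keep_prob, cfg.activation, sort_cache,
        )
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite training objective at epoch {epoch}; "
                "reduce the learning rate or increase the penalty"
            )
        trace[epoch] = obj
        lr = cfg.learning_rate
        if cfg.momentum > 0:
            vW = cfg.momentum * vW + g_W
            vb = cfg.momentum * vb + g_b
            vbeta = cfg.momentum * vbeta + g_beta
            W += lr * vW
            b += lr * vb
            beta += lr * vbeta
        else:
            W += lr * g_W
            b += lr * g_b
            beta += lr * g_beta
    return CoxnnetModel(
        W=W, b=b, beta=beta, activation=cfg.activation,
        dropout_rate=cfg.dropout_rate, x_mean=x_mean, x_std=x_std, l2=l2,
        feature_names=list(data.feature_names),
        train_ids=tuple(data.sample_ids), loss_trace=trace,
    )


def grid_search_cv(data: SurvivalDataset, cfg: TrainConfig):
    """Select the L2 penalty by k-fold CV on the partial log-likelihood.

    The CV criterion is the mean validation partial log-likelihood per
    event (the training objective); the validation C-index is reported
    alongside. Returns ``(best_l2, score_table)``.
    """
    grid = list(cfg.l2_grid)
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    folds = []
    for tr_idx, va_idx in kf.split(np.arange(data.n)):
        if data.d[va_idx].sum() == 0 or data.d[tr_idx].sum() == 0:
            # one reshuffle with a shifted seed, then give up
            kf2 = KFold(n_splits=cfg.cv_folds, shuffle=True,
                        random_state=cfg.seed + 1)
            folds = []
            for tr2, va2 in kf2.split(np.arange(data.n)):
                if data.d[va2].sum() == 0 or data.d[tr2].sum() == 0:
                    raise ValueError(
                        "a CV fold has zero events even after resampling; "
                        "dataset too small or censoring too heavy"
                    )
                folds.append((tr2, va2))
            break
        folds.append((tr_idx, va_idx))
    rows = []
    for l2 in grid:
        lls, cis = [], []
        for tr_idx, va_idx in folds:
            try:
                m = _fit(data.subset(tr_idx), cfg, l2)
            except FloatingPointError:
                # divergent grid point (penalty too large for the fixed
                # step): score it as unusable instead of aborting the search
                lls.append(-np.inf)
                cis.append(np.nan)
                continue
            eta_va = m.predict(data.X[va_idx])
            T_va, d_va = data.T[va_idx], data.d[va_idx]
            lls.append(
                cox_partial_log_likelihood(eta_va, T_va, d_va) / d_va.sum()
            )
            try:
                cis.append(c_index(eta_va, T_va, d_va))
            except ValueError:
                cis.append(np.nan)
        cis_ok = [c for c in cis if not np.isnan(c)]
        rows.append({"l2": l2, "cv_pll_per_event": float(np.mean(lls)),
                     "cv_c_index": float(np.mean(cis_ok)) if cis_ok else np.nan})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["cv_pll_per_event"].idxmax(), "l2"])
    return best, table


def repeated_holdout(data: SurvivalDataset, plan: HoldoutPlan,
                     cfg: TrainConfig) -> pd.DataFrame:
    """Repeated 80/20 hold-out evaluation.

    Per repetition: split, grid-search the penalty on the training split,
    refit there, then report train/test C-index and the test log-rank
    p-value from a median split. The dichotomization threshold is the
    TRAINING-split median PI, applied unchanged to the held-out samples.
    """
    rows = []
    for rep, seed in enumerate(plan.seeds):
        tr_idx, te_idx = _holdout_split(data, plan.train_fraction, seed)
        d_tr = data.subset(tr_idx)
        rep_cfg = replace(cfg, seed=seed)
        best_l2, _ = grid_search_cv(d_tr, rep_cfg)
        model = _fit(d_tr, rep_cfg, best_l2)
        eta_tr = model.predict(d_tr.X)
        d_te = data.subset(te_idx)
        eta_te = model.predict(d_te.X)
        thr = float(np.median(eta_tr))
        groups_te = apply_threshold(eta_te, thr)
        try:
            _, p_te = log_rank_test(d_te.T, d_te.d, groups_te)
        except ValueError:
            p_te = np.nan
        rows.append({
            "repetition": rep, "seed": seed, "l2": best_l2,
            "train_c_index": c_index(eta_tr, d_tr.T, d_tr.d),
            "test_c_index": c_index(eta_te, d_te.T, d_te.d),
            "test_logrank_p": p_te,
        })
    return pd.DataFrame(rows)


def _holdout_split(data: SurvivalDataset, train_fraction: float, seed: int,
                   max_tries: int = 10):
    """Random split with >= 2 events on each side; resamples on failure."""
    idx = np.arange(data.n)
    for t in range(max_tries):
        tr, te = train_test_split(
            idx, train_size=train_fraction, random_state=seed + t
        )
        if data.d[tr].sum() >= 2 and data.d[te].sum() >= 2:
            if t > 0:
                warnings.warn(
                    f"degenerate split at seed {seed}; resampled {t} time(s)"
                )
            return tr, te
    raise ValueError("could not find a split with >= 2 events per side")


def holdout_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR spread of the hold-out metrics."""
    cols = ["train_c_index", "test_c_index", "test_logrank_p"]
    return pd.DataFrame({
        "median": table[cols].median(),
        "iqr": table[cols].quantile(0.75) - table[cols].quantile(0.25),
    })
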
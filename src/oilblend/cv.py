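"""10-fold cross-validation harness, metrics and model-stage adapters.

The evaluation protocol: samples are randomly split into ten equal-size
partitions; each partition serves once as the prediction set while the
other nine form the calibration set, and the reported figures are the
means over the ten folds.  In the default ``fold_safe`` mode everything
learned from data — the MSC reference, the wavelength subset, the model
— is fitted on the calibration partition only.  ``pooled`` mode
fits pretreatment and selection once on all samples before the split,
matching protocols that pretreat globally; the mode is recorded in the
result's provenance.

Metrics: classification accuracy ``m_k / n``; regression
``R^2 = 1 - SS_res / SS_tot`` and ``RMSE = sqrt(SS_res / n)``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, SVR

from .exceptions import ConfigError, ParameterError
from .pls import choose_components, pls_fit, pls_predict
from .pretreat import apply_pretreatment, fit_pretreatment
from .select import (
    CARSConfig,
    cars_select,
    pca_loading_select,
    spa_select,
    vip_select,
)
from .spectra import SpectrumSet
from .synth import assign_class_labels

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- metrics

def accuracy(labels_true, labels_pred) -> float:
    """Fraction of correctly predicted samples, ``m_k / n``."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape or t.ndim != 1:
        raise ParameterError("label arrays must be 1-D with equal length")
    if t.size == 0:
        raise ParameterError("accuracy undefined for zero samples")
    return float(np.mean(t == p))


def r2_rmse(y_true, y_pred) -> tuple[float, float]:
    """Coefficient of determination and root mean square error.

    ``R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2``;
    ``RMSE = sqrt(sum (y_i - yhat_i)^2 / n)``.  A constant truth vector
    leaves R^2 undefined and raises; RMSE alone is then still available
    via a direct call with a non-constant truth.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.size != yh.size or y.size < 2:
        raise ParameterError("need equal-length vectors with n >= 2")
    ss_res = float(np.sum((y - yh) ** 2))
    rmse = float(np.sqrt(ss_res / y.size))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ParameterError(f"R^2 undefined for constant y (RMSE={rmse:g})")
    return 1.0 - ss_res / ss_tot, rmse


# ------------------------------------------------------------- fold plans

@dataclass(frozen=True)
class FoldPlan:
    """A disjoint, exhaustive partition of samples into folds."""

    n_samples: int
    folds: int
    assignment: np.ndarray  # sample index -> fold index
    seed: int

    def split(self):
        """Yield (calibration indices, prediction indices) per fold."""
        for f in range(self.folds):
            pred = np.flatnonzero(self.assignment == f)
            cal = np.flatnonzero(self.assignment != f)
            yield cal, pred


def make_folds(n: int, folds: int = 10, seed: int = 0,
               stratify_by=None) -> FoldPlan:
    """Random fold assignment; sizes differ by at most one.

    With ``stratify_by``, samples sharing a stratum value are dealt
    round-robin across folds so every fold spans the response range.
    """
    if folds > n or folds < 1:
        raise ParameterError(f"folds must lie in [1, n={n}], got {folds}")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        order = rng.permutation(n)
    else:
        strata = np.asarray(stratify_by)
        if strata.size != n:
            raise ParameterError("stratify_by length must equal n")
        order = []
        for value in sorted(map(str, set(strata.tolist()))):
            members = np.flatnonzero(strata.astype(str) == value)
            order.extend(rng.permutation(members).tolist())
        order = np.asarray(order)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.arange(n) % folds
    return FoldPlan(n_samples=n, folds=folds, assignment=assignment, seed=seed)


# --------------------------------------------------------- model adapters

_DEFAULT_HYPERPARAMS = {
    "svm": {"C": 1000.0, "gamma": "auto", "kernel": "rbf"},
    "svr": {"C": 10.0, "gamma": "auto", "kernel": "rbf"},
    "rf": {"n_estimators": 500},
    "knn": {"n_neighbors": 5},
    "plsr": {"max_components": 15, "folds": 10},
}


class _PLSRegressorAdapter:
    """fit/predict wrapper giving NIPALS PLS the estimator contract."""

    def __init__(self, max_components: int = 15, folds: int = 10, seed: int = 0,
                 n_components: int | None = None):
        self.max_components = max_components
        self.folds = folds
        self.seed = seed
        self.n_components = n_components
        self.model_ = None

    def fit(self, X, y):
        a = self.n_components
        if a is None:
            a = choose_components(X, y, max_components=self.max_components,
                                  folds=min(self.folds, len(y)), seed=self.seed)
        self.model_ = pls_fit(X, y, a)
        return self

    def predict(self, X):
        return pls_predict(self.model_, X)


def _merge(kind: str, hyperparams: dict | None) -> dict:
    params = dict(_DEFAULT_HYPERPARAMS.get(kind, {}))
    params.update(hyperparams or {})
    return params


def fit_classifier(kind: str, X, y, hyperparams: dict | None = None,
                   seed: int = 0):
    """Fit a classification model: ``svm``, ``rf`` or ``knn``.

    Radial-kernel SVM defaults to C=1000, gamma=1/p; RF uses 500 trees
    with a threaded seed; KNN uses 5 neighbours.
    """
    params = _merge(kind, hyperparams)
    if kind == "svm":
        est = SVC(**params)
    elif kind == "rf":
        est = RandomForestClassifier(random_state=seed, **params)
    elif kind == "knn":
        est = KNeighborsClassifier(**params)
    else:
        raise ConfigError(f"unknown classifier kind {kind!r}")
    return est.fit(np.asarray(X, float), np.asarray(y))


def fit_regressor(kind: str, X, y, hyperparams: dict | None = None,
                  seed: int = 0):
    """Fit a regression model: ``plsr`` (native), ``svr`` or ``rf``."""
    params = _merge(kind, hyperparams)
    if kind == "plsr":
        est = _PLSRegressorAdapter(seed=seed, **params)
    elif kind == "svr":
        est = SVR(**params)
    elif kind == "rf":
        est = RandomForestRegressor(random_state=seed, **params)
    else:
        raise ConfigError(f"unknown regressor kind {kind!r}")
    return est.fit(np.asarray(X, float), np.asarray(y, float))


# ------------------------------------------------------------ correlation

def pcc_by_wavelength(data: SpectrumSet, target: np.ndarray | None = None):
    """Pearson correlation of reflectance with the mixing ratio, per wavelength.

    Returns ``(pcc, p_value)`` arrays over the grid; the two-sided
    p-value comes from the exact t reference distribution with n-2
    degrees of freedom.  Constant reflectance columns get NaN (flagged,
    not fatal).
    """
    y = data.ratios() if target is None else np.asarray(target, dtype=float)
    n = data.n_samples
    if n < 3:
        raise ParameterError("correlation needs at least 3 samples")
    if np.ptp(y) == 0:
        raise ParameterError("ratios are constant; correlation undefined")
    X = data.reflectance
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc ** 2, axis=0))
    sy = np.sqrt(np.sum(yc ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.where(sx == 0, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    n_const = int(np.count_nonzero(np.isnan(r)))
    if n_const:
        logger.warning("PCC undefined at %d constant wavelengths", n_const)
    return r, p


# ------------------------------------------------------------ CV pipeline

@dataclass(frozen=True)
class PipelineConfig:
    """One end-to-end run: task, pretreatment, selection, model, folds."""

    task: str = "regress_rate"          # or "classify_type"
    case: str | None = None             # row filter for per-case regression
    pretreatment: str = "raw"
    pretreatment_params: dict = field(default_factory=dict)
    selection: str | None = None        # pca | vip | spa | cars | None (full)
    selection_params: dict = field(default_factory=dict)
    model: str = "plsr"
    hyperparams: dict = field(default_factory=dict)
    folds: int = 10
    seed: int = 0
    leakage_mode: str = "fold_safe"     # or "pooled"
    invert_target: bool = False         # predict soybean fraction instead

    def __post_init__(self) -> None:
        if self.task not in ("regress_rate", "classify_type"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.leakage_mode not in ("fold_safe", "pooled"):
            raise ConfigError(f"unknown leakage_mode {self.leakage_mode!r}")
        if self.selection is not None and self.selection not in (
                "pca", "vip", "spa", "cars"):
            raise ConfigError(f"unknown selection {self.selection!r}")


@dataclass
class CVResult:
    """Per-fold and aggregated cross-validation metrics with provenance."""

    per_fold: list[dict]
    aggregates: dict[str, float]
    config: dict
    seed: int


def _run_selection(config: PipelineConfig, X: np.ndarray,
                   y: np.ndarray) -> np.ndarray:
    params = dict(config.selection_params)
    if config.selection == "pca":
        params.setdefault("k", max(2, X.shape[1] // 20))
        return pca_loading_select(X, **params).selected
    if config.selection == "vip":
        params.setdefault("seed", config.seed)
        return vip_select(X, y, **params).selected
    if config.selection == "spa":
        params.setdefault("k_min", 5)
        params.setdefault("k_max", min(30, X.shape[0] - 2, X.shape[1]))
        params.setdefault("seed", config.seed)
        return spa_select(X, y, **params).selected
    cars_cfg = CARSConfig(seed=config.seed, **params)
    return cars_select(X, y, cars_cfg).selected


def _pipeline_rows(data: SpectrumSet, config: PipelineConfig) -> np.ndarray:
    """Row filter: case restriction; the 50% blends leave the class task."""
    keep = np.ones(data.n_samples, dtype=bool)
    if config.case is not None:
        keep &= np.array([m.case == config.case for m in data.meta])
    if config.task == "classify_type":
        keep &= np.abs(data.ratios() - 0.5) > 1e-9
    return np.flatnonzero(keep)


def run_cv_pipeline(data: SpectrumSet, config: PipelineConfig) -> CVResult:
    """Cross-validate one pipeline configuration end to end.

    Per fold the pretreatment state, the wavelength subset (if any) and
    the model are fitted on the calibration partition and applied to
    both partitions; aggregates are arithmetic means over folds.
    """
    if config.task == "classify_type" and any(
            m.class_label is None and abs(m.genuine_ratio - 0.5) > 1e-9
            for m in data.meta):
        data = assign_class_labels(data)
    rows = _pipeline_rows(data, config)
    if rows.size == 0:
        raise ConfigError("no samples left after filtering")
    work = data.subset(rows)

    if config.task == "classify_type":
        y = np.asarray(work.labels(), dtype=object)
        strata = y
    else:
        y = work.ratios()
        if config.invert_target:
            y = 1.0 - y
        strata = np.round(y, 6)

    plan = make_folds(work.n_samples, folds=config.folds, seed=config.seed,
                      stratify_by=strata)

    global_set = None
    global_cols = None
    if config.leakage_mode == "pooled":
        state = fit_pretreatment(config.pretreatment, calibration=work,
                                 **config.pretreatment_params)
        global_set = apply_pretreatment(state, work)
        if config.selection is not None:
            sel_y = work.ratios() if config.task == "classify_type" else y
            global_cols = _run_selection(config, global_set.reflectance, sel_y)

    per_fold: list[dict] = []
    for fold_id, (cal, pred) in enumerate(plan.split()):
        if global_set is not None:
            Xc_full = global_set.reflectance[cal]
            Xp_full = global_set.reflectance[pred]
            cols = global_cols
        else:
            state = fit_pretreatment(config.pretreatment,
                                     calibration=work.subset(cal),
                                     **config.pretreatment_params)
            Xc_full = apply_pretreatment(state, work.subset(cal)).reflectance
            Xp_full = apply_pretreatment(state, work.subset(pred)).reflectance
            cols = None
            if config.selection is not None:
                sel_y = (work.ratios()[cal] if config.task == "classify_type"
                         else y[cal])
                cols = _run_selection(config, Xc_full, sel_y)
        if cols is None:
            Xc, Xp = Xc_full, Xp_full
            n_sel = Xc_full.shape[1]
        else:
            Xc, Xp = Xc_full[:, cols], Xp_full[:, cols]
            n_sel = int(len(cols))

        record: dict[str, Any] = {"fold": fold_id, "n_selected": n_sel}
        if config.task == "classify_type":
            est = fit_classifier(config.model, Xc, y[cal],
                                 hyperparams=config.hyperparams,
                                 seed=config.seed)
            record["acc_c"] = accuracy(y[cal], est.predict(Xc))
            record["acc_p"] = accuracy(y[pred], est.predict(Xp))
        else:
            est = fit_regressor(config.model, Xc, y[cal],
                                hyperparams=config.hyperparams,
                                seed=config.seed)
            record["r2_c"], record["rmse_c"] = r2_rmse(y[cal], est.predict(Xc))
            record["r2_p"], record["rmse_p"] = r2_rmse(y[pred], est.predict(Xp))
        per_fold.append(record)
        logger.info("fold %d/%d done (%s)", fold_id + 1, config.folds,
                    config.model)

    metric_keys = [k for k in per_fold[0] if k != "fold"]
    aggregates = {k: float(np.mean([f[k] for f in per_fold]))
                  for k in metric_keys}
    snapshot = asdict(config)
    return CVResult(per_fold=per_fold, aggregates=aggregates,
                    config=snapshot, seed=config.seed)
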
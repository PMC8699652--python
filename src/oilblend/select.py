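"""Effective-wavelength selection: PCA loadings, VIP, SPA and CARS.

Full Vis-NIR spectra carry thousands of collinear, partly uninformative
wavelengths; these four algorithms each return a small subset intended
to preserve (or improve) predictive power while simplifying the model:

* **PCA loadings** — rank wavelengths by their largest absolute loading
  across the leading principal components of the spectra (unsupervised).
* **VIP** — rank by variable importance in projection from a fitted PLS
  model; keep scores above a cutoff (default 1.0) or a fixed top-k.
* **SPA** (successive projections algorithm) — forward selection of
  minimally collinear wavelengths by maximal residual norm after
  orthogonal projection off the chosen span; candidate chains are scored
  by cross-validated least-squares RMSE.
* **CARS** (competitive adaptive reweighted sampling) — Monte-Carlo PLS
  runs on row subsamples with an exponentially shrinking, coefficient-
  weighted wavelength retention; the run whose subset has the lowest
  10-fold RMSECV wins.

All selectors return sorted, duplicate-free indices and are
deterministic for a fixed seed; ranking ties break toward the lower
wavelength index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.model_selection import KFold

from .exceptions import ParameterError, SelectionError
from .pls import choose_components, pls_fit, pls_predict, vip_scores

logger = logging.getLogger(__name__)

ALGORITHMS = ("pca", "vip", "spa", "cars")


@dataclass
class SelectionResult:
    """Selected wavelength indices plus per-algorithm diagnostics."""

    algorithm: str
    selected: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None
    n_wavelengths: int | None = None  # grid size, for overlap sanity checks

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=int)
        if sel.size < 1:
            raise SelectionError(f"{self.algorithm}: empty selection")
        if np.any(np.diff(sel) <= 0):
            raise SelectionError(f"{self.algorithm}: indices must be sorted, unique")
        if sel[0] < 0 or (self.n_wavelengths is not None
                          and sel[-1] >= self.n_wavelengths):
            raise SelectionError(f"{self.algorithm}: index out of grid bounds")
        self.selected = sel

    @property
    def n_selected(self) -> int:
        return int(self.selected.size)


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties go to the lower index."""
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def pca_loading_select(X: np.ndarray, k: int, n_pcs: int | None = None,
                       var_explained: float = 0.99) -> SelectionResult:
    """Keep the k wavelengths with the largest absolute PCA loading.

    Each wavelength is scored by its maximum absolute loading over the
    first ``n_pcs`` principal components of the column-centred spectra;
    by default ``n_pcs`` is the smallest count explaining
    ``var_explained`` of the variance.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= k <= p:
        raise ParameterError(f"k must lie in [1, p={p}], got {k}")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    r = int(np.count_nonzero(var > var[0] * 1e-24)) or 1
    if n_pcs is None:
        frac = np.cumsum(var[:r]) / var[:r].sum()
        n_pcs = int(np.searchsorted(frac, var_explained) + 1)
    if not 1 <= n_pcs <= r:
        raise ParameterError(f"n_pcs must lie in [1, rank={r}], got {n_pcs}")
    scores = np.abs(vt[:n_pcs]).max(axis=0)
    return SelectionResult(
        algorithm="pca",
        selected=_top_k(scores, k),
        diagnostics={"loading_scores": scores, "n_pcs": n_pcs},
        n_wavelengths=p,
    )


def vip_select(X: np.ndarray, y: np.ndarray, threshold: float = 1.0,
               k: int | None = None, max_components: int = 15,
               folds: int = 10, seed: int = 0) -> SelectionResult:
    """Keep wavelengths whose VIP score passes a cutoff (or a fixed top-k).

    Fits PLS with the RMSECV-selected component count, computes VIP
    scores, then applies either ``VIP > threshold`` (default 1.0) or, if
    ``k`` is given, the top-k rule.  An empty threshold selection falls
    back to the single best wavelength with a warning.
    """
    X = np.asarray(X, dtype=float)
    a = choose_components(X, y, max_components=max_components,
                          folds=min(folds, X.shape[0]), seed=seed)
    model = pls_fit(X, y, a)
    vip = vip_scores(model)
    if k is not None:
        selected = _top_k(vip, k)
    else:
        selected = np.flatnonzero(vip > threshold)
        if selected.size == 0:
            warnings.warn("no VIP score above threshold; keeping the top "
                          "wavelength", stacklevel=2)
            selected = _top_k(vip, 1)
    return SelectionResult(
        algorithm="vip",
        selected=selected,
        diagnostics={"vip_scores": vip, "n_components": a,
                     "rule": "top-k" if k is not None else f">{threshold}"},
        seed=seed,
        n_wavelengths=X.shape[1],
    )


def _spa_chain(Xc: np.ndarray, start: int, length: int) -> list[int]:
    """One forward SPA chain from a start column via Gram-Schmidt deflation."""
    R = Xc.copy()
    chain = [start]
    alive = np.ones(R.shape[1], dtype=bool)
    alive[start] = False
    current = start
    for _ in range(length - 1):
        u = R[:, current]
        uu = float(u @ u)
        if uu <= 1e-24:
            break
        R = R - np.outer(u, u @ R) / uu
        norms = np.einsum("ij,ij->j", R, R)
        norms[~alive] = -1.0
        nxt = int(np.argmax(norms))  # argmax takes the first (lowest) index on ties
        if norms[nxt] <= 1e-24:
            break
        chain.append(nxt)
        alive[nxt] = False
        current = nxt
    return chain


def _cv_lstsq_rmse(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """RMSE of cross-validated ordinary least squares with intercept."""
    n = X.shape[0]
    kf = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
    sse = 0.0
    for train, test in kf.split(X):
        A = np.column_stack([np.ones(len(train)), X[train]])
        coef, *_ = np.linalg.lstsq(A, y[train], rcond=None)
        pred = np.column_stack([np.ones(len(test)), X[test]]) @ coef
        sse += float(np.sum((y[test] - pred) ** 2))
    return float(np.sqrt(sse / n))


def spa_select(X: np.ndarray, y: np.ndarray, k_min: int, k_max: int,
               n_starts: int | None = None, cv_folds: int = 5,
               seed: int = 0) -> SelectionResult:
    """Successive projections algorithm with CV-scored chain prefixes.

    For each candidate start column a chain of length ``k_max`` is grown
    by repeatedly adding the column with the largest norm after
    orthogonal projection off the span of the chain.  Every prefix of
    length ``k_min..k_max`` is scored by ``cv_folds``-fold least-squares
    RMSE against ``y``; the best-scoring prefix over all starts wins.

    ``n_starts`` limits the candidate starts to that many evenly spaced
    columns (default ``min(p, 50)``; pass ``p`` to try every column).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if not 1 <= k_min <= k_max or k_max > min(n - 1, p):
        raise ParameterError(
            f"need 1 <= k_min <= k_max <= min(n-1, p) = {min(n - 1, p)}; "
            f"got k_min={k_min}, k_max={k_max}"
        )
    if n_starts is None:
        n_starts = min(p, 50)
    starts = np.unique(np.linspace(0, p - 1, num=min(n_starts, p)).astype(int))
    Xc = X - X.mean(axis=0)

    best: tuple[float, int, int] | None = None  # (rmse, length, start order)
    best_chain: list[int] = []
    chain_rmse: dict[int, list[float]] = {}
    for si, start in enumerate(starts):
        chain = _spa_chain(Xc, int(start), k_max)
        scores = []
        for length in range(k_min, min(k_max, len(chain)) + 1):
            cols = chain[:length]
            rmse = _cv_lstsq_rmse(X[:, cols], y, cv_folds, seed)
            scores.append(rmse)
            key = (rmse, length, si)
            if best is None or key < best:
                best = key
                best_chain = cols
        chain_rmse[int(start)] = scores
    if best is None:
        raise SelectionError("SPA produced no scoreable chain")
    return SelectionResult(
        algorithm="spa",
        selected=np.sort(np.asarray(best_chain, dtype=int)),
        diagnostics={"chain_rmse": chain_rmse, "best_rmse": best[0],
                     "chain": best_chain},
        seed=seed,
        n_wavelengths=p,
    )


@dataclass(frozen=True)
class CARSConfig:
    """Monte-Carlo settings for CARS."""

    n_runs: int = 50
    sample_fraction: float = 0.8
    folds: int = 10
    seed: int = 0
    n_components: int = 10  # latent-variable cap for the per-run PLS fits

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ParameterError("CARS needs n_runs >= 2")
        if not 0 < self.sample_fraction <= 1:
            raise ParameterError("sample_fraction must lie in (0, 1]")
        if self.folds < 2:
            raise ParameterError("folds must be >= 2")


def cars_retention_schedule(p: int, n_runs: int) -> np.ndarray:
    """Wavelengths retained at each run under the exponential decay.

    The retention ratio is ``r_i = a * exp(-k * i)`` with the two
    constants fixed by the endpoint conditions: all ``p`` wavelengths
    survive run 1 and exactly 2 survive run ``n_runs``.
    """
    if p < 2:
        raise ParameterError("need at least 2 wavelengths")
    k = np.log(p / 2.0) / (n_runs - 1)
    a = np.exp(k)
    ratios = a * np.exp(-k * np.arange(1, n_runs + 1))
    return np.maximum(np.ceil(ratios * p - 1e-9).astype(int), 2)


def _rmsecv(X: np.ndarray, y: np.ndarray, cols: np.ndarray, folds: int,
            seed: int, n_components: int) -> float:
    """10-fold RMSECV of a PLS model restricted to the given wavelengths."""
    n = X.shape[0]
    kf = KFold(n_splits=min(folds, n), shuffle=True, random_state=seed)
    sse = 0.0
    for train, test in kf.split(X):
        a = min(n_components, len(train) - 1, len(cols))
        model = pls_fit(X[np.ix_(train, cols)], y[train], a)
        pred = pls_predict(model, X[np.ix_(test, cols)])
        sse += float(np.sum((y[test] - pred) ** 2))
    return float(np.sqrt(sse / n))


def cars_select(X: np.ndarray, y: np.ndarray,
                config: CARSConfig = CARSConfig()) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per Monte-Carlo run: (1) subsample calibration rows; (2) fit PLS on
    the surviving wavelengths and weight each by its absolute regression
    coefficient; (3) truncate to the exponentially decreasing retention
    count, keeping the largest weights; (4) resolve the run's subset by
    adaptive reweighted sampling — weighted draws with replacement,
    probability proportional to the coefficient weights; (5) record the
    subset's cross-validated RMSE on the full calibration data.  The
    subset with the minimum RMSECV over all runs is returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ParameterError("CARS needs at least 2 wavelengths")
    rng = np.random.default_rng(config.seed)
    schedule = cars_retention_schedule(p, config.n_runs)
    n_sub = max(2, int(np.ceil(config.sample_fraction * n)))

    survivors = np.arange(p)
    sizes: list[int] = []
    rmse_path: list[float] = []
    subsets: list[np.ndarray] = []
    for i in range(config.n_runs):
        rows = rng.choice(n, size=n_sub, replace=False)
        a = min(config.n_components, n_sub - 1, survivors.size)
        try:
            model = pls_fit(X[np.ix_(rows, survivors)], y[rows], a)
        except Exception as exc:  # degenerate subsample: truncate this run
            logger.warning("CARS run %d truncated: %s", i + 1, exc)
            continue
        weights = np.abs(model.B)

        m = min(schedule[i], survivors.size)
        keep = _top_k(weights, m)          # enforced exponential retention
        survivors = survivors[keep]
        weights = weights[keep]

        total = weights.sum()               # adaptive reweighted sampling
        prob = weights / total if total > 0 else np.full(m, 1.0 / m)
        drawn = np.unique(rng.choice(m, size=m, replace=True, p=prob))
        if drawn.size < 2:
            logger.warning("CARS run %d: subset collapsed below 2 wavelengths; "
                           "keeping the top 2 weights", i + 1)
            drawn = _top_k(weights, 2)
        survivors = survivors[drawn]

        sizes.append(int(survivors.size))
        subsets.append(survivors.copy())
        rmse_path.append(_rmsecv(X, y, survivors, config.folds, config.seed,
                                 config.n_components))
    if not subsets:
        raise SelectionError("all CARS runs failed")

    best_run = int(np.argmin(rmse_path))
    selected = np.sort(subsets[best_run])
    full_rmse = _rmsecv(X, y, np.arange(p), config.folds, config.seed,
                        config.n_components)
    if rmse_path[best_run] > full_rmse:
        warnings.warn(
            "CARS subset RMSECV exceeds the full-wavelength RMSECV "
            f"({rmse_path[best_run]:.4g} > {full_rmse:.4g})", stacklevel=2)
    return SelectionResult(
        algorithm="cars",
        selected=selected,
        diagnostics={"subset_sizes": sizes, "rmsecv_path": rmse_path,
                     "best_run": best_run, "full_rmsecv": full_rmse,
                     "retention_schedule": schedule},
        seed=config.seed,
        n_wavelengths=p,
    )


def overlap_counts(results: list[SelectionResult]) -> dict[tuple[str, ...], int]:
    """Venn-decomposition counts of the selectors' wavelength sets.

    Returns, for every non-empty combination of algorithms, the number
    of wavelengths selected by exactly that combination (the exclusive
    Venn region), keyed by the tuple of algorithm names.
    """
    if not results:
        raise ParameterError("need at least one selection result")
    grids = {r.n_wavelengths for r in results if r.n_wavelengths is not None}
    if len(grids) > 1:
        raise ParameterError(f"selections come from different grids: {grids}")
    names = [r.algorithm for r in results]
    if len(set(names)) != len(names):
        raise ParameterError("duplicate algorithm names in overlap input")
    sets = {r.algorithm: set(map(int, r.selected)) for r in results}
    counts: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in names if c not in combo)) \
                if len(combo) < len(names) else set()
            counts[tuple(sorted(combo))] = len(inside - outside)
    return counts
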
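"""NMF synergy extraction, cross-validated model-order selection, compactness.

Two factorizations of the same trials:

* temporal: ``M (101 x 30*tr) ~ C (101 x n) @ W (n x 30*tr)`` with
  trial-independent activation profiles C and trial-dependent muscle
  weightings W (per trial an n x 30 block);
* spatial: ``M (30 x 101*tr) ~ W (30 x n) @ C (n x 101*tr)`` with
  trial-independent weighting vectors and trial-dependent profiles.

NMF minimizes squared (Frobenius) reconstruction error with Lee-Seung
multiplicative updates, restarted from multiple seeded random initializations;
the best restart by final objective is kept. The model order is selected on
the across-fold mean of the cross-validated R² curve, either at the R²-knee
(smallest left endpoint whose linear fit to the remaining curve has mean
squared residual < 1e-4) or by the dual criterion N* (global R² >= 0.9 and
local increment < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .datatypes import N_TIME, ProcessedTrial

EPS = 1e-12


class DegenerateInputError(ValueError):
    pass


class UndefinedRSquaredError(ZeroDivisionError):
    pass


class FoldError(ValueError):
    pass


class SelectionError(RuntimeError):
    pass


@dataclass
class StrategyDataset:
    """All processed trials of one movement x floor x strategy."""

    label: str
    trials: list[ProcessedTrial]

    def __post_init__(self):
        for tr in self.trials:
            if tr.envelope.shape != (N_TIME, 30):
                raise ValueError("all trials must be 101 x 30")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def temporal_matrix(self) -> np.ndarray:
        """101 x (30*tr): trials concatenated along columns, muscle-major."""
        return np.hstack([tr.envelope for tr in self.trials])

    @property
    def spatial_matrix(self) -> np.ndarray:
        """30 x (101*tr): trials concatenated along columns, time-major."""
        return np.hstack([tr.envelope.T for tr in self.trials])

    def matrix(self, kind: str) -> np.ndarray:
        if kind == "temporal":
            return self.temporal_matrix
        if kind == "spatial":
            return self.spatial_matrix
        raise ValueError(f"kind must be 'temporal' or 'spatial', got {kind!r}")

    def split_columns(self, H: np.ndarray, kind: str) -> list[np.ndarray]:
        """Cut a trial-dependent factor back into per-trial blocks."""
        block = 30 if kind == "temporal" else N_TIME
        return [H[:, i * block : (i + 1) * block] for i in range(self.n_trials)]


def build_strategy_dataset(trials: list[ProcessedTrial], label: str | None = None) -> StrategyDataset:
    if not trials:
        raise ValueError("empty trial list")
    labels = {tr.meta.dataset_label for tr in trials}
    if label is None:
        if len(labels) != 1:
            raise ValueError(f"trials span multiple dataset labels: {sorted(labels)}")
        label = labels.pop()
    return StrategyDataset(label=label, trials=list(trials))


@dataclass
class SynergyModel:
    kind: str
    n: int
    trial_independent: np.ndarray          # temporal: (101, n); spatial: (30, n)
    trial_dependent: list[np.ndarray]      # per trial: (n, 30) or (n, 101)
    r2_train: float
    objective: float
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def trial_dependent_concat(self) -> np.ndarray:
        return np.hstack(self.trial_dependent)


def compute_r_squared(
    data: np.ndarray, reconstruction: np.ndarray, *, sst_mode: str = "row_mean"
) -> float:
    """Multivariate R² = 1 - SSE/SST with SST about the mean vector.

    ``sst_mode='row_mean'`` (default) takes the mean across columns per row;
    ``'grand_mean'`` uses the scalar grand mean.
    """
    data = np.asarray(data, dtype=float)
    reconstruction = np.asarray(reconstruction, dtype=float)
    if data.shape != reconstruction.shape:
        raise ValueError("data and reconstruction must share a shape")
    sse = float(np.sum((data - reconstruction) ** 2))
    if sst_mode == "row_mean":
        ref = data.mean(axis=1, keepdims=True)
    elif sst_mode == "grand_mean":
        ref = data.mean()
    else:
        raise ValueError(f"unknown sst_mode {sst_mode!r}")
    sst = float(np.sum((data - ref) ** 2))
    if sst == 0.0:
        raise UndefinedRSquaredError("SST is zero; R² undefined for constant data")
    return 1.0 - sse / sst


def _mu_nmf(
    V: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float = 1e-6,
    tol_window: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One multiplicative-update run; returns (A, B, objective trace)."""
    m, k = V.shape
    scale = np.sqrt(V.mean() / n)
    A = rng.uniform(1e-3, 1.0, size=(m, n)) * scale
    B = rng.uniform(1e-3, 1.0, size=(n, k)) * scale
    trace = []
    obj = float(np.sum((V - A @ B) ** 2))
    trace.append(obj)
    for it in range(max_iter):
        B *= (A.T @ V) / (A.T @ A @ B + EPS)
        A *= (V @ B.T) / (A @ (B @ B.T) + EPS)
        obj = float(np.sum((V - A @ B) ** 2))
        trace.append(obj)
        if it >= tol_window:
            past = trace[-1 - tol_window]
            if past - obj < tol * max(past, EPS):
                break
    return A, B, np.asarray(trace)


def _unit_max_normalize(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale trial-independent columns to unit maximum; fold scale into B."""
    scales = A.max(axis=0)
    scales = np.where(scales > 0, scales, 1.0)
    return A / scales, B * scales[:, None]


def nmf_extract(
    matrix: np.ndarray,
    n: int,
    *,
    restarts: int = 50,
    max_iter: int = 3000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Best-of-restarts NMF of a nonnegative matrix.

    Returns ``(A, B, objective, objective_trace)`` with A column-normalized to
    unit maximum. The objective is the final squared reconstruction error of
    the best restart.
    """
    V = np.asarray(matrix, dtype=float)
    if np.any(V < 0):
        raise ValueError("matrix must be nonnegative")
    if not np.any(V > 0):
        raise DegenerateInputError("all-zero matrix cannot be factorized")
    if not (1 <= n <= min(V.shape)):
        raise ValueError(f"n must be in [1, {min(V.shape)}], got {n}")
    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    for ss in seeds:
        A, B, trace = _mu_nmf(V, n, np.random.default_rng(ss), max_iter)
        if best is None or trace[-1] < best[2][-1]:
            best = (A, B, trace)
    A, B, trace = best
    A, B = _unit_max_normalize(A, B)
    return A, B, float(trace[-1]), trace


def extract_synergies(
    dataset: StrategyDataset,
    kind: str,
    n: int,
    *,
    restarts: int = 50,
    max_iter: int = 3000,
    seed: int = 0,
) -> SynergyModel:
    """NMF of a strategy dataset in the requested arrangement."""
    V = dataset.matrix(kind)
    A, B, obj, trace = nmf_extract(
        V, n, restarts=restarts, max_iter=max_iter, seed=seed
    )
    r2 = compute_r_squared(V, A @ B)
    return SynergyModel(
        kind=kind,
        n=n,
        trial_independent=A,
        trial_dependent=dataset.split_columns(B, kind),
        r2_train=r2,
        objective=obj,
        objective_trace=trace,
    )


def fit_fixed_factors(
    fixed: np.ndarray, matrix: np.ndarray
) -> tuple[np.ndarray, float]:
    """Fit trial-dependent factors to new data with the trial-independent
    factors held fixed (nonnegative least squares per column).

    Returns ``(H, r2)`` where ``fixed @ H`` approximates ``matrix``.
    """
    fixed = np.asarray(fixed, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if fixed.ndim != 2 or matrix.ndim != 2 or fixed.shape[0] != matrix.shape[0]:
        raise ValueError(
            f"dimension mismatch: fixed {fixed.shape} vs data {matrix.shape}"
        )
    H = np.empty((fixed.shape[1], matrix.shape[1]))
    for j in range(matrix.shape[1]):
        H[:, j], _ = nnls(fixed, matrix[:, j])
    try:
        r2 = compute_r_squared(matrix, fixed @ H)
    except UndefinedRSquaredError:
        r2 = float("nan")  # e.g. a single column, where SST about row means is 0
    return H, r2


@dataclass
class CrossValidationCurve:
    kind: str
    n_values: np.ndarray
    r2_cv: np.ndarray  # (folds, len(n_values))

    @property
    def r2_mean(self) -> np.ndarray:
        return self.r2_cv.mean(axis=0)

    @property
    def r2_sd(self) -> np.ndarray:
        return self.r2_cv.std(axis=0, ddof=1)


def make_folds(
    dataset: StrategyDataset, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Whole-trial folds, stratified by support condition where possible."""
    tr = dataset.n_trials
    if tr < n_folds:
        raise FoldError(
            f"dataset {dataset.label!r} has {tr} trials; need >= {n_folds} for "
            f"{n_folds}-fold cross-validation"
        )
    rng = np.random.default_rng(seed)
    by_support: dict[str, list[int]] = {}
    for i, t in enumerate(dataset.trials):
        by_support.setdefault(t.meta.support, []).append(i)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    cursor = 0
    for sup in sorted(by_support):
        idx = np.array(by_support[sup])
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % n_folds].append(int(i))
            cursor += 1
    return [np.array(sorted(f)) for f in folds]


def cross_validated_curve(
    dataset: StrategyDataset,
    kind: str,
    *,
    n_values=None,
    n_folds: int = 5,
    restarts: int = 50,
    max_iter: int = 3000,
    seed: int = 0,
) -> CrossValidationCurve:
    """R²_CV per fold and model order: extract on ~80 % of trials, fix the
    trial-independent factors, fit them to the held-out ~20 %."""
    if n_values is None:
        n_values = np.arange(1, 31)
    n_values = np.asarray(n_values, dtype=int)
    folds = make_folds(dataset, n_folds, seed)
    all_idx = set(range(dataset.n_trials))
    r2 = np.empty((n_folds, len(n_values)))
    for fi, test_idx in enumerate(folds):
        train_idx = sorted(all_idx - set(test_idx.tolist()))
        train = StrategyDataset(dataset.label, [dataset.trials[i] for i in train_idx])
        test = StrategyDataset(dataset.label, [dataset.trials[i] for i in test_idx])
        V_test = test.matrix(kind)
        for ni, n in enumerate(n_values):
            model = extract_synergies(
                train, kind, int(n),
                restarts=restarts, max_iter=max_iter,
                seed=seed + 1000 * fi + int(n),
            )
            _, r2[fi, ni] = fit_fixed_factors(model.trial_independent, V_test)
    return CrossValidationCurve(kind=kind, n_values=n_values, r2_cv=r2)


@dataclass
class ModelSelection:
    n_knee: int | None = None
    n_star: int | None = None
    knee_mse_trace: dict[int, float] = field(default_factory=dict)
    criteria_trace: dict[int, dict] = field(default_factory=dict)


def select_n_knee(
    n_values: np.ndarray, r2_mean: np.ndarray, *, mse_threshold: float = 1e-4
) -> ModelSelection:
    """R²-knee: iteratively drop the smallest order from the regression
    interval; pick the first left endpoint whose linear fit to the remaining
    curve has mean squared residual below the threshold."""
    n_values = np.asarray(n_values, dtype=float)
    r2_mean = np.asarray(r2_mean, dtype=float)
    if len(n_values) < 2:
        raise SelectionError("need at least 2 curve points")
    trace: dict[int, float] = {}
    for i in range(len(n_values) - 1):
        x = n_values[i:]
        y = r2_mean[i:]
        coeffs = np.polyfit(x, y, 1)
        mse = float(np.mean((y - np.polyval(coeffs, x)) ** 2))
        trace[int(n_values[i])] = mse
        if mse < mse_threshold:
            return ModelSelection(n_knee=int(n_values[i]), knee_mse_trace=trace)
    raise SelectionError(
        f"no left endpoint reaches MSE < {mse_threshold}; min MSE = {min(trace.values()):.3g}"
    )


def select_n_star(
    n_values: np.ndarray,
    r2_mean: np.ndarray,
    *,
    global_threshold: float = 0.9,
    local_threshold: float = 0.05,
) -> ModelSelection:
    """Dual criterion: smallest n with R² >= 0.9 and increment over n-1 below
    0.05 (R² at order 0 taken as 0)."""
    n_values = np.asarray(n_values, dtype=int)
    r2_mean = np.asarray(r2_mean, dtype=float)
    trace: dict[int, dict] = {}
    prev = 0.0
    for n, r2 in zip(n_values, r2_mean):
        ok_global = r2 >= global_threshold
        ok_local = (r2 - prev) < local_threshold
        trace[int(n)] = {"r2": float(r2), "global": bool(ok_global), "local": bool(ok_local)}
        if ok_global and ok_local:
            return ModelSelection(n_star=int(n), criteria_trace=trace)
        prev = r2
    raise SelectionError(
        "no order satisfies both the global (R² >= "
        f"{global_threshold}) and local (increment < {local_threshold}) criteria"
    )


@dataclass
class CompactnessSummary:
    n_temporal: int
    n_spatial: int
    trial_independent_temporal: int
    trial_dependent_temporal: int
    trial_independent_spatial: int
    trial_dependent_spatial: int
    sum_temporal: int
    sum_spatial: int


def compactness_summary(
    n_temporal: int, n_spatial: int, T: int = N_TIME, M: int = 30
) -> CompactnessSummary:
    """Parameter-count arithmetic of the two representations.

    Temporal: T*n trial-independent + n*M trial-dependent per trial;
    spatial: n*M trial-independent + T*n trial-dependent per trial.
    """
    if n_temporal < 1 or n_spatial < 1:
        raise ValueError("synergy counts must be >= 1")
    return CompactnessSummary(
        n_temporal=n_temporal,
        n_spatial=n_spatial,
        trial_independent_temporal=T * n_temporal,
        trial_dependent_temporal=n_temporal * M,
        trial_independent_spatial=n_spatial * M,
        trial_dependent_spatial=T * n_spatial,
        sum_temporal=T * n_temporal + n_temporal * M,
        sum_spatial=n_spatial * M + T * n_spatial,
    )


def compare_model_counts(pairs: list[tuple[int, int]]) -> tuple[float, float]:
    """Mean and sample SD of (n_spatial - n_temporal) across datasets."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 datasets")
    diffs = np.array([s - t for t, s in pairs], dtype=float)
    return float(diffs.mean()), float(diffs.std(ddof=1))


def best_pairing_cosine(true_factors: np.ndarray, est_factors: np.ndarray) -> np.ndarray:
    """Hungarian-matched cosine similarities between factor columns."""
    A = np.asarray(true_factors, dtype=float)
    B = np.asarray(est_factors, dtype=float)
    An = A / (np.linalg.norm(A, axis=0, keepdims=True) + EPS)
    Bn = B / (np.linalg.norm(B, axis=0, keepdims=True) + EPS)
    sim = An.T @ Bn
    r, c = linear_sum_assignment(-sim)
    return sim[r, c]
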
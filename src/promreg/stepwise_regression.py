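"""OLS engine and greedy forward feature selection.

The selection criterion at every step is the Pearson correlation between the
model's fitted and observed activities (r_op); with an intercept this equals
sqrt(R^2), so the greedy step is computed cheaply by orthogonalizing the
remaining candidates against the already selected columns.  The final
coefficients and p-values always come from a single OLS refit on the selected
columns.

Determinism: candidate ties in r_op (within 1e-12) are broken toward the
lowest column index; all randomness (cross-validation splits) is seeded.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .feature_builder import FeatureMatrix

__all__ = [
    "RegressionModel",
    "StepTrace",
    "SelectionConfig",
    "CrossValidationResult",
    "ols_fit",
    "forward_select",
    "cross_validate_model",
    "build_predicted_mean_profile",
    "select_attendant_features",
]

logger = logging.getLogger(__name__)

P_VALUE_FLOOR = 1e-300
TIE_TOL = 1e-12


@dataclasses.dataclass
class StepTrace:
    """Selected feature per step with the r_op attained after inclusion."""

    features: list[str]
    r_op: list[float]

    @property
    def increments(self) -> list[float]:
        prev = [0.0] + self.r_op[:-1]
        return [r - p for r, p in zip(self.r_op, prev)]


@dataclasses.dataclass
class RegressionModel:
    intercept: float
    feature_names: list[str]
    coefficients: np.ndarray
    p_values: np.ndarray
    p_floored: list[bool]
    r_op: float
    n_obs: int
    feature_indices: list[int] | None = None  # into the candidate matrix
    trace: StepTrace | None = None
    fitted: bool = True

    def predict(self, X: np.ndarray | FeatureMatrix) -> np.ndarray:
        """Predict from the full candidate matrix the model was selected from."""
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
        if self.feature_indices is not None:
            values = values[:, self.feature_indices]
        if values.shape[1] != len(self.coefficients):
            raise ValueError(
                f"expected {len(self.coefficients)} columns, got {values.shape[1]}"
            )
        return self.intercept + values @ self.coefficients


@dataclasses.dataclass
class SelectionConfig:
    max_steps: int = 20
    p_stop: float = 1e-20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


def _as_values_names(
    features: np.ndarray | FeatureMatrix, names: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, FeatureMatrix):
        return features.values, features.column_names
    values = np.asarray(features, dtype=float)
    if values.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if names is None:
        names = [f"x{i}" for i in range(values.shape[1])]
    return values, list(names)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def ols_fit(
    X: np.ndarray | FeatureMatrix,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    feature_indices: Sequence[int] | None = None,
) -> RegressionModel:
    """Ordinary least squares with intercept, t-test p-values, and r_op.

    Raises on singular designs, naming the columns that are linearly
    dependent on the ones preceding them.  p-values below 1e-300 are floored
    and flagged.
    """
    values, names = _as_values_names(X, feature_names)
    y = np.asarray(y, dtype=float)
    n, p = values.shape
    if len(y) != n:
        raise ValueError(f"y has length {len(y)}, expected {n}")
    if n <= p + 1:
        raise ValueError(f"need more than p + 1 = {p + 1} observations, got {n}")

    design = np.hstack([np.ones((n, 1)), values])
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = max(n, p + 1) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.flatnonzero(diag < tol)
    if bad.size:
        offenders = [names[i - 1] if i > 0 else "<intercept>" for i in bad]
        raise np.linalg.LinAlgError(
            f"singular design: columns {offenders} are collinear with the others"
        )

    beta = np.linalg.solve(r, q.T @ y)
    fitted = design @ beta
    resid = y - fitted
    df = n - p - 1
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    cov = rinv @ rinv.T * sigma2
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    coef_p = pvals[1:]
    floored = coef_p < P_VALUE_FLOOR
    coef_p = np.maximum(coef_p, P_VALUE_FLOOR)

    return RegressionModel(
        intercept=float(beta[0]),
        feature_names=names,
        coefficients=beta[1:].copy(),
        p_values=coef_p,
        p_floored=list(floored),
        r_op=_pearson(fitted, y),
        n_obs=n,
        feature_indices=list(feature_indices) if feature_indices is not None else None,
    )


class _GreedyState:
    """Orthogonalized state for fast forward selection.

    Columns and the response are centered once (the intercept); selected
    columns are kept as an orthonormal basis and every remaining candidate is
    maintained as its residual against that basis.
    """

    def __init__(self, values: np.ndarray, y: np.ndarray) -> None:
        self.n = values.shape[0]
        self.Z = values - values.mean(axis=0)
        self.orig_norm2 = np.einsum("ij,ij->j", self.Z, self.Z)
        cy = y - y.mean()
        self.tss = float(cy @ cy)
        self.r = cy
        self.rss = self.tss
        self.usable = self.orig_norm2 > 0
        self.Q: list[np.ndarray] = []

    def candidate_r_op(self) -> np.ndarray:
        """r_op each remaining candidate would attain if added now."""
        zz = np.einsum("ij,ij->j", self.Z, self.Z)
        zr = self.Z.T @ self.r
        valid = self.usable & (zz > 1e-12 * np.maximum(self.orig_norm2, 1e-30))
        out = np.full(self.Z.shape[1], -np.inf)
        if self.tss == 0:
            return out
        with np.errstate(divide="ignore", invalid="ignore"):
            rss_new = self.rss - np.where(valid, zr**2 / np.where(zz > 0, zz, 1.0), 0.0)
        ratio = np.clip(1.0 - rss_new / self.tss, 0.0, 1.0)
        out[valid] = np.sqrt(ratio[valid])
        return out

    def add(self, j: int) -> float:
        """Add candidate j to the basis; returns the r_op after inclusion."""
        q = self.Z[:, j].copy()
        # re-orthogonalize once for numerical stability
        for qk in self.Q:
            q -= (qk @ q) * qk
        norm = np.linalg.norm(q)
        q /= norm
        self.Q.append(q)
        proj = q @ self.r
        self.r = self.r - proj * q
        self.rss = float(self.r @ self.r)
        self.Z -= np.outer(q, q @ self.Z)
        self.usable[j] = False
        if self.tss == 0:
            return 0.0
        return float(np.sqrt(np.clip(1.0 - self.rss / self.tss, 0.0, 1.0)))


def forward_select(
    features: np.ndarray | FeatureMatrix,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> tuple[RegressionModel, StepTrace]:
    """Greedy forward selection maximizing r_op at every step.

    Stops after ``config.max_steps`` steps, when no usable candidate remains,
    or when the fit is numerically perfect.  The returned model is a single
    OLS refit on the selected columns; the trace holds the per-step r_op.
    """
    config = config or SelectionConfig()
    values, names = _as_values_names(features, feature_names)
    y = np.asarray(y, dtype=float)
    n = values.shape[0]
    if len(y) != n:
        raise ValueError(f"y has length {len(y)}, expected {n}")

    state = _GreedyState(values, y)
    n_const = int(np.sum(state.orig_norm2 == 0))
    if n_const:
        logger.warning("skipping %d constant candidate column(s)", n_const)
    if not state.usable.any():
        raise ValueError("all candidate columns are constant")

    selected: list[int] = []
    trace_r: list[float] = []
    for _ in range(config.max_steps):
        if len(selected) + 2 >= n:
            break
        scores = state.candidate_r_op()
        best = scores.max()
        if not np.isfinite(best):
            break
        j = int(np.flatnonzero(scores >= best - TIE_TOL)[0])
        r_op = state.add(j)
        selected.append(j)
        trace_r.append(r_op)
        if state.rss <= 1e-14 * max(state.tss, 1.0):
            break

    model = ols_fit(
        values[:, selected],
        y,
        feature_names=[names[j] for j in selected],
        feature_indices=selected,
    )
    trace = StepTrace(features=[names[j] for j in selected], r_op=trace_r)
    model.trace = trace
    return model, trace


@dataclasses.dataclass
class CrossValidationResult:
    r_op_full: float
    r_op_train: float
    r_op_test: float


def cross_validate_model(
    features: np.ndarray | FeatureMatrix,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    seed: int | None = None,
) -> CrossValidationResult:
    """50/50 split reliability check.

    Observations (TSS rows) are split at random into equal halves; selection
    and fitting are re-run on the training half only, and r_op is evaluated on
    both halves with that training model.  r_op_full comes from selection on
    all rows.
    """
    config = config or SelectionConfig()
    values, names = _as_values_names(features, None)
    y = np.asarray(y, dtype=float)
    n = values.shape[0]
    if n < 200:
        raise ValueError("cross-validation requires n >= 200 observations")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train, test = perm[: n // 2], perm[n // 2 :]

    full_model, _ = forward_select(values, y, config, feature_names=names)
    train_model, _ = forward_select(values[train], y[train], config, feature_names=names)
    pred_train = train_model.predict(values[train])
    pred_test = train_model.predict(values[test])
    return CrossValidationResult(
        r_op_full=full_model.r_op,
        r_op_train=_pearson(pred_train, y[train]),
        r_op_test=_pearson(pred_test, y[test]),
    )


def build_predicted_mean_profile(
    per_cell_line: Sequence[tuple[FeatureMatrix, np.ndarray]],
    config: SelectionConfig | None = None,
) -> np.ndarray:
    """Average of independently fitted activity profiles across cell lines.

    Each cell line's features and activities are fed through forward
    selection; the fitted profiles (on the shared TSS universe) are averaged
    per TSS.
    """
    if not per_cell_line:
        raise ValueError("at least one (features, y) pair is required")
    tss_ids = per_cell_line[0][0].tss_ids
    fitted_profiles = []
    for fm, y in per_cell_line:
        if fm.tss_ids != tss_ids:
            raise ValueError("feature matrices do not share the TSS universe")
        model, _ = forward_select(fm, np.asarray(y, float), config)
        fitted_profiles.append(model.predict(fm))
    return np.mean(fitted_profiles, axis=0)


def select_attendant_features(
    features: np.ndarray | FeatureMatrix,
    y: np.ndarray,
    already_selected: RegressionModel,
    config: SelectionConfig | None = None,
) -> list[tuple[str, float, float]]:
    """Extend a fitted model greedily until significance runs out.

    Selection continues past ``already_selected``; after each inclusion the
    extended model is refitted and, if the least significant coefficient's
    p-value exceeds ``config.p_stop``, the last feature is rejected and
    selection stops.  At most ``config.max_steps`` features are appended.
    Returns (feature name, coefficient, p-value) for the accepted extension,
    taken from the final accepted refit.
    """
    config = config or SelectionConfig()
    values, names = _as_values_names(
        features, features.column_names if isinstance(features, FeatureMatrix) else None
    )
    y = np.asarray(y, dtype=float)
    if already_selected.feature_indices is None:
        raise ValueError("already_selected must carry feature_indices")
    base = list(already_selected.feature_indices)

    state = _GreedyState(values, y)
    for j in base:
        state.add(j)

    accepted: list[int] = []
    final_model = already_selected
    while len(accepted) < config.max_steps:
        if len(base) + len(accepted) + 2 >= values.shape[0]:
            break
        scores = state.candidate_r_op()
        best = scores.max()
        if not np.isfinite(best):
            break
        j = int(np.flatnonzero(scores >= best - TIE_TOL)[0])
        trial = base + accepted + [j]
        model = ols_fit(
            values[:, trial],
            y,
            feature_names=[names[i] for i in trial],
            feature_indices=trial,
        )
        if model.p_values.max() > config.p_stop:
            break
        state.add(j)
        accepted.append(j)
        final_model = model

    if not accepted:
        return []
    k = len(base)
    return [
        (
            final_model.feature_names[k + i],
            float(final_model.coefficients[k + i]),
            float(final_model.p_values[k + i]),
        )
        for i in range(len(accepted))
    ]
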
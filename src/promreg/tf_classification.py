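"""Location-dependent activator/repressor calls and co-binding statistics."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .feature_builder import FeatureDescriptor, FeatureMatrix, PromoterWindow
from .stepwise_regression import RegressionModel, ols_fit

__all__ = [
    "TFWindowCall",
    "classify_model_features",
    "classify_tf_by_windows",
    "cobinding_ratio",
    "top_correlated_features",
]

ACTIVATOR = "activator"
REPRESSOR = "repressor"
INSIGNIFICANT = "insignificant"


@dataclasses.dataclass
class TFWindowCall:
    tf: str
    window: PromoterWindow
    category: str
    coefficient: float
    p_value: float
    r_op_of_model: float
    coefficient_defined: bool = True


def classify_model_features(
    model: RegressionModel, columns: Sequence[FeatureDescriptor]
) -> list[TFWindowCall]:
    """Call every binary feature in a fitted model by its coefficient sign.

    ``columns`` are the candidate-matrix descriptors the model was selected
    from.  Abundance and extra columns pass through unclassified; no p-value
    filter is applied because selected features are significant by
    construction.
    """
    if model.feature_indices is None:
        raise ValueError("model must carry feature_indices into the candidate matrix")
    calls: list[TFWindowCall] = []
    for k, idx in enumerate(model.feature_indices):
        desc = columns[idx]
        if desc.kind != "binary":
            continue
        coef = float(model.coefficients[k])
        calls.append(
            TFWindowCall(
                tf=desc.tf,
                window=desc.window,
                category=ACTIVATOR if coef > 0 else REPRESSOR,
                coefficient=coef,
                p_value=float(model.p_values[k]),
                r_op_of_model=model.r_op,
            )
        )
    return calls


def classify_tf_by_windows(
    tf: str,
    windows: Sequence[PromoterWindow],
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 1e-5,
) -> list[TFWindowCall]:
    """Classify one TF's eight windows from a dedicated 8-column OLS.

    A window is called repressor (activator) when its coefficient is negative
    (positive) with p-value below ``alpha``; otherwise insignificant.
    All-zero or constant columns are reported insignificant with an undefined
    coefficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != len(windows):
        raise ValueError(
            f"expected {len(windows)} columns for the TF's windows, got {X.shape[1]}"
        )
    variable = np.flatnonzero(X.std(axis=0) > 0)
    if variable.size == 0:
        return [
            TFWindowCall(tf, w, INSIGNIFICANT, float("nan"), float("nan"), 0.0,
                         coefficient_defined=False)
            for w in windows
        ]
    model = ols_fit(
        X[:, variable],
        y,
        feature_names=[f"{tf}{windows[j].label}" for j in variable],
    )
    calls: list[TFWindowCall] = []
    pos = {int(j): k for k, j in enumerate(variable)}
    for j, w in enumerate(windows):
        if j not in pos:
            calls.append(
                TFWindowCall(tf, w, INSIGNIFICANT, float("nan"), float("nan"),
                             model.r_op, coefficient_defined=False)
            )
            continue
        k = pos[j]
        coef = float(model.coefficients[k])
        p = float(model.p_values[k])
        if p < alpha and coef < 0:
            cat = REPRESSOR
        elif p < alpha and coef > 0:
            cat = ACTIVATOR
        else:
            cat = INSIGNIFICANT
        calls.append(TFWindowCall(tf, w, cat, coef, p, model.r_op))
    return calls


def cobinding_ratio(feature_a: np.ndarray, feature_b: np.ndarray) -> float:
    """Observed over independence-expected probability of simultaneous binding.

    Values below 1 indicate avoidance, above 1 co-occurrence.  The expected
    probability is the product of the two marginal binding frequencies.
    """
    a = np.asarray(feature_a, dtype=float)
    b = np.asarray(feature_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("feature columns must have equal length")
    pa, pb = a.mean(), b.mean()
    if pa == 0 or pb == 0:
        raise ValueError("co-binding ratio undefined for a zero marginal frequency")
    return float((a * b).mean() / (pa * pb))


def top_correlated_features(
    target_index: int,
    matrix: FeatureMatrix,
    k: int = 5,
    by_abs: bool = False,
) -> list[tuple[FeatureDescriptor, float]]:
    """The k features most correlated with a target column.

    Ranks by signed Pearson r (or by absolute value with ``by_abs``);
    constant columns and the target itself are excluded; ties break toward the
    lower column index.
    """
    target = matrix.values[:, target_index]
    if np.std(target) == 0:
        raise ValueError("target column has zero variance")
    rs: list[tuple[int, float]] = []
    for j in range(matrix.n_cols):
        if j == target_index:
            continue
        col = matrix.values[:, j]
        if np.std(col) == 0:
            continue
        rs.append((j, float(np.corrcoef(target, col)[0, 1])))
    key = (lambda t: (-abs(t[1]), t[0])) if by_abs else (lambda t: (-t[1], t[0]))
    rs.sort(key=key)
    return [(matrix.columns[j], r) for j, r in rs[:k]]
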
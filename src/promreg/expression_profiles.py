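"""Expression transforms and profile-level analyses.

The activity scale used throughout is the log-transformed expression level:
0 when the raw level EL is below 2, log10(EL) otherwise.  Profiles are
vectors of such values aligned to a shared TSS ordering.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import TSSRecord

__all__ = [
    "ActivityProfile",
    "SumTransformConfig",
    "GroupCorrelation",
    "lte_transform",
    "mean_profile",
    "sum_transform",
    "sum_transform_components",
    "profile_correlation_summary",
    "cross_profile_regression",
]

OBJECT_TYPES = ("cell_line", "primary_cell", "tissue")


@dataclasses.dataclass
class ActivityProfile:
    """A named activity profile over the shared TSS universe."""

    label: str
    object_type: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be a 1-D vector")
        if np.any(self.values < 0):
            raise ValueError("activity values must be >= 0")


@dataclasses.dataclass
class SumTransformConfig:
    max_gap: int = 100

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


def lte_transform(el: float | np.ndarray) -> float | np.ndarray:
    """Log-transformed expression: 0 if EL < 2 else log10(EL)."""
    arr = np.asarray(el, dtype=float)
    if np.any(arr < 0):
        raise ValueError("EL must be >= 0")
    out = np.where(arr < 2, 0.0, np.log10(np.maximum(arr, 1.0)))
    if np.isscalar(el) or arr.ndim == 0:
        return float(out)
    return out


def mean_profile(profiles: Sequence[ActivityProfile]) -> np.ndarray:
    """Per-TSS arithmetic mean over aligned profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile is required")
    n = len(profiles[0].values)
    for p in profiles:
        if len(p.values) != n:
            raise ValueError(
                f"profile {p.label!r} has length {len(p.values)}, expected {n}"
            )
    return np.mean([p.values for p in profiles], axis=0)


def sum_transform_components(
    tss_list: Sequence[TSSRecord], config: SumTransformConfig | None = None
) -> list[list[int]]:
    """Single-linkage components of TSSs closer than ``max_gap`` bp.

    Grouping is strand-agnostic and restricted to a chromosome; distance is
    the absolute difference of TSS positions.  In 1-D single linkage reduces
    to chaining consecutive sorted positions.
    """
    config = config or SumTransformConfig()
    by_chrom: dict[str, list[int]] = {}
    for i, t in enumerate(tss_list):
        by_chrom.setdefault(t.chrom, []).append(i)
    components: list[list[int]] = []
    for chrom in sorted(by_chrom):
        idx = sorted(by_chrom[chrom], key=lambda i: tss_list[i].position)
        comp = [idx[0]]
        for prev, cur in zip(idx, idx[1:]):
            if tss_list[cur].position - tss_list[prev].position < config.max_gap:
                comp.append(cur)
            else:
                components.append(comp)
                comp = [cur]
        components.append(comp)
    return components


def sum_transform(
    tss_list: Sequence[TSSRecord],
    cell_line: str,
    config: SumTransformConfig | None = None,
) -> np.ndarray:
    """LTE values after summing raw EL within closely spaced TSS components.

    Every member of a component receives the LTE of the component's raw EL
    sum; isolated TSSs keep the LTE of their own EL.
    """
    out = np.zeros(len(tss_list))
    for comp in sum_transform_components(tss_list, config):
        total = sum(tss_list[i].el[cell_line] for i in comp)
        val = lte_transform(total)
        for i in comp:
            out[i] = val
    return out


@dataclasses.dataclass
class GroupCorrelation:
    group: str
    size: int  # number of profiles in the group
    n_pairs: int
    mean: float
    min: float
    max: float
    n_undefined: int  # pairs excluded for zero variance


def _pairwise_summary(group: str, profiles: Sequence[ActivityProfile]) -> GroupCorrelation:
    mat = np.array([p.values for p in profiles])
    sd = mat.std(axis=1)
    rs: list[float] = []
    undefined = 0
    k = len(profiles)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    for i in range(k):
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                undefined += 1
                continue
            rs.append(corr[i, j])
    if not rs:
        return GroupCorrelation(group, k, 0, float("nan"), float("nan"),
                                float("nan"), undefined)
    arr = np.array(rs)
    return GroupCorrelation(
        group, k, len(rs), float(arr.mean()), float(arr.min()), float(arr.max()),
        undefined,
    )


def profile_correlation_summary(
    profiles: Sequence[ActivityProfile],
    random_sample_size: int,
    seed: int | None = None,
) -> list[GroupCorrelation]:
    """Pairwise Pearson-r summaries per object type plus a random mixed sample.

    The mixed sample is drawn uniformly without replacement across all
    profiles regardless of type, using ``seed``.  Zero-variance pairs are
    excluded and counted in ``n_undefined``.
    """
    profiles = list(profiles)
    by_type: dict[str, list[ActivityProfile]] = {}
    for p in profiles:
        by_type.setdefault(p.object_type, []).append(p)
    out: list[GroupCorrelation] = []
    for typ in sorted(by_type):
        group = by_type[typ]
        if len(group) < 2:
            raise ValueError(f"object type {typ!r} needs >= 2 profiles")
        out.append(_pairwise_summary(typ, group))
    if random_sample_size > len(profiles):
        raise ValueError("random sample larger than the number of profiles")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(profiles), size=random_sample_size, replace=False)
    out.append(
        _pairwise_summary("random_sample", [profiles[i] for i in sorted(pick)])
    )
    return out


def cross_profile_regression(
    y: ActivityProfile, x: ActivityProfile
) -> tuple[float, float, float]:
    """OLS of one profile on another: (intercept, slope, r between fit and y)."""
    yv, xv = y.values, x.values
    if len(yv) != len(xv):
        raise ValueError("profiles are not aligned")
    if np.std(xv) == 0:
        raise ValueError(f"predictor profile {x.label!r} has zero variance")
    res = stats.linregress(xv, yv)
    fitted = res.intercept + res.slope * xv
    if np.std(yv) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(fitted, yv)[0, 1])
    return float(res.intercept), float(res.slope), r
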
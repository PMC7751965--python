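"""Ground-truth synthetic data for every pipeline stage.

Generates TSS landscapes with a controlled fraction of closely spaced sites,
per-TF binding-region sets with window-specific propensities, activities from
a sparse linear model on the realized features (built on the log scale and
back-transformed through the expression-level definition), and caller
replicates with injected orphans for the meta-processing stage.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .feature_builder import (
    FeatureMatrix,
    PromoterWindow,
    build_primary_features,
    default_windows,
    window_to_genomic,
)
from .io_formats import GenomicInterval, TFBRSet, TSSRecord
from .meta_processing import merge_intervals

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "generate_tss_landscape",
    "generate_tfbr_sets",
    "generate_activities",
    "generate_caller_replicates",
    "simulate_dataset",
    "theoretical_r_op",
]

_EDGE_MARGIN = 6000  # keeps all default windows on-chromosome


@dataclasses.dataclass
class SimConfig:
    """Knobs for the synthetic generator.

    ``true_effects`` maps feature-column names (as produced by the feature
    builder, e.g. ``"TF003[1, 100]"``) to coefficients on the log-activity
    scale.  ``propensities`` overrides the default per-(TF, window index)
    binding probability.
    """

    seed: int = 0
    n_tss: int = 1000
    chrom_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chrSim1": 250_000_000}
    )
    close_pair_fraction: float = 0.556
    max_gap: int = 100
    # groups further apart than the +-5 kb window reach cannot share TFBRs,
    # so binary features stay Bernoulli(propensity) across groups
    isolated_gap_range: tuple[int, int] = (11_000, 15_000)
    m_tfs: int = 10
    binding_propensity: float = 0.2
    propensities: dict[tuple[str, int], float] | None = None
    true_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    noise_sd: float = 0.3
    intercept: float = 1.5
    background_rate: float = 0.0
    cell_line: str = "SIM"
    # caller-replicate knobs
    caller_jitter: int = 10
    caller_dropout: float = 0.0
    orphan_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_tss < 1:
            raise ValueError("n_tss must be >= 1")
        if not 0 <= self.close_pair_fraction <= 1:
            raise ValueError("close_pair_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.isolated_gap_range[0] < self.max_gap:
            raise ValueError("isolated gaps must be at least max_gap")

    def tf_names(self) -> list[str]:
        width = max(3, len(str(self.m_tfs - 1)))
        return [f"TF{i:0{width}d}" for i in range(self.m_tfs)]

    def propensity(self, tf: str, window_index: int) -> float:
        if self.propensities is not None:
            return self.propensities.get((tf, window_index), self.binding_propensity)
        return self.binding_propensity


def generate_tss_landscape(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[TSSRecord]:
    """Place TSSs so that a target fraction has a neighbor closer than max_gap.

    Close TSSs are laid down in pairs (one triple when the close count is
    odd) with intra-pair gaps below ``max_gap``; all groups are separated by
    gaps of at least ``max_gap``, so the realized close fraction equals the
    target up to rounding.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_tss
    n_close = int(round(config.close_pair_fraction * n))
    if n_close == 1:  # a single TSS cannot have a close neighbor
        n_close = 2 if n >= 2 else 0
    groups: list[int] = []
    if n_close:
        n_pairs, rem = divmod(n_close, 2)
        groups.extend([2] * n_pairs)
        if rem:
            groups[-1] += 1  # one triple absorbs the odd member
    groups.extend([1] * (n - sum(groups)))
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]

    chrom_items = list(config.chrom_lengths.items())
    ci = 0
    chrom, length = chrom_items[ci]
    pos = _EDGE_MARGIN
    records: list[TSSRecord] = []
    idx = 0
    for size in groups:
        span = (size - 1) * (config.max_gap - 1)
        while pos + span > length - _EDGE_MARGIN:
            ci += 1
            if ci >= len(chrom_items):
                raise ValueError(
                    "chromosomes too short for the requested number of TSSs"
                )
            chrom, length = chrom_items[ci]
            pos = _EDGE_MARGIN
        p = pos
        for k in range(size):
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                TSSRecord(
                    tss_id=f"tss{idx:06d}", chrom=chrom, position=int(p),
                    strand=strand, el={},
                )
            )
            idx += 1
            if k < size - 1:
                p += int(rng.integers(10, config.max_gap))
        gap = int(rng.integers(*config.isolated_gap_range))
        pos = p + gap
    return records


def generate_tfbr_sets(
    tss_list: Sequence[TSSRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TFBRSet]:
    """One final binding-region set per TF, driven by per-window propensities.

    For each (TF, window, TSS) an interval is placed, with the configured
    probability, as a random sub-interval of the realized genomic window.
    Background intervals (100 bp) are sprinkled uniformly at
    ``background_rate`` expected intervals per TSS per TF.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    windows = default_windows()
    n = len(tss_list)
    gstarts = np.empty((n, len(windows)), dtype=np.int64)
    gends = np.empty((n, len(windows)), dtype=np.int64)
    for i, tss in enumerate(tss_list):
        for j, w in enumerate(windows):
            g = window_to_genomic(tss, w)
            gstarts[i, j], gends[i, j] = g.start, g.end
    chroms = [t.chrom for t in tss_list]

    out: list[TFBRSet] = []
    for tf in config.tf_names():
        intervals: list[GenomicInterval] = []
        for j in range(len(windows)):
            p = config.propensity(tf, j)
            if p <= 0:
                continue
            hits = np.flatnonzero(rng.random(n) < p)
            if hits.size == 0:
                continue
            ws, we = gstarts[hits, j], gends[hits, j]
            lengths = rng.integers(1, we - ws + 1)
            starts = ws + rng.integers(0, we - ws - lengths + 1)
            for i, s, ln in zip(hits, starts, lengths):
                intervals.append(GenomicInterval(chroms[i], int(s), int(s + ln)))
        if config.background_rate > 0:
            n_bg = rng.poisson(config.background_rate * n)
            for _ in range(n_bg):
                chrom = list(config.chrom_lengths)[
                    int(rng.integers(0, len(config.chrom_lengths)))
                ]
                length = config.chrom_lengths[chrom]
                s = int(rng.integers(0, max(1, length - 100)))
                intervals.append(GenomicInterval(chrom, s, s + 100))
        out.append(
            TFBRSet(
                tf=tf, cell_line=config.cell_line, experiment_id="sim",
                caller="final", intervals=merge_intervals(intervals),
            )
        )
    return out


def generate_activities(
    tss_list: Sequence[TSSRecord],
    feature_matrix: FeatureMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict:
    """Fill raw expression levels from a sparse linear model on the features.

    The log-scale activity is intercept + sum of true effects times the
    realized feature values plus Gaussian noise, floored at 0.  Positive
    log activities are back-transformed to EL = 10**value; floored TSSs draw
    EL uniformly in [0, 2) so the log transform returns them to 0.

    Returns a ground-truth dict with the signal, noise-free and noisy
    log activities, and the effect vector used.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    n = feature_matrix.n_rows
    if len(tss_list) != n:
        raise ValueError("tss_list and feature matrix disagree on row count")
    name_to_col = {name: j for j, name in enumerate(feature_matrix.column_names)}
    beta = np.zeros(feature_matrix.n_cols)
    for name, coef in config.true_effects.items():
        if name not in name_to_col:
            raise KeyError(f"true effect on unknown feature column {name!r}")
        beta[name_to_col[name]] = coef
    signal = feature_matrix.values @ beta
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    lte_star = np.maximum(config.intercept + signal + noise, 0.0)
    el = np.where(lte_star > 0, np.power(10.0, lte_star), rng.uniform(0.0, 2.0, n))
    for rec, v in zip(tss_list, el):
        rec.el[config.cell_line] = float(v)
    return {
        "signal": signal,
        "lte_star": lte_star,
        "el": el,
        "beta": beta,
        "intercept": config.intercept,
        "noise_sd": config.noise_sd,
    }


def theoretical_r_op(signal: np.ndarray, noise_sd: float) -> float:
    """Correlation a correctly specified fit can attain: sd(signal)/sd(signal+noise)."""
    v = float(np.var(signal))
    if v == 0:
        return 0.0
    return float(np.sqrt(v / (v + noise_sd**2)))


def generate_caller_replicates(
    true_peaks: TFBRSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    callers: Sequence[str] = ("callerA", "callerB", "callerC", "callerD"),
) -> list[TFBRSet]:
    """Four jittered copies of a true peak set plus non-overlapping orphans.

    Each caller reproduces each true peak (boundary jitter preserves >= 1 bp
    overlap with the truth) with probability 1 - dropout, and contributes
    ``round(orphan_rate * n_true)`` false peaks placed beyond the occupied
    span so they overlap nothing from any caller.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    n_true = len(true_peaks.intervals)
    chrom_max: dict[str, int] = {}
    for iv in true_peaks.intervals:
        chrom_max[iv.chrom] = max(chrom_max.get(iv.chrom, 0), iv.end)
    orphan_cursor = {c: m + 10_000 for c, m in chrom_max.items()}
    anchor = true_peaks.intervals[0].chrom if n_true else "chrSim1"

    out: list[TFBRSet] = []
    j = config.caller_jitter
    for caller in callers:
        intervals: list[GenomicInterval] = []
        for iv in true_peaks.intervals:
            if config.caller_dropout > 0 and rng.random() < config.caller_dropout:
                continue
            s = iv.start + int(rng.integers(-j, j + 1)) if j else iv.start
            e = iv.end + int(rng.integers(-j, j + 1)) if j else iv.end
            s = max(0, min(s, iv.end - 1))  # keep >= 1 bp overlap with truth
            e = max(e, iv.start + 1)
            if e <= s:
                e = s + 1
            intervals.append(GenomicInterval(iv.chrom, s, e))
        n_orphans = int(round(config.orphan_rate * n_true))
        for _ in range(n_orphans):
            cur = orphan_cursor.get(anchor, 10_000)
            intervals.append(GenomicInterval(anchor, cur, cur + 200))
            orphan_cursor[anchor] = cur + 200 + 500
        out.append(
            TFBRSet(
                tf=true_peaks.tf, cell_line=true_peaks.cell_line,
                experiment_id=true_peaks.experiment_id, caller=caller,
                intervals=intervals,
            )
        )
    return out


@dataclasses.dataclass
class SimulatedDataset:
    config: SimConfig
    tss_list: list[TSSRecord]
    tfbr_sets: list[TFBRSet]
    feature_matrix: FeatureMatrix
    y: np.ndarray  # log-transformed activities the pipeline would fit
    truth: dict


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Landscape -> binding sets -> features -> activities, fully seeded."""
    from .expression_profiles import lte_transform

    rng = np.random.default_rng(config.seed)
    tss_list = generate_tss_landscape(config, rng)
    tfbr_sets = generate_tfbr_sets(tss_list, config, rng)
    fm = build_primary_features(tss_list, tfbr_sets)
    truth = generate_activities(tss_list, fm, config, rng)
    y = np.asarray(lte_transform(truth["el"]))
    return SimulatedDataset(
        config=config, tss_list=tss_list, tfbr_sets=tfbr_sets,
        feature_matrix=fm, y=y, truth=truth,
    )
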
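"""Meta-processing of per-experiment peak sets.

Three stages: overlap the callers' peak sets into connected-component
clusters, drop single-caller orphans when the experiment's quality metric
exceeds its threshold, and union the refined experiments into one final set
per TF.  Overlap means >= 1 shared bp; touching half-open intervals do not
overlap.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

from .io_formats import GenomicInterval, TFBRSet

__all__ = [
    "OverlapCluster",
    "MetaConfig",
    "cluster_caller_peaks",
    "refine_with_fpcm_gate",
    "union_refined",
    "merge_intervals",
    "meta_process_experiment",
]

DEFAULT_FPCM_THRESHOLD = 3.0


@dataclasses.dataclass
class OverlapCluster:
    """A connected component of overlapping peaks across callers."""

    merged: GenomicInterval
    members: list[tuple[str, GenomicInterval]]
    support: int  # number of distinct callers among members


@dataclasses.dataclass
class MetaConfig:
    """Configuration for the orphan-removal gate.

    The quality metric itself is injected: either a per-experiment value in
    ``fpcm_values`` or a callable on the cluster list.  Its formula is outside
    this package's scope.
    """

    fpcm_threshold: float = DEFAULT_FPCM_THRESHOLD
    fpcm_values: dict[str, float] | None = None
    fpcm_fn: Callable[[Sequence[OverlapCluster]], float] | None = None

    def __post_init__(self) -> None:
        if self.fpcm_threshold <= 0:
            raise ValueError("fpcm_threshold must be positive")

    def resolve_fpcm(
        self,
        experiment_id: str,
        clusters: Sequence[OverlapCluster],
        fpcm: float | None = None,
    ) -> float:
        if fpcm is not None:
            return fpcm
        if self.fpcm_values is not None and experiment_id in self.fpcm_values:
            return self.fpcm_values[experiment_id]
        if self.fpcm_fn is not None:
            return float(self.fpcm_fn(clusters))
        raise ValueError(
            f"no FPCM value available for experiment {experiment_id!r}: supply "
            "one via MetaConfig.fpcm_values, MetaConfig.fpcm_fn, or the fpcm "
            "argument"
        )


def cluster_caller_peaks(sets: Iterable[TFBRSet]) -> list[OverlapCluster]:
    """Cluster all callers' peaks into overlap connected components.

    All input sets must share tf and experiment_id.  Within a chromosome,
    clusters are the connected components of the pairwise >= 1 bp overlap
    graph; ``support`` counts distinct callers contributing to the component.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("at least one caller set is required")
    tfs = {s.tf for s in sets}
    if len(tfs) > 1:
        raise ValueError(f"mixed TF labels in caller sets: {sorted(tfs)}")
    exps = {s.experiment_id for s in sets}
    if len(exps) > 1:
        raise ValueError(f"mixed experiment ids in caller sets: {sorted(exps)}")

    tagged: list[tuple[str, GenomicInterval]] = []
    for s in sets:
        tagged.extend((s.caller, iv) for iv in s.intervals)
    tagged.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end))

    # Sweep: because members are sorted by start, a component is a maximal run
    # where each interval starts before the running max end on its chromosome.
    clusters: list[OverlapCluster] = []
    cur: list[tuple[str, GenomicInterval]] = []
    cur_chrom = None
    cur_end = -1
    for caller, iv in tagged:
        if cur and iv.chrom == cur_chrom and iv.start < cur_end:
            cur.append((caller, iv))
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(_finish_cluster(cur))
            cur = [(caller, iv)]
            cur_chrom = iv.chrom
            cur_end = iv.end
    if cur:
        clusters.append(_finish_cluster(cur))
    return clusters


def _finish_cluster(members: list[tuple[str, GenomicInterval]]) -> OverlapCluster:
    chrom = members[0][1].chrom
    start = min(iv.start for _, iv in members)
    end = max(iv.end for _, iv in members)
    return OverlapCluster(
        merged=GenomicInterval(chrom, start, end),
        members=list(members),
        support=len({c for c, _ in members}),
    )


def refine_with_fpcm_gate(
    clusters: Sequence[OverlapCluster],
    tf: str,
    cell_line: str = "",
    experiment_id: str = "",
    fpcm: float | None = None,
    config: MetaConfig | None = None,
) -> TFBRSet:
    """Drop support-1 orphan clusters when FPCM exceeds the threshold.

    If the resolved FPCM value is at or below ``config.fpcm_threshold`` every
    cluster is kept.  Surviving clusters are emitted as their merged spans
    with ``caller="refined"``.
    """
    config = config or MetaConfig()
    value = config.resolve_fpcm(experiment_id, clusters, fpcm)
    if value > config.fpcm_threshold:
        kept = [c for c in clusters if c.support > 1]
    else:
        kept = list(clusters)
    return TFBRSet(
        tf=tf,
        cell_line=cell_line,
        experiment_id=experiment_id,
        caller="refined",
        intervals=[c.merged for c in kept],
    )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge >= 1 bp-overlapping intervals into maximal non-overlapping ones."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def union_refined(refined: Iterable[TFBRSet], cell_line: str | None = None) -> TFBRSet:
    """Union refined per-experiment sets into the final per-TF set."""
    refined = list(refined)
    if not refined:
        raise ValueError("at least one refined set is required")
    tfs = {s.tf for s in refined}
    if len(tfs) > 1:
        raise ValueError(f"mixed TF labels in refined sets: {sorted(tfs)}")
    if cell_line is None:
        cell_line = refined[0].cell_line
    all_ivs = [iv for s in refined for iv in s.intervals]
    return TFBRSet(
        tf=refined[0].tf,
        cell_line=cell_line,
        experiment_id="union",
        caller="final",
        intervals=merge_intervals(all_ivs),
    )


def meta_process_experiment(
    caller_sets: Iterable[TFBRSet],
    fpcm: float | None = None,
    config: MetaConfig | None = None,
) -> TFBRSet:
    """Run clustering plus the orphan gate for one experiment."""
    caller_sets = list(caller_sets)
    clusters = cluster_caller_peaks(caller_sets)
    first = caller_sets[0]
    return refine_with_fpcm_gate(
        clusters,
        tf=first.tf,
        cell_line=first.cell_line,
        experiment_id=first.experiment_id,
        fpcm=fpcm,
        config=config,
    )
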
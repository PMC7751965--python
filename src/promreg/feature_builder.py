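"""Promoter-window feature construction.

Builds, for each TSS, eight window-level abundance features (fraction of TFs
bound in the window) and, per TF, eight binary presence/absence features --
8*(m+1) columns in total for m TFs.

Window offsets are closed intervals in TSS-relative bp.  Offset 0 is the TSS
base itself and belongs only to the [-100, 0] window, so the eight default
windows tile -5000..+1000 without gaps.  On the minus strand the offsets are
mirrored so that negative offsets are always upstream.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, TFBRSet, TSSRecord

__all__ = [
    "PromoterWindow",
    "FeatureDescriptor",
    "FeatureMatrix",
    "default_windows",
    "window_to_genomic",
    "compute_binary_feature",
    "compute_abundance",
    "build_primary_features",
]

_DEFAULT_OFFSETS = [
    (-5000, -1001),
    (-1000, -501),
    (-500, -201),
    (-200, -101),
    (-100, 0),
    (1, 100),
    (101, 500),
    (501, 1000),
]


@dataclasses.dataclass(frozen=True, order=True)
class PromoterWindow:
    """A closed TSS-relative offset interval [x1, x2] in bp."""

    x1: int
    x2: int

    def __post_init__(self) -> None:
        if self.x1 > self.x2:
            raise ValueError(f"window lower bound exceeds upper: [{self.x1}, {self.x2}]")

    @property
    def label(self) -> str:
        return f"[{self.x1}, {self.x2}]"


def default_windows() -> list[PromoterWindow]:
    """The eight default promoter windows, upstream-most first."""
    return [PromoterWindow(a, b) for a, b in _DEFAULT_OFFSETS]


def window_to_genomic(tss: TSSRecord, w: PromoterWindow) -> GenomicInterval:
    """Realize a TSS-relative window as a genomic interval (0-based half-open).

    For strand "+" the window covers 1-based positions position+x1..position+x2;
    for strand "-" it covers position-x2..position-x1, so negative offsets are
    upstream on either strand.  The interval is clamped at the chromosome
    start; a window falling entirely before bp 1 collapses to a 1 bp stub at 0.
    """
    if tss.strand == "+":
        lo1, hi1 = tss.position + w.x1, tss.position + w.x2
    else:
        lo1, hi1 = tss.position - w.x2, tss.position - w.x1
    # 1-based closed [lo1, hi1] -> 0-based half-open [lo1-1, hi1)
    start = max(lo1 - 1, 0)
    end = max(hi1, start + 1)
    return GenomicInterval(tss.chrom, start, end)


@dataclasses.dataclass(frozen=True)
class FeatureDescriptor:
    """Metadata for one feature-matrix column."""

    kind: str  # "abundance" | "binary" | "extra"
    window: PromoterWindow | None = None
    tf: str | None = None
    name_override: str | None = None

    @property
    def name(self) -> str:
        if self.name_override is not None:
            return self.name_override
        if self.kind == "abundance":
            return f"Abundance{self.window.label}"
        if self.kind == "binary":
            return f"{self.tf}{self.window.label}"
        raise ValueError(f"extra column without a name: {self!r}")


class FeatureMatrix:
    """TSS-by-feature matrix with per-column metadata.

    Rows follow the TSS order given at construction; columns are
    :class:`FeatureDescriptor` instances.  ``m`` is the number of distinct TFs
    the matrix was built from.
    """

    def __init__(
        self,
        tss_ids: Sequence[str],
        columns: Sequence[FeatureDescriptor],
        values: np.ndarray,
        m: int,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(tss_ids), len(columns)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(tss_ids)}, {len(columns)})"
            )
        self.tss_ids = list(tss_ids)
        self.columns = list(columns)
        self.values = values
        self.m = m

    @property
    def n_rows(self) -> int:
        return len(self.tss_ids)

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def subset(self, indices: Sequence[int]) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(
            self.tss_ids,
            [self.columns[i] for i in indices],
            self.values[:, indices],
            self.m,
        )

    def binary_only(self) -> "FeatureMatrix":
        return self.subset([i for i, c in enumerate(self.columns) if c.kind == "binary"])

    def filter_tfs(self, allowlist: Iterable[str]) -> "FeatureMatrix":
        """Keep abundance columns plus binary columns of allow-listed TFs."""
        allowed = set(allowlist)
        idx = [
            i
            for i, c in enumerate(self.columns)
            if c.kind != "binary" or c.tf in allowed
        ]
        return self.subset(idx)

    def with_extra_column(self, name: str, values: np.ndarray) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_rows,):
            raise ValueError(f"extra column must have length {self.n_rows}")
        return FeatureMatrix(
            self.tss_ids,
            self.columns + [FeatureDescriptor(kind="extra", name_override=name)],
            np.hstack([self.values, values[:, None]]),
            self.m,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.tss_ids, name="tss_id"),
            columns=self.column_names,
        )

    def column_metadata(self) -> pd.DataFrame:
        rows = []
        for c in self.columns:
            rows.append(
                {
                    "name": c.name,
                    "kind": c.kind,
                    "tf": c.tf or "",
                    "x1": c.window.x1 if c.window else "",
                    "x2": c.window.x2 if c.window else "",
                }
            )
        return pd.DataFrame(rows)


def write_feature_matrix(fm: FeatureMatrix, path, meta_path) -> None:
    """Write the matrix as TSV plus a column-metadata sidecar TSV."""
    fm.to_frame().to_csv(path, sep="\t")
    fm.column_metadata().to_csv(meta_path, sep="\t", index=False)


def read_feature_matrix(path, meta_path) -> FeatureMatrix:
    """Rebuild a :class:`FeatureMatrix` from the TSV pair written above."""
    frame = pd.read_csv(path, sep="\t", index_col="tss_id")
    meta = pd.read_csv(meta_path, sep="\t", keep_default_na=False)
    columns: list[FeatureDescriptor] = []
    tfs: set[str] = set()
    for _, row in meta.iterrows():
        kind = row["kind"]
        if kind == "extra":
            columns.append(FeatureDescriptor(kind="extra", name_override=row["name"]))
            continue
        window = PromoterWindow(int(row["x1"]), int(row["x2"]))
        tf = row["tf"] or None
        if kind == "binary":
            tfs.add(tf)
        columns.append(FeatureDescriptor(kind=kind, window=window, tf=tf))
    return FeatureMatrix(
        tss_ids=[str(i) for i in frame.index],
        columns=columns,
        values=frame.to_numpy(dtype=float),
        m=len(tfs),
    )


class _ChromIndex:
    """Sorted, merged interval arrays per chromosome for fast overlap queries."""

    def __init__(self, tfbrs: TFBRSet) -> None:
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for chrom, ivs in tfbrs.by_chrom().items():
            self.starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self.ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        starts = self.starts.get(chrom)
        if starts is None:
            return False
        ends = self.ends[chrom]
        # first interval ending after the query start; non-overlapping sorted
        # intervals make this the only overlap candidate
        j = int(np.searchsorted(ends, start, side="right"))
        return j < len(starts) and starts[j] < end

    def overlaps_many(
        self, chrom: str, qstarts: np.ndarray, qends: np.ndarray
    ) -> np.ndarray:
        starts = self.starts.get(chrom)
        if starts is None:
            return np.zeros(len(qstarts), dtype=bool)
        ends = self.ends[chrom]
        j = np.searchsorted(ends, qstarts, side="right")
        ok = j < len(starts)
        out = np.zeros(len(qstarts), dtype=bool)
        out[ok] = starts[j[ok]] < qends[ok]
        return out


def compute_binary_feature(tss: TSSRecord, w: PromoterWindow, tfbrs: TFBRSet) -> int:
    """1 iff any binding region shares >= 1 bp with the realized window."""
    if tfbrs.caller != "final":
        raise ValueError("binary features are computed against final TFBR sets")
    g = window_to_genomic(tss, w)
    idx = _ChromIndex(tfbrs)
    return int(idx.overlaps_any(g.chrom, g.start, g.end))


def compute_abundance(
    tss: TSSRecord,
    w: PromoterWindow,
    all_tfbrs: Sequence[TFBRSet],
    m: int | None = None,
) -> float:
    """Fraction m0/m of TFs with at least one binding region in the window."""
    all_tfbrs = list(all_tfbrs)
    if m is None:
        m = len(all_tfbrs)
    if m == 0:
        raise ValueError("abundance is undefined for m = 0 TFs")
    m0 = sum(compute_binary_feature(tss, w, t) for t in all_tfbrs)
    return m0 / m


def build_primary_features(
    tss_list: Sequence[TSSRecord],
    all_tfbrs: Sequence[TFBRSet],
    windows: Sequence[PromoterWindow] | None = None,
) -> FeatureMatrix:
    """Build the full 8*(m+1)-column feature matrix.

    Column order: the abundance columns in window order, then for each TF
    (sorted lexicographically) its binary columns in window order.  Rows
    follow ``tss_list`` order.
    """
    if windows is None:
        windows = default_windows()
    windows = list(windows)
    tfs = [t.tf for t in all_tfbrs]
    if len(set(tfs)) != len(tfs):
        dupes = sorted({t for t in tfs if tfs.count(t) > 1})
        raise ValueError(f"duplicate TF names in TFBR sets: {dupes}")
    order = sorted(range(len(all_tfbrs)), key=lambda i: all_tfbrs[i].tf)
    sets = [all_tfbrs[i] for i in order]
    m = len(sets)

    n = len(tss_list)
    n_w = len(windows)
    # realized query windows, grouped per chromosome for vectorized lookup
    qstart = np.empty((n, n_w), dtype=np.int64)
    qend = np.empty((n, n_w), dtype=np.int64)
    for i, tss in enumerate(tss_list):
        for j, w in enumerate(windows):
            g = window_to_genomic(tss, w)
            qstart[i, j] = g.start
            qend[i, j] = g.end
    chroms = np.array([t.chrom for t in tss_list])

    binary = np.zeros((n, m, n_w), dtype=float)
    uniq_chroms = sorted(set(chroms.tolist()))
    row_groups = {c: np.flatnonzero(chroms == c) for c in uniq_chroms}
    for k, tfbrs in enumerate(sets):
        if tfbrs.caller != "final":
            raise ValueError(
                f"TFBR set for {tfbrs.tf} must be final, got caller={tfbrs.caller!r}"
            )
        idx = _ChromIndex(tfbrs)
        for c, rows in row_groups.items():
            for j in range(n_w):
                binary[rows, k, j] = idx.overlaps_many(
                    c, qstart[rows, j], qend[rows, j]
                )

    abundance = binary.sum(axis=1) / m if m else np.zeros((n, n_w))

    columns = [FeatureDescriptor(kind="abundance", window=w) for w in windows]
    vals = [abundance]
    for k, tfbrs in enumerate(sets):
        columns += [
            FeatureDescriptor(kind="binary", window=w, tf=tfbrs.tf) for w in windows
        ]
        vals.append(binary[:, k, :])
    return FeatureMatrix(
        tss_ids=[t.tss_id for t in tss_list],
        columns=columns,
        values=np.hstack(vals),
        m=m,
    )
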
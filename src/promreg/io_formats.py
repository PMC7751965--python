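"""Readers and writers for the interval, activity-table, and report formats.

Coordinates are BED-style internally: 0-based, half-open.  TSS positions are
stored 1-based, as in annotation tables, and converted on use.  Chromosome
names are compared as exact strings -- no "chr" normalization is attempted.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "GenomicInterval",
    "TFBRSet",
    "TSSRecord",
    "ParseError",
    "read_tfbr_bed",
    "read_tss_activity_table",
    "write_tfbr_bed",
    "write_tss_activity_table",
    "write_model_report",
]

P_VALUE_FLOOR = 1e-300


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclasses.dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-agnostic genomic interval, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome name, compared as an exact string.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must exceed ``start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one bp (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class TFBRSet:
    """TF binding regions for one (TF, cell line, experiment, caller) combination.

    ``intervals`` are kept sorted by (chrom, start, end).  For
    ``caller="final"`` the intervals must additionally be non-overlapping per
    chromosome (enforced at construction).
    """

    tf: str
    cell_line: str
    experiment_id: str
    caller: str
    intervals: list[GenomicInterval] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        if self.caller == "final":
            self._check_nonoverlapping()

    def _check_nonoverlapping(self) -> None:
        for a, b in zip(self.intervals, self.intervals[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"final TFBRSet for {self.tf} has overlapping intervals "
                    f"{a} and {b}"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclasses.dataclass
class TSSRecord:
    """A transcription start site with raw expression levels per cell line.

    ``position`` is the 1-based bp of the TSS anchor.  ``el`` maps cell-line
    label to the raw expression level EL (>= 0).
    """

    tss_id: str
    chrom: str
    position: int
    strand: str
    el: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"TSS position must be >= 1, got {self.position}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for cl, v in self.el.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"EL for {cl} must be finite and >= 0, got {v}")


def read_tfbr_bed(
    path: str | Path,
    tf: str,
    cell_line: str = "",
    experiment_id: str = "",
    caller: str = "",
) -> TFBRSet:
    """Parse a 3+ column BED file into a :class:`TFBRSet`.

    Extra columns are ignored; ``track``, ``browser`` and ``#`` lines are
    skipped.  Malformed coordinates raise :class:`ParseError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate {s!r}/{e!r}"
                ) from None
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            intervals.append(GenomicInterval(chrom, start, end))
    return TFBRSet(
        tf=tf,
        cell_line=cell_line,
        experiment_id=experiment_id,
        caller=caller,
        intervals=intervals,
    )


def write_tfbr_bed(tfbrs: TFBRSet, path: str | Path) -> None:
    """Write intervals as 3-column BED (sorted)."""
    with open(path, "w") as fh:
        for iv in tfbrs.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tss_activity_table(path: str | Path) -> list[TSSRecord]:
    """Read the TSS activity TSV.

    The header must start with ``tss_id, chrom, position, strand``; every
    following column is a cell-line label holding EL values.  Cell-line column
    order is preserved as profile order (dicts keep insertion order).
    """
    records: list[TSSRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file, header required")
        cols = header.split("\t")
        required = ["tss_id", "chrom", "position", "strand"]
        if cols[: len(required)] != required:
            raise ParseError(
                f"{path}: header must begin with {required}, got {cols[:4]}"
            )
        cell_lines = cols[len(required) :]
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(cols)} columns, "
                    f"got {len(fields)}"
                )
            tss_id, chrom, pos_s, strand = fields[:4]
            if tss_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate tss_id {tss_id!r}")
            seen.add(tss_id)
            try:
                position = int(pos_s)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            el: dict[str, float] = {}
            for cl, v in zip(cell_lines, fields[4:]):
                try:
                    val = float(v)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric EL {v!r} for {cl}"
                    ) from None
                if val < 0:
                    raise ParseError(
                        f"{path}: line {lineno}: negative EL {val} for {cl}"
                    )
                el[cl] = val
            try:
                records.append(
                    TSSRecord(
                        tss_id=tss_id, chrom=chrom, position=position,
                        strand=strand, el=el,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_tss_activity_table(
    records: Iterable[TSSRecord], path: str | Path, cell_lines: list[str] | None = None
) -> None:
    """Write TSS records as the activity TSV read by :func:`read_tss_activity_table`."""
    records = list(records)
    if cell_lines is None:
        cell_lines = list(records[0].el) if records else []
    with open(path, "w") as fh:
        fh.write("\t".join(["tss_id", "chrom", "position", "strand"] + cell_lines))
        fh.write("\n")
        for rec in records:
            row = [rec.tss_id, rec.chrom, str(rec.position), rec.strand]
            row += [format_el(rec.el[cl]) for cl in cell_lines]
            fh.write("\t".join(row) + "\n")


def format_el(v: float) -> str:
    """Render an EL value exactly enough to round-trip through float()."""
    return repr(float(v))


def format_p_value(p: float, floored: bool) -> str:
    if floored or p < P_VALUE_FLOOR:
        return "<1.0e-300"
    return f"{p:.6g}"


def write_model_report(model, path: str | Path) -> None:
    """Write a fitted model as a TSV in selection order.

    Columns: Feature, R_o-p, increment, coefficient, p_value.  p-values
    below 1e-300 are rendered ``<1.0e-300``.
    """
    if model is None or not getattr(model, "fitted", False):
        raise ValueError("cannot write report for an unfitted model")
    with open(path, "w") as fh:
        fh.write("Feature\tR_o-p\tincrement\tcoefficient\tp_value\n")
        prev = 0.0
        for i, name in enumerate(model.feature_names):
            r_op = model.trace.r_op[i] if model.trace is not None else model.r_op
            incr = r_op - prev
            prev = r_op
            fh.write(
                f"{name}\t{r_op:.6g}\t{incr:.6g}\t{model.coefficients[i]:.6g}\t"
                f"{format_p_value(model.p_values[i], model.p_floored[i])}\n"
            )
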
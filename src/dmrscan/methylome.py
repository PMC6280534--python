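"""Per-cytosine methylation tables: parsing, validation, QC, and pooling.

Files use 1-based inclusive positions (the per-cytosine convention); all
interval math elsewhere in the package is 0-based half-open.  The ``pos``
column of a :class:`MethylomeTable` stays 1-based; converting functions are
the only crossing point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "MethylomeTable",
    "ValidationError",
    "EmptySelectionError",
    "AlignmentError",
    "read_methylation_calls",
    "write_methylation_calls",
    "classify_context",
    "conversion_rate",
    "weighted_methylation_level",
    "filter_by_depth",
    "pool_replicates",
    "qc_report",
]

CONTEXTS = ("CG", "CHG", "CHH")

_COLUMNS = ["chrom", "pos", "strand", "context", "c_count", "ct_count"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ValidationError(ValueError):
    """Raised when methylation calls violate the table invariants."""


class EmptySelectionError(ValueError):
    """Raised when an operation selects zero cytosines."""


class AlignmentError(ValueError):
    """Raised when tables do not share a cytosine catalogue."""


@dataclass
class MethylomeTable:
    """One sample's per-cytosine methylation calls.

    ``data`` holds columns chrom, pos (1-based), strand, context, c_count,
    ct_count, sorted by (chrom, pos, strand).
    """

    sample: str
    condition: str
    replicate: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))

    def levels(self) -> np.ndarray:
        """Per-cytosine methylation ratios c/ct (NaN where ct == 0)."""
        ct = self.data["ct_count"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ct > 0, self.data["c_count"].to_numpy(dtype=float) / ct, np.nan)


def _validate_frame(df: pd.DataFrame, line_offset: int = 0) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    df = df[_COLUMNS].copy()
    bad_lines: list[tuple[int, str]] = []

    def flag(mask: pd.Series, reason: str) -> None:
        for idx in df.index[mask][:20]:
            bad_lines.append((int(idx) + line_offset, reason))

    flag(~df["context"].isin(CONTEXTS), "unknown context token")
    flag(~df["strand"].isin(["+", "-"]), "strand must be + or -")
    flag(df["pos"] < 1, "position must be >= 1")
    flag(df["c_count"] < 0, "negative c_count")
    flag((df["ct_count"] < df["c_count"]), "c_count exceeds ct_count")
    dup = df.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    flag(dup & ~df.duplicated(subset=["chrom", "pos", "strand"], keep="first"),
         "duplicate (chrom, pos, strand)")
    if bad_lines:
        detail = "; ".join(f"line {ln}: {why}" for ln, why in bad_lines[:20])
        raise ValidationError(f"{len(bad_lines)} malformed rows ({detail})")
    df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["c_count"] = df["c_count"].astype(np.int64)
    df["ct_count"] = df["ct_count"].astype(np.int64)
    return df


def read_methylation_calls(
    path: str | Path,
    dialect: str = "native",
    sample: str | None = None,
    condition: str = "",
    replicate: int = 0,
) -> MethylomeTable:
    """Read a per-cytosine methylation call table.

    ``dialect="native"`` expects the six-column headered TSV written by this
    package; ``dialect="cx"`` accepts a Bismark-style CX report
    (chrom, pos, strand, meth, unmeth, context, trinucleotide; no header).
    """
    path = Path(path)
    if dialect == "native":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        offset = 2  # header occupies line 1
    elif dialect == "cx":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"],
            dtype={"chrom": str},
        )
        df["c_count"] = df["meth"]
        df["ct_count"] = df["meth"] + df["unmeth"]
        df = df[_COLUMNS]
        offset = 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        frame = _validate_frame(df, line_offset=offset)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None
    return MethylomeTable(sample or path.stem, condition, replicate, frame)


def write_methylation_calls(table: MethylomeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def classify_context(reference: str, pos: int, strand: str) -> str:
    """Classify the cytosine at 1-based ``pos`` on ``strand`` as CG/CHG/CHH.

    Context is read 5'->3' on the cytosine's own strand, i.e. the two bases
    3' of the cytosine (for the minus strand: the reverse complement of the
    two reference bases immediately to the left).  Near a contig end, a
    missing first downstream base forces CHH; a missing second base rules
    out CHG, so a non-G first base also yields CHH.
    """
    if not 1 <= pos <= len(reference):
        raise ValueError(f"position {pos} outside reference of length {len(reference)}")
    i = pos - 1
    base = reference[i].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"base at {pos}:+ is {base}, not C")
        n1 = reference[i + 1].upper() if i + 1 < len(reference) else ""
        n2 = reference[i + 2].upper() if i + 2 < len(reference) else ""
    elif strand == "-":
        if base != "G":
            raise ValueError(f"base at {pos}:- is {base.translate(_COMPLEMENT)}, not C")
        n1 = reference[i - 1].upper().translate(_COMPLEMENT) if i - 1 >= 0 else ""
        n2 = reference[i - 2].upper().translate(_COMPLEMENT) if i - 2 >= 0 else ""
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    if n1 == "G":
        return "CG"
    if not n1 or not n2:
        return "CHH"
    if n2 == "G":
        return "CHG"
    return "CHH"


def conversion_rate(
    table: MethylomeTable,
    control_contig: str,
    threshold: float = 0.996,
) -> tuple[float, bool]:
    """Bisulfite conversion rate on the unmethylated control contig.

    Returns ``(rate, qc_pass)`` where rate = 1 - pooled methylation over the
    control and the QC passes when rate >= threshold.
    """
    sub = table.data[table.data["chrom"] == control_contig]
    if sub.empty:
        raise EmptySelectionError(f"control contig {control_contig!r} absent")
    ct = int(sub["ct_count"].sum())
    if ct == 0:
        raise EmptySelectionError("zero informative reads on control contig")
    rate = 1.0 - int(sub["c_count"].sum()) / ct
    return rate, rate >= threshold


def weighted_methylation_level(
    table: MethylomeTable | pd.DataFrame,
    context: str | Sequence[str] | None = None,
    region: tuple[str, int, int] | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Pooled (count-weighted) methylation level: sum(c) / sum(ct).

    ``region`` is (chrom, start, end) in 0-based half-open coordinates;
    ``mask`` is a boolean row selector aligned to the table.
    """
    df = table.data if isinstance(table, MethylomeTable) else table
    sel = np.ones(len(df), dtype=bool)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if context is not None:
        wanted = [context] if isinstance(context, str) else list(context)
        sel &= df["context"].isin(wanted).to_numpy()
    if region is not None:
        chrom, start, end = region
        pos0 = df["pos"].to_numpy() - 1
        sel &= (df["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)
    ct = int(df["ct_count"].to_numpy()[sel].sum())
    if not sel.any() or ct == 0:
        raise EmptySelectionError("no informative cytosines in selection")
    return int(df["c_count"].to_numpy()[sel].sum()) / ct


def _assert_aligned(tables: Sequence[MethylomeTable]) -> None:
    ref = tables[0].data
    key = ref[["chrom", "pos", "strand"]]
    for t in tables[1:]:
        other = t.data[["chrom", "pos", "strand"]]
        if len(other) != len(key) or not (
            key["chrom"].equals(other["chrom"])
            and key["pos"].equals(other["pos"])
            and key["strand"].equals(other["strand"])
        ):
            raise AlignmentError(
                f"cytosine catalogues differ between {tables[0].sample} and {t.sample}"
            )


def filter_by_depth(tables: Sequence[MethylomeTable], min_depth: int = 4) -> np.ndarray:
    """Boolean mask of positions with ct_count >= min_depth in every library."""
    if not tables:
        raise ValueError("at least one table required")
    _assert_aligned(tables)
    mask = np.ones(len(tables[0]), dtype=bool)
    for t in tables:
        mask &= t.data["ct_count"].to_numpy() >= min_depth
    return mask


def pool_replicates(tables: Sequence[MethylomeTable]) -> MethylomeTable:
    """Sum c_count and ct_count across replicates of one condition."""
    if not tables:
        raise ValueError("at least one table required")
    conditions = {t.condition for t in tables}
    if len(conditions) > 1:
        raise ValueError(f"cannot pool across conditions {sorted(conditions)}")
    _assert_aligned(tables)
    pooled = tables[0].data.copy()
    for t in tables[1:]:
        pooled["c_count"] = pooled["c_count"] + t.data["c_count"].to_numpy()
        pooled["ct_count"] = pooled["ct_count"] + t.data["ct_count"].to_numpy()
    condition = tables[0].condition
    return MethylomeTable(f"{condition}_pooled", condition, -1, pooled)


def qc_report(
    tables: Iterable[MethylomeTable],
    control_contig: str,
    threshold: float = 0.996,
) -> pd.DataFrame:
    """Per-sample QC table: conversion rate, pass flag, global context levels."""
    rows = []
    for t in tables:
        rate, ok = conversion_rate(t, control_contig, threshold)
        genomic = t.data[t.data["chrom"] != control_contig]
        row = {
            "sample": t.sample,
            "condition": t.condition,
            "replicate": t.replicate,
            "conversion_rate": rate,
            "qc_pass": ok,
        }
        for ctx in CONTEXTS:
            try:
                row[f"level_{ctx}"] = weighted_methylation_level(genomic, context=ctx)
            except EmptySelectionError:
                row[f"level_{ctx}"] = np.nan
        row["level_mC"] = weighted_methylation_level(genomic)
        rows.append(row)
    return pd.DataFrame(rows)
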
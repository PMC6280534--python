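"""Small-RNA characterisation and 24-nt siRNA cluster / DMR association."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from .methylome import EmptySelectionError

__all__ = [
    "length_filter_and_histogram",
    "five_prime_composition",
    "normalize_rpm",
    "filter_long_te_clusters",
    "cluster_dmr_overlap",
    "sirna_metaprofile",
    "simple_cluster_positions",
    "read_clusters_bed",
    "write_clusters_bed",
]

MIN_LEN, MAX_LEN = 18, 30


def length_filter_and_histogram(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop reads outside [18, 30] nt; per-sample length fractions.

    ``records`` columns: sample, length, first_nt, chrom, start, end, count.
    The histogram is count-weighted and normalised to sum to 1 per sample.
    """
    kept = records[(records["length"] >= MIN_LEN) & (records["length"] <= MAX_LEN)].copy()
    hist = (
        kept.groupby(["sample", "length"])["count"].sum().reset_index(name="count")
    )
    totals = hist.groupby("sample")["count"].transform("sum")
    hist["fraction"] = hist["count"] / totals
    return kept.reset_index(drop=True), hist


def five_prime_composition(records: pd.DataFrame, length: int = 24) -> pd.Series:
    """Count-weighted 5'-nucleotide fractions among reads of one length."""
    sub = records[records["length"] == length]
    if sub.empty:
        raise EmptySelectionError(f"no records of length {length}")
    counts = sub.groupby("first_nt")["count"].sum()
    return counts / counts.sum()


def normalize_rpm(counts, total_cleaned_reads: float):
    """Reads-per-million: count * 1e6 / total cleaned reads."""
    if total_cleaned_reads <= 0:
        raise ValueError("total cleaned reads must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / total_cleaned_reads


def filter_long_te_clusters(
    clusters: pd.DataFrame,
    te_features: pd.DataFrame,
    min_te_len: float = 4000,
) -> pd.DataFrame:
    """Flag clusters fully inside long TE bodies; the rest are canonical.

    A cluster is excluded only when its whole interval lies within a TE of
    length >= ``min_te_len``; partial overlaps are retained.  Returns the
    input with an ``in_long_te`` column added.
    """
    tes = te_features[te_features["kind"] == "TE"] if "kind" in te_features else te_features
    long_tes = tes[(tes["end"] - tes["start"]) >= min_te_len]
    out = clusters.copy()
    flag = np.zeros(len(clusters), dtype=bool)
    if len(long_tes):
        ts = iv.interval_set(long_tes[["chrom", "start", "end"]])
        for chrom, (st, en) in ts.items():
            cm = (out["chrom"] == chrom).to_numpy()
            if not cm.any():
                continue
            cs = out["start"].to_numpy()[cm]
            ce = out["end"].to_numpy()[cm]
            i = np.searchsorted(st, cs, side="right") - 1
            contained = (i >= 0) & (ce <= en[np.maximum(i, 0)])
            flag[np.flatnonzero(cm)[contained]] = True
    out["in_long_te"] = flag
    return out


def canonical_clusters(clusters: pd.DataFrame, te_features: pd.DataFrame,
                       min_te_len: float = 4000) -> pd.DataFrame:
    flagged = filter_long_te_clusters(clusters, te_features, min_te_len)
    return flagged[~flagged["in_long_te"]].reset_index(drop=True)


def cluster_dmr_overlap(
    dmrs: pd.DataFrame,
    clusters: pd.DataFrame,
) -> tuple[np.ndarray, float]:
    """Per-DMR hit flags (>= 1 bp intersection with any cluster) + hit rate."""
    if dmrs.empty:
        return np.zeros(0, dtype=bool), float("nan")
    cset = iv.interval_set(clusters[["chrom", "start", "end"]])
    hits = iv.any_overlap(cset, dmrs)
    return hits, float(hits.mean())


def sirna_metaprofile(
    clusters: pd.DataFrame,
    anchors: pd.DataFrame,
    abundance_col: str,
    flank: int = 2000,
    body_bins: int = 10,
    flank_bin: int = 200,
) -> pd.DataFrame:
    """Mean normalised 24-nt abundance in bins around anchor regions.

    Anchor bodies are scaled into ``body_bins`` bins with fixed-width flank
    bins on either side.  Per-bin value = sum over anchors of the abundance
    of clusters overlapping the bin span, per bp, averaged over anchors.
    """
    if anchors.empty:
        raise EmptySelectionError("no anchor regions")
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    by_chrom = {}
    for c, sub in clusters.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[c] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                       sub[abundance_col].to_numpy(dtype=float))
    for anchor in anchors.itertuples():
        data = by_chrom.get(anchor.chrom)
        s, e = int(anchor.start), int(anchor.end)
        width = e - s
        spans = []
        for i in range(n_flank):
            spans.append((i, s - flank + i * flank_bin, s - flank + (i + 1) * flank_bin))
        for i in range(body_bins):
            spans.append((n_flank + i, s + (i * width) // body_bins,
                          s + ((i + 1) * width) // body_bins))
        for i in range(n_flank):
            spans.append((n_flank + body_bins + i, e + i * flank_bin,
                          e + (i + 1) * flank_bin))
        for b, bs, be in spans:
            if be <= bs:
                continue
            den[b] += be - bs
            if data is None:
                continue
            cs, ce, ab = data
            j = np.searchsorted(cs, be, side="left")
            k = np.searchsorted(ce, bs, side="right")
            # clusters[k:j] overlap [bs, be); weight by overlap length
            if j > k:
                ov = np.minimum(ce[k:j], be) - np.maximum(cs[k:j], bs)
                ov = np.clip(ov, 0, None)
                num[b] += float((ab[k:j] * ov).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(den > 0, num / den, np.nan)
    zone = ["upstream"] * n_flank + ["body"] * body_bins + ["downstream"] * n_flank
    return pd.DataFrame({"bin": np.arange(n_bins), "zone": zone, "value": prof})


def simple_cluster_positions(
    positions: pd.DataFrame,
    max_gap: int = 100,
    min_reads: int = 5,
) -> pd.DataFrame:
    """Convenience clusterer for synthetic pipelines only: merge 24-nt read
    positions within ``max_gap`` bp and keep groups with >= ``min_reads``
    reads.  This is a deliberately simplified stand-in for a dedicated
    small-RNA cluster caller and is not meant for real libraries.
    """
    rows = []
    for chrom, sub in positions.groupby("chrom"):
        sub = sub.sort_values("start")
        pos = sub["start"].to_numpy()
        cnt = sub["count"].to_numpy() if "count" in sub else np.ones(len(sub))
        if len(pos) == 0:
            continue
        cut = np.flatnonzero(np.diff(pos) > max_gap)
        bounds = np.concatenate(([0], cut + 1, [len(pos)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            reads = int(cnt[lo:hi].sum())
            if reads >= min_reads:
                rows.append({"chrom": chrom, "start": int(pos[lo]),
                             "end": int(pos[hi - 1]) + 1, "n_reads": reads})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_reads"])


def read_clusters_bed(path: str | Path,
                      abundance_tsv: str | Path | None = None) -> pd.DataFrame:
    """BED6 clusters; optional sidecar TSV joins per-sample abundances by name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     usecols=range(6), dtype={"chrom": str})
    if abundance_tsv is not None:
        ab = pd.read_csv(abundance_tsv, sep="\t")
        df = df.merge(ab, on="name", how="left")
    return df


def write_clusters_bed(clusters: pd.DataFrame, path: str | Path,
                       abundance_tsv: str | Path | None = None,
                       abundance_cols: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(clusters.itertuples(), start=1):
            name = getattr(row, "name", None) or f"cluster_{i}"
            score = int(getattr(row, "n_reads", 0))
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}\t{score}\t.\n")
    if abundance_tsv is not None and abundance_cols:
        cols = ["name"] if "name" in clusters else []
        out = clusters[cols + abundance_cols].copy()
        if "name" not in out:
            out.insert(0, "name", [f"cluster_{i}" for i in range(1, len(out) + 1)])
        out.to_csv(abundance_tsv, sep="\t", index=False, float_format="%.6g")
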
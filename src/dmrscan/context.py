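"""Genomic context of DMRs: gene association, element classes, enrichment
versus random regions, and metagene profiles.

Features are genes/TEs with strand-aware TSS/TES: on the plus strand the
TSS is ``start`` and the TES is ``end``; on the minus strand the converse.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals as iv
from .stats import fisher_exact_2x2

__all__ = [
    "read_features_gff3",
    "read_features_bed",
    "write_bed",
    "associate_dmrs_to_genes",
    "classify_elements",
    "ELEMENT_CLASSES",
    "sample_random_regions",
    "enrichment_test",
    "metagene_profile",
    "methylation_change_matrix",
]

ELEMENT_CLASSES = ("gene_body", "tss_up_2kb", "tes_down_2kb", "intergenic")

_FEATURE_COLS = ["chrom", "start", "end", "strand", "kind", "id"]


def read_features_gff3(path: str | Path, kinds: dict[str, str] | None = None) -> pd.DataFrame:
    """Load gene/TE features from GFF3 into a chrom/start/end/strand/kind/id frame.

    ``kinds`` maps GFF3 ``type`` values to feature kinds (default:
    gene->gene, transposable_element->TE); other types are skipped.
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    kinds = kinds or {"gene": "gene", "transposable_element": "TE"}
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in kinds:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append({
                "chrom": f[0],
                "start": int(f[3]) - 1,
                "end": int(f[4]),
                "strand": f[6] if f[6] in "+-" else "+",
                "kind": kinds[f[2]],
                "id": attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
            })
    return pd.DataFrame(rows, columns=_FEATURE_COLS).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def read_features_bed(path: str | Path, kind: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "id", "score", "strand"],
                     usecols=range(6), dtype={"chrom": str})
    df["kind"] = kind
    df["strand"] = df["strand"].where(df["strand"].isin(["+", "-"]), "+")
    return df[_FEATURE_COLS].sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str = "id",
              score_col: str | None = None) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(), start=1):
            name = getattr(row, name_col, None) or f"region_{i}"
            score = getattr(row, score_col) if score_col else 0
            strand = getattr(row, "strand", ".") or "."
            fh.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}\t{score}\t{strand}\n")


def _regulatory_window(features: pd.DataFrame, up: int, down: int) -> pd.DataFrame:
    """Strand-aware [TSS - up, TES + down) window per feature."""
    plus = features["strand"].to_numpy() == "+"
    start = np.where(plus,
                     features["start"].to_numpy() - up,
                     features["start"].to_numpy() - down)
    end = np.where(plus,
                   features["end"].to_numpy() + down,
                   features["end"].to_numpy() + up)
    out = features.copy()
    out["win_start"] = np.maximum(start, 0)
    out["win_end"] = end
    return out


def associate_dmrs_to_genes(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    up: int = 2000,
    down: int = 2000,
) -> pd.DataFrame:
    """Pair DMRs with genes whose [TSS-up, TES+down) window they overlap.

    Returns one row per (gene, DMR) pair with the DMR row index, plus the
    signed distance from the DMR to the gene body in gene orientation
    (0 when overlapping the body, negative upstream of the TSS).  A gene is
    DMR-associated iff it appears here; each DMR's closest gene is the pair
    with the smallest absolute distance.
    """
    win = _regulatory_window(genes, up, down)
    rows = []
    for g in win.itertuples():
        hits = dmrs[(dmrs["chrom"] == g.chrom)
                    & (dmrs["start"] < g.win_end)
                    & (dmrs["end"] > g.win_start)]
        for ridx, d in hits.iterrows():
            if d["end"] > g.start and d["start"] < g.end:
                dist = 0
            elif d["end"] <= g.start:
                gap = g.start - d["end"] + 1
                dist = -gap if g.strand == "+" else gap
            else:
                gap = d["start"] - g.end + 1
                dist = gap if g.strand == "+" else -gap
            rows.append({
                "gene_id": g.id,
                "dmr_index": ridx,
                "distance": int(dist),
                "direction": d.get("direction", ""),
            })
    return pd.DataFrame(rows, columns=["gene_id", "dmr_index", "distance", "direction"])


def _element_partition(features: pd.DataFrame, flank: int = 2000) -> dict[str, iv.IntervalSet]:
    """Disjoint genome partition with priority gene_body > tss_up > tes_down."""
    genes = features[features["kind"] == "gene"]
    body = iv.interval_set(genes[["chrom", "start", "end"]])
    plus = genes["strand"] == "+"
    tss_up = pd.concat([
        pd.DataFrame({"chrom": genes.loc[plus, "chrom"],
                      "start": np.maximum(genes.loc[plus, "start"] - flank, 0),
                      "end": genes.loc[plus, "start"]}),
        pd.DataFrame({"chrom": genes.loc[~plus, "chrom"],
                      "start": genes.loc[~plus, "end"],
                      "end": genes.loc[~plus, "end"] + flank}),
    ], ignore_index=True)
    tes_down = pd.concat([
        pd.DataFrame({"chrom": genes.loc[plus, "chrom"],
                      "start": genes.loc[plus, "end"],
                      "end": genes.loc[plus, "end"] + flank}),
        pd.DataFrame({"chrom": genes.loc[~plus, "chrom"],
                      "start": np.maximum(genes.loc[~plus, "start"] - flank, 0),
                      "end": genes.loc[~plus, "start"]}),
    ], ignore_index=True)
    tss_set = iv.subtract(iv.interval_set(tss_up), body)
    tes_set = iv.subtract(iv.subtract(iv.interval_set(tes_down), body), tss_set)
    return {"gene_body": body, "tss_up_2kb": tss_set, "tes_down_2kb": tes_set}


def classify_elements(
    dmrs: pd.DataFrame,
    features: pd.DataFrame,
    chrom_sizes: dict[str, int],
    flank: int = 2000,
) -> tuple[pd.Series, pd.Series]:
    """Element-class fractions of DMR midpoints and of the whole genome.

    Each DMR is assigned by its midpoint with priority gene_body >
    tss_up_2kb > tes_down_2kb > intergenic; the background applies the same
    partition to every genomic base.  Both outputs sum to 1.
    """
    parts = _element_partition(features, flank)
    mid = ((dmrs["start"] + dmrs["end"]) // 2).to_numpy()
    chroms = dmrs["chrom"].to_numpy()
    assigned = np.full(len(dmrs), "intergenic", dtype=object)
    unclaimed = np.ones(len(dmrs), dtype=bool)
    for cls in ("gene_body", "tss_up_2kb", "tes_down_2kb"):
        hit = iv.points_in(parts[cls], chroms, mid) & unclaimed
        assigned[hit] = cls
        unclaimed &= ~hit
    counts = pd.Series(assigned).value_counts()
    obs = pd.Series({c: counts.get(c, 0) / max(len(dmrs), 1) for c in ELEMENT_CLASSES})

    genome_bp = sum(chrom_sizes.values())
    # clip partition classes to chromosome bounds for the background
    bounds = iv.interval_set(pd.DataFrame({
        "chrom": list(chrom_sizes), "start": 0, "end": list(chrom_sizes.values())}))
    taken = 0
    bg = {}
    remaining = bounds
    for cls in ("gene_body", "tss_up_2kb", "tes_down_2kb"):
        clipped = iv.subtract(parts[cls], iv.subtract(parts[cls], remaining))
        n = iv.total_length(clipped)
        bg[cls] = n / genome_bp
        remaining = iv.subtract(remaining, clipped)
        taken += n
    bg["intergenic"] = (genome_bp - taken) / genome_bp
    return obs, pd.Series(bg)[list(ELEMENT_CLASSES)]


def sample_random_regions(
    dmrs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    seed: int,
    n_draws: int = 1,
) -> list[pd.DataFrame]:
    """Random region sets matching the DMR length multiset.

    Each draw places len(dmrs) regions uniformly over the genome (weighted
    by placeable positions per contig); regions that would run off a contig
    are redrawn.  Reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    lengths = (dmrs["end"] - dmrs["start"]).to_numpy()
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    draws = []
    for _ in range(n_draws):
        rows = []
        for L in lengths:
            room = sizes - L
            ok = room >= 0
            if not ok.any():
                raise ValueError(f"region of length {L} exceeds every contig")
            w = np.where(ok, room + 1, 0).astype(float)
            ci = rng.choice(len(chroms), p=w / w.sum())
            s = int(rng.integers(0, room[ci] + 1))
            rows.append({"chrom": chroms[ci], "start": s, "end": s + int(L)})
        draws.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return draws


def enrichment_test(
    observed_hits: np.ndarray,
    random_hits: np.ndarray,
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher p for observed-vs-random hit rates.

    Builds the 2x2 table [[obs_hit, obs_miss], [rand_hit, rand_miss]].
    The odds ratio is NaN when a margin cell pair is all zero.
    """
    obs = np.asarray(observed_hits, dtype=bool)
    rnd = np.asarray(random_hits, dtype=bool)
    a, b = int(obs.sum()), int((~obs).sum())
    c, d = int(rnd.sum()), int((~rnd).sum())
    p = fisher_exact_2x2(a, b, c, d)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return odds, p


def _feature_bins(
    feature,
    flank: int,
    body_bins: int,
    flank_bin: int,
) -> list[tuple[int, int, int]]:
    """(bin_index, start, end) spans for one stranded feature, 5'->3'.

    Bin indices run 0..n_flank-1 (upstream), then body, then downstream.
    """
    n_flank = flank // flank_bin
    s, e = int(feature.start), int(feature.end)
    spans = []
    # coordinates left->right first, flip bin order for minus strand below
    for i in range(n_flank):
        spans.append((i, s - flank + i * flank_bin, s - flank + (i + 1) * flank_bin))
    width = e - s
    for i in range(body_bins):
        bs = s + (i * width) // body_bins
        be = s + ((i + 1) * width) // body_bins
        spans.append((n_flank + i, bs, max(be, bs + 1) if width >= body_bins else be))
    for i in range(n_flank):
        spans.append((n_flank + body_bins + i, e + i * flank_bin, e + (i + 1) * flank_bin))
    if feature.strand == "-":
        total = 2 * n_flank + body_bins
        spans = [(total - 1 - b, bs, be) for b, bs, be in spans]
    return spans


def metagene_profile(
    signal: pd.DataFrame,
    features: pd.DataFrame,
    flank: int = 2000,
    body_bins: int = 20,
    flank_bin: int = 100,
    mode: str = "level",
) -> pd.DataFrame:
    """Average signal across length-normalised features plus fixed flanks.

    ``mode="level"``: signal has chrom/pos (0-based)/value and optional
    weight columns; per-bin output is the weighted mean value.
    ``mode="density"``: signal has chrom/start/end intervals; midpoints are
    counted and normalised per bp of aggregated bin span.
    Minus-strand features are flipped so bins read 5'->3'.
    """
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    if mode == "level":
        weights = (signal["weight"] if "weight" in signal else
                   pd.Series(1.0, index=signal.index))
        by_chrom = {}
        for c, sub in signal.groupby("chrom"):
            order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
            by_chrom[c] = (sub["pos"].to_numpy()[order],
                           sub["value"].to_numpy()[order],
                           weights[sub.index].to_numpy()[order])
    elif mode == "density":
        mids = (signal["start"] + signal["end"]) // 2
        by_chrom = {
            c: (np.sort(mids[sub.index].to_numpy()), None, None)
            for c, sub in signal.groupby("chrom")
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for feat in features.itertuples():
        data = by_chrom.get(feat.chrom)
        if data is None:
            continue
        pos, val, w = data
        for b, bs, be in _feature_bins(feat, flank, body_bins, flank_bin):
            if be <= bs:
                continue
            lo = np.searchsorted(pos, bs, side="left")
            hi = np.searchsorted(pos, be, side="left")
            if mode == "level":
                if hi > lo:
                    num[b] += float((val[lo:hi] * w[lo:hi]).sum())
                    den[b] += float(w[lo:hi].sum())
            else:
                num[b] += hi - lo
                den[b] += be - bs
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(den > 0, num / den, np.nan)
    zone = (["upstream"] * n_flank + ["body"] * body_bins + ["downstream"] * n_flank)
    return pd.DataFrame({"bin": np.arange(n_bins), "zone": zone, "value": prof})


def methylation_change_matrix(
    genes: pd.DataFrame,
    signal_a: pd.DataFrame,
    signal_b: pd.DataFrame,
    flank: int = 2000,
    body_bins: int = 20,
    flank_bin: int = 100,
) -> pd.DataFrame:
    """Per-gene, per-bin methylation change (condition B minus A).

    Signals are per-position level frames (chrom, pos, value, weight).
    Rows are genes (indexed by id), columns bin_0..bin_{n-1}; bins with no
    data on either side are NaN.
    """
    n_flank = flank // flank_bin
    n_bins = 2 * n_flank + body_bins
    mats = []
    for sig in (signal_a, signal_b):
        weights = (sig["weight"] if "weight" in sig else pd.Series(1.0, index=sig.index))
        by_chrom = {}
        for c, sub in sig.groupby("chrom"):
            order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
            by_chrom[c] = (sub["pos"].to_numpy()[order],
                           sub["value"].to_numpy()[order],
                           weights[sub.index].to_numpy()[order])
        mat = np.full((len(genes), n_bins), np.nan)
        for gi, feat in enumerate(genes.itertuples()):
            data = by_chrom.get(feat.chrom)
            if data is None:
                continue
            pos, val, w = data
            for b, bs, be in _feature_bins(feat, flank, body_bins, flank_bin):
                if be <= bs:
                    continue
                lo = np.searchsorted(pos, bs, side="left")
                hi = np.searchsorted(pos, be, side="left")
                if hi > lo and w[lo:hi].sum() > 0:
                    mat[gi, b] = float((val[lo:hi] * w[lo:hi]).sum() / w[lo:hi].sum())
        mats.append(mat)
    change = mats[1] - mats[0]
    out = pd.DataFrame(change, columns=[f"bin_{i}" for i in range(n_bins)])
    out.insert(0, "gene_id", genes["id"].to_numpy())
    return out
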
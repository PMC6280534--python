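"""Differential methylation calling between two pooled conditions.

The procedure: per-context 200-bp windows advanced by 50 bp are tested with
a two-sided Fisher exact test on pooled methylated/unmethylated counts;
windows are BH-adjusted per context genome-wide; candidate windows
(FDR < 0.05) across all three contexts are unioned and each merged region is
shrunk to its first and last differentially methylated cytosines (DMCs,
per-cytosine Fisher p < 0.05 at depth >= 4 in every library).  Regions with
more than three DMCs and an absolute pooled methylation difference above
0.15 are reported as DMRs, scored for replicate consistency by the robust
index |log2FC1 - log2FC2| / |log2FC1 + log2FC2|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .methylome import MethylomeTable, filter_by_depth, pool_replicates
from .stats import bh_adjust, fisher_exact_2x2_many

__all__ = [
    "DmrParams",
    "DmrResult",
    "scan_windows",
    "call_dmcs",
    "merge_and_shrink",
    "filter_dmrs",
    "robust_index",
    "rank_dmrs",
    "call_dmr_pipeline",
    "write_dmrs_bed",
    "write_dmrs_tsv",
]

CONTEXTS = ("CG", "CHG", "CHH")

DMR_COLUMNS = [
    "chrom", "start", "end", "n_dmc", "mean_diff", "direction", "fdr",
    "robust_index",
]


@dataclass
class DmrParams:
    """Tuning knobs of the DMR caller (defaults follow the pipeline above)."""

    window: int = 200
    step: int = 50
    min_depth: int = 4
    dmc_alpha: float = 0.05
    fdr: float = 0.05
    min_dmc: int = 4           # kept when n_dmc >= min_dmc (i.e. "> 3")
    min_diff: float = 0.15     # kept when |mean_diff| > min_diff
    epsilon: float = 0.01      # pseudocount for fold-change ratios
    robust_depth_floor: float = 4.0  # mean per-replicate depth for a usable index

    def validate(self) -> None:
        if self.window <= 0 or self.step <= 0 or self.step > self.window:
            raise ValueError("require 0 < step <= window")
        if not 0 < self.dmc_alpha <= 1 or not 0 < self.fdr <= 1:
            raise ValueError("alpha/fdr must be in (0, 1]")


@dataclass
class DmrResult:
    dmrs: pd.DataFrame
    windows: pd.DataFrame
    dmcs: pd.DataFrame
    counts: dict = field(default_factory=dict)
    params: DmrParams = field(default_factory=DmrParams)

    def manifest(self) -> dict:
        return {"params": asdict(self.params), "counts": self.counts}


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Window start coordinates tiling [0, length)."""
    if length <= window:
        return np.array([0], dtype=np.int64)
    last = length - window
    starts = np.arange(0, last + 1, step, dtype=np.int64)
    if starts[-1] != last:
        starts = np.append(starts, last)  # tail window, still full width
    return starts


def scan_windows(
    pooled_a: MethylomeTable,
    pooled_b: MethylomeTable,
    mask: np.ndarray,
    window: int = 200,
    step: int = 50,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window Fisher tests with per-context genome-wide BH FDR.

    Returns one row per (chrom, window, context) with pooled counts, the
    number of covered cytosines, the two-sided Fisher p and its BH-adjusted
    FDR.  Windows containing no depth-passing cytosine of a context are not
    tested in that context.
    """
    da, db = pooled_a.data, pooled_b.data
    mask = np.asarray(mask, dtype=bool)
    rows: list[pd.DataFrame] = []
    for chrom, sub in da.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        m = mask[idx]
        if not m.any():
            continue
        pos0 = sub["pos"].to_numpy()[m] - 1
        ctx = sub["context"].to_numpy()[m]
        ca = sub["c_count"].to_numpy()[m]
        ta = sub["ct_count"].to_numpy()[m]
        cb = db["c_count"].to_numpy()[idx][m]
        tb = db["ct_count"].to_numpy()[idx][m]
        length = (chrom_sizes or {}).get(chrom, int(pos0[-1]) + 1)
        starts = _window_starts(length, window, step)
        ends = starts + window
        for context in CONTEXTS:
            cm = ctx == context
            if not cm.any():
                continue
            p = pos0[cm]
            meth_a = np.concatenate(([0], np.cumsum(ca[cm])))
            tot_a = np.concatenate(([0], np.cumsum(ta[cm])))
            meth_b = np.concatenate(([0], np.cumsum(cb[cm])))
            tot_b = np.concatenate(([0], np.cumsum(tb[cm])))
            lo = np.searchsorted(p, starts, side="left")
            hi = np.searchsorted(p, ends, side="left")
            n_sites = hi - lo
            keep = n_sites > 0
            if not keep.any():
                continue
            lo, hi = lo[keep], hi[keep]
            wa = meth_a[hi] - meth_a[lo]
            wta = tot_a[hi] - tot_a[lo]
            wb = meth_b[hi] - meth_b[lo]
            wtb = tot_b[hi] - tot_b[lo]
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "start": starts[keep],
                "end": ends[keep],
                "context": context,
                "meth_a": wa,
                "unmeth_a": wta - wa,
                "meth_b": wb,
                "unmeth_b": wtb - wb,
                "n_sites": n_sites[keep],
            }))
    if not rows:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "context", "meth_a", "unmeth_a",
            "meth_b", "unmeth_b", "n_sites", "p_value", "fdr"])
    out = pd.concat(rows, ignore_index=True)
    out["p_value"] = fisher_exact_2x2_many(
        out["meth_a"].to_numpy(), out["unmeth_a"].to_numpy(),
        out["meth_b"].to_numpy(), out["unmeth_b"].to_numpy())
    out["fdr"] = np.nan
    for context in CONTEXTS:
        cm = (out["context"] == context).to_numpy()
        if cm.any():
            out.loc[cm, "fdr"] = bh_adjust(out.loc[cm, "p_value"].to_numpy())
    return out


def call_dmcs(
    pooled_a: MethylomeTable,
    pooled_b: MethylomeTable,
    mask: np.ndarray,
    alpha: float = 0.05,
    regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Differentially methylated cytosines: per-site Fisher p < alpha.

    ``mask`` is the all-library depth mask.  ``regions`` (chrom/start/end,
    0-based half-open) optionally restricts testing to positions inside the
    given intervals, which is how the pipeline uses it when shrinking
    candidate regions.
    """
    da, db = pooled_a.data, pooled_b.data
    sel = np.asarray(mask, dtype=bool).copy()
    if regions is not None and len(regions):
        in_region = np.zeros(len(da), dtype=bool)
        pos0 = da["pos"].to_numpy() - 1
        chrom_arr = da["chrom"].to_numpy()
        for chrom, sub in regions.groupby("chrom"):
            cm = chrom_arr == chrom
            if not cm.any():
                continue
            starts = np.sort(sub["start"].to_numpy())
            ends = sub.sort_values("start")["end"].to_numpy()
            i = np.searchsorted(starts, pos0[cm], side="right") - 1
            ok = (i >= 0) & (pos0[cm] < ends[np.maximum(i, 0)])
            in_region[np.flatnonzero(cm)[ok]] = True
        sel &= in_region
    elif regions is not None:
        sel &= False
    ca = da["c_count"].to_numpy()[sel]
    ta = da["ct_count"].to_numpy()[sel]
    cb = db["c_count"].to_numpy()[sel]
    tb = db["ct_count"].to_numpy()[sel]
    p = fisher_exact_2x2_many(ca, ta - ca, cb, tb - cb)
    hit = p < alpha
    out = pd.DataFrame({
        "chrom": da["chrom"].to_numpy()[sel][hit],
        "pos": da["pos"].to_numpy()[sel][hit],
        "strand": da["strand"].to_numpy()[sel][hit],
        "context": da["context"].to_numpy()[sel][hit],
        "level_a": np.where(ta[hit] > 0, ca[hit] / np.maximum(ta[hit], 1), np.nan),
        "level_b": np.where(tb[hit] > 0, cb[hit] / np.maximum(tb[hit], 1), np.nan),
        "p_value": p[hit],
    })
    return out.reset_index(drop=True)


def merge_and_shrink(candidates: pd.DataFrame, dmcs: pd.DataFrame) -> pd.DataFrame:
    """Union candidate windows across contexts, shrink to first/last DMC.

    Overlapping or book-ended candidate windows are merged; each merged
    region is trimmed to the span of the DMCs it contains (half-open end =
    last DMC position + 1) and records their count plus the minimum window
    FDR.  Regions without any DMC are dropped.
    """
    if candidates.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_dmc", "fdr"])
    out_rows = []
    for chrom, sub in candidates.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        fdrs = sub["fdr"].to_numpy()
        d = dmcs[dmcs["chrom"] == chrom]
        dpos0 = np.sort(d["pos"].to_numpy() - 1)
        cur_s, cur_e, cur_f = starts[0], ends[0], fdrs[0]
        merged = []
        for s, e, f in zip(starts[1:], ends[1:], fdrs[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
                cur_f = min(cur_f, f)
            else:
                merged.append((cur_s, cur_e, cur_f))
                cur_s, cur_e, cur_f = s, e, f
        merged.append((cur_s, cur_e, cur_f))
        for s, e, f in merged:
            lo = np.searchsorted(dpos0, s, side="left")
            hi = np.searchsorted(dpos0, e, side="left")
            if hi <= lo:
                continue  # no DMC: shrink undefined, region discarded
            out_rows.append({
                "chrom": chrom,
                "start": int(dpos0[lo]),
                "end": int(dpos0[hi - 1]) + 1,
                "n_dmc": int(hi - lo),
                "fdr": float(f),
            })
    return pd.DataFrame(out_rows, columns=["chrom", "start", "end", "n_dmc", "fdr"])


def robust_index(
    levels_a: Sequence[float],
    levels_b: Sequence[float],
    epsilon: float = 0.01,
    depth_ok: bool = True,
) -> float:
    """Replicate-consistency score |log2FC1 - log2FC2| / |log2FC1 + log2FC2|.

    FC_i = (level_b_i + epsilon) / (level_a_i + epsilon) for replicate i.
    Returns NaN (the NA marker) when the replicate count is not two, when a
    replicate failed the depth floor, or when log2FC1 + log2FC2 == 0.
    Lower values indicate more reproducible differential methylation.
    """
    if not depth_ok or len(levels_a) != 2 or len(levels_b) != 2:
        return float("nan")
    fc = [
        (lb + epsilon) / (la + epsilon)
        for la, lb in zip(levels_a, levels_b)
    ]
    lfc = np.log2(fc)
    denom = abs(lfc[0] + lfc[1])
    if denom == 0:
        return float("nan")
    return float(abs(lfc[0] - lfc[1]) / denom)


def filter_dmrs(
    regions: pd.DataFrame,
    min_dmc: int = 4,
    min_diff: float = 0.15,
) -> pd.DataFrame:
    """Keep regions with n_dmc >= min_dmc and |mean_diff| > min_diff.

    Requires a ``mean_diff`` column (condition B minus A, pooled over all
    contexts); assigns direction hypo when negative, hyper when positive.
    """
    if regions.empty:
        out = regions.copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    keep = (regions["n_dmc"] >= min_dmc) & (regions["mean_diff"].abs() > min_diff)
    out = regions[keep].copy()
    out["direction"] = np.where(out["mean_diff"] < 0, "hypo", "hyper")
    return out.reset_index(drop=True)


def rank_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Order DMRs by ascending robust index (lower = more credible).

    NA indices sort last; ties break by smaller window FDR, then genomic
    order.
    """
    if dmrs.empty:
        return dmrs.copy()
    df = dmrs.copy()
    df["_na"] = df["robust_index"].isna()
    df = df.sort_values(
        ["_na", "robust_index", "fdr", "chrom", "start"],
        kind="mergesort", na_position="last",
    ).drop(columns="_na")
    return df.reset_index(drop=True)


def _region_profiles(
    regions: pd.DataFrame,
    tables: Sequence[MethylomeTable],
    mask: np.ndarray,
) -> tuple[list[dict[str, np.ndarray]], np.ndarray]:
    """Per-region summed (c, ct) for each table, masked rows only.

    Regions must be non-overlapping per chromosome.  Returns one dict per
    table with 'c', 'ct' arrays aligned to ``regions`` rows (plus per-context
    breakdowns under 'c_<ctx>'/'ct_<ctx>'), and the per-region count of
    depth-passing cytosines.
    """
    n = len(regions)
    ref = tables[0].data
    pos0 = ref["pos"].to_numpy() - 1
    ctx_arr = ref["context"].to_numpy()
    chrom_arr = ref["chrom"].to_numpy()
    region_of = np.full(len(ref), -1, dtype=np.int64)
    for chrom, sub in regions.groupby("chrom"):
        cm = chrom_arr == chrom
        if not cm.any():
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ridx = sub.index.to_numpy()
        i = np.searchsorted(starts, pos0[cm], side="right") - 1
        ok = (i >= 0) & (pos0[cm] < ends[np.maximum(i, 0)])
        region_of[np.flatnonzero(cm)[ok]] = ridx[i[ok]]
    usable = (region_of >= 0) & np.asarray(mask, dtype=bool)
    rid = region_of[usable]
    sites = np.bincount(rid, minlength=n)
    out = []
    for t in tables:
        c = t.data["c_count"].to_numpy()[usable]
        ct = t.data["ct_count"].to_numpy()[usable]
        prof = {
            "c": np.bincount(rid, weights=c, minlength=n),
            "ct": np.bincount(rid, weights=ct, minlength=n),
        }
        for context in CONTEXTS:
            cm = ctx_arr[usable] == context
            prof[f"c_{context}"] = np.bincount(rid[cm], weights=c[cm], minlength=n)
            prof[f"ct_{context}"] = np.bincount(rid[cm], weights=ct[cm], minlength=n)
        out.append(prof)
    return out, sites


def call_dmr_pipeline(
    tables_a: Sequence[MethylomeTable],
    tables_b: Sequence[MethylomeTable],
    params: DmrParams | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> DmrResult:
    """Run the full two-condition DMR calling procedure.

    ``tables_a``/``tables_b`` are the replicate methylomes of condition A
    (reference, e.g. immature) and condition B (e.g. ripe).  Replicates are
    pooled for calling; per-replicate levels feed the robust index.
    """
    params = params or DmrParams()
    params.validate()
    all_tables = list(tables_a) + list(tables_b)
    mask = filter_by_depth(all_tables, params.min_depth)
    pooled_a = pool_replicates(list(tables_a))
    pooled_b = pool_replicates(list(tables_b))

    windows = scan_windows(pooled_a, pooled_b, mask, params.window, params.step, chrom_sizes)
    candidates = windows[windows["fdr"] < params.fdr]
    # Merge intervals first so DMC testing is confined to candidate space.
    merged_span = candidates[["chrom", "start", "end", "fdr"]]
    dmcs = call_dmcs(
        pooled_a, pooled_b, mask, params.dmc_alpha,
        regions=_merge_intervals(merged_span) if len(merged_span) else merged_span,
    )
    regions = merge_and_shrink(candidates, dmcs)

    counts = {
        "positions_total": int(len(pooled_a)),
        "positions_depth_pass": int(mask.sum()),
        "windows_tested": int(len(windows)),
        "windows_candidate": int(len(candidates)),
        "dmcs_in_candidates": int(len(dmcs)),
        "regions_shrunk": int(len(regions)),
    }

    if regions.empty:
        dmrs = pd.DataFrame(columns=DMR_COLUMNS)
        return DmrResult(dmrs, windows, dmcs, counts, params)

    profiles, region_sites = _region_profiles(regions, all_tables, mask)
    regions = regions.copy()
    regions["n_sites"] = region_sites
    n_a = len(tables_a)
    pooled = {
        "a": {k: sum(p[k] for p in profiles[:n_a]) for k in profiles[0]},
        "b": {k: sum(p[k] for p in profiles[n_a:]) for k in profiles[0]},
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = np.where(pooled["a"]["ct"] > 0, pooled["a"]["c"] / pooled["a"]["ct"], np.nan)
        level_b = np.where(pooled["b"]["ct"] > 0, pooled["b"]["c"] / pooled["b"]["ct"], np.nan)
    regions = regions.copy()
    regions["mean_diff"] = level_b - level_a
    for cond, key in (("a", "a"), ("b", "b")):
        for context in CONTEXTS:
            ct = pooled[key][f"ct_{context}"]
            with np.errstate(invalid="ignore", divide="ignore"):
                regions[f"level_{cond}_{context}"] = np.where(
                    ct > 0, pooled[key][f"c_{context}"] / ct, np.nan)

    dmrs = filter_dmrs(regions, params.min_dmc, params.min_diff)
    counts["dmrs"] = int(len(dmrs))
    counts["dmrs_hypo"] = int((dmrs["direction"] == "hypo").sum()) if len(dmrs) else 0
    counts["dmrs_hyper"] = int((dmrs["direction"] == "hyper").sum()) if len(dmrs) else 0

    if dmrs.empty:
        dmrs = pd.DataFrame(columns=DMR_COLUMNS)
        return DmrResult(dmrs, windows, dmcs, counts, params)

    # Per-replicate levels over each DMR for the robust index.  Map kept
    # DMR rows back onto `regions` row order by (chrom, start, end).
    pos_of = {
        (r.chrom, r.start, r.end): i for i, r in enumerate(regions.itertuples())
    }
    ridx = np.array([pos_of[(r.chrom, r.start, r.end)] for r in dmrs.itertuples()])
    sites = np.maximum(regions["n_sites"].to_numpy()[ridx], 1)

    rep_levels_a, rep_levels_b, rep_depths = [], [], []
    for i, prof in enumerate(profiles):
        ct = prof["ct"][ridx]
        with np.errstate(invalid="ignore", divide="ignore"):
            lev = np.where(ct > 0, prof["c"][ridx] / np.maximum(ct, 1), np.nan)
        rep_depths.append(ct / sites)  # mean informative reads per covered site
        (rep_levels_a if i < n_a else rep_levels_b).append(lev)

    ri = np.full(len(dmrs), np.nan)
    log2fc = np.full((len(dmrs), max(len(rep_levels_b), 1)), np.nan)
    if len(rep_levels_a) == 2 and len(rep_levels_b) == 2:
        depth_ok_vec = np.all(
            np.vstack(rep_depths) >= params.robust_depth_floor, axis=0)
        for j in range(len(dmrs)):
            la = [rep_levels_a[r][j] for r in range(2)]
            lb = [rep_levels_b[r][j] for r in range(2)]
            depth_ok = bool(depth_ok_vec[j]) and not any(np.isnan(la + lb))
            ri[j] = robust_index(la, lb, params.epsilon, depth_ok)
            if depth_ok:
                for r in range(2):
                    log2fc[j, r] = np.log2(
                        (lb[r] + params.epsilon) / (la[r] + params.epsilon))
    dmrs = dmrs.copy()
    dmrs["robust_index"] = ri
    for r in range(log2fc.shape[1]):
        dmrs[f"log2fc_rep{r + 1}"] = log2fc[:, r]
    for r, lev in enumerate(rep_levels_a):
        dmrs[f"level_a_rep{r + 1}"] = lev
    for r, lev in enumerate(rep_levels_b):
        dmrs[f"level_b_rep{r + 1}"] = lev

    dmrs = rank_dmrs(dmrs)
    return DmrResult(dmrs, windows, dmcs, counts, params)


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of (possibly overlapping/book-ended) intervals per chromosome."""
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_dmrs_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """BED6+ export: name=dmr_<i>, score column carries the robust index."""
    with open(path, "w") as fh:
        for i, row in enumerate(dmrs.itertuples(), start=1):
            ri = "NA" if np.isnan(row.robust_index) else f"{row.robust_index:.6g}"
            fields = [
                row.chrom, str(int(row.start)), str(int(row.end)),
                f"dmr_{i}", ri, ".",
                str(int(row.n_dmc)), f"{row.mean_diff:.6g}", row.direction,
                f"{row.fdr:.6g}",
            ]
            for ctx in CONTEXTS:
                for cond in ("a", "b"):
                    v = getattr(row, f"level_{cond}_{ctx}", np.nan)
                    fields.append("NA" if np.isnan(v) else f"{v:.6g}")
            fh.write("\t".join(fields) + "\n")


def write_dmrs_tsv(dmrs: pd.DataFrame, path: str | Path) -> None:
    dmrs.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def write_manifest(result: DmrResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result.manifest(), fh, indent=2, sort_keys=True)
        fh.write("\n")
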
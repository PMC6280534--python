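"""Differential-expression integration: DEG classes, hypomethylation flags,
and Fisher-based GO term enrichment."""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .context import associate_dmrs_to_genes
from .stats import bh_adjust, fisher_exact_2x2

__all__ = [
    "classify_degs",
    "flag_hypomethylated_degs",
    "go_enrichment",
    "read_deg_table",
    "read_go_map",
]

log = logging.getLogger(__name__)


def read_deg_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str})


def read_go_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def classify_degs(table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Three-way DEG classification: up / down (padj < alpha) or ns.

    Rows with a missing padj are dropped with a warning.  Genes with
    log2fc == 0 are never classified as differential.
    """
    df = table.copy()
    bad = df["padj"].isna() | df["log2fc"].isna()
    if bad.any():
        log.warning("dropping %d rows with missing padj/log2fc", int(bad.sum()))
        df = df[~bad]
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise ValueError("padj outside [0, 1]")
    sig = df["padj"] < alpha
    df["class"] = np.select(
        [sig & (df["log2fc"] > 0), sig & (df["log2fc"] < 0)],
        ["up", "down"], default="ns")
    return df.reset_index(drop=True)


def flag_hypomethylated_degs(
    degs: pd.DataFrame,
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    up: int = 2000,
    down: int = 2000,
) -> pd.DataFrame:
    """Flag DEGs with >= 1 hypo-DMR in their [TSS-2kb, TES+2kb] window.

    Adds ``hypomethylated`` and a four-way ``group`` (hypo-up, hypo-down,
    nonhypo-up, nonhypo-down; ns genes keep group "ns").  DEG genes missing
    from the annotation get a warning and flag False.
    """
    hypo = dmrs[dmrs["direction"] == "hypo"] if len(dmrs) else dmrs
    pairs = associate_dmrs_to_genes(hypo, genes, up, down) if len(hypo) else \
        pd.DataFrame(columns=["gene_id"])
    hypo_genes = set(pairs["gene_id"])
    known = set(genes["id"])
    out = degs.copy()
    missing = ~out["gene"].isin(known)
    if missing.any():
        log.warning("%d DEG genes absent from annotation", int(missing.sum()))
    out["hypomethylated"] = out["gene"].isin(hypo_genes)
    out["group"] = np.where(
        out["class"].isin(["up", "down"]),
        np.where(out["hypomethylated"], "hypo-", "nonhypo-") + out["class"],
        "ns")
    return out


def go_enrichment(
    gene_set: set[str] | list[str],
    background: set[str] | list[str],
    go_map: pd.DataFrame,
    fold_gate: float = 1.0,
    p_gate: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-term Fisher enrichment of ``gene_set`` against ``background``.

    For each term: k = set hits, n = set size, K = background hits,
    N = background size; fold = (k/n)/(K/N); two-sided Fisher p on
    [[k, n-k], [K-k, N-n-(K-k)]].  A term is enriched when
    |log2 fold| > fold_gate and p < p_gate (after optional BH adjustment).
    Terms with no background annotation are skipped.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    gm = go_map[go_map["gene"].isin(background)]
    n = len(gene_set)
    n_bg = len(background)
    rows = []
    for term, sub in gm.groupby("term"):
        term_genes = set(sub["gene"])
        big_k = len(term_genes)
        if big_k == 0:  # unreachable after the isin filter; kept for clarity
            continue
        k = len(term_genes & gene_set)
        fold = (k / n) / (big_k / n_bg) if n else float("nan")
        p = fisher_exact_2x2(k, n - k, big_k - k, n_bg - n - (big_k - k))
        log2_fold = math.log2(fold) if fold > 0 else float("-inf")
        rows.append({
            "term": term, "k": k, "n": n, "K": big_k, "N": n_bg,
            "fold_enrichment": fold, "log2_fold": log2_fold, "p_value": p,
        })
    out = pd.DataFrame(rows, columns=[
        "term", "k", "n", "K", "N", "fold_enrichment", "log2_fold", "p_value"])
    if out.empty:
        out["enriched"] = pd.Series(dtype=bool)
        return out
    p_eff = bh_adjust(out["p_value"].to_numpy()) if bh_correct else out["p_value"].to_numpy()
    out["p_effective"] = p_eff
    out["enriched"] = (np.abs(out["log2_fold"]) > fold_gate) & (p_eff < p_gate)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
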
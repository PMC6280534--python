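"""Synthetic two-condition methylome studies with planted ground truth.

Generates a miniature study end to end: random reference with an
unmethylated control contig, gene/TE annotation, replicated per-cytosine
methylomes with planted hypo/hyper differential regions, 24-nt siRNA
clusters co-located with hypo regions, and a differential-expression table
with genes linked to promoter hypomethylation.  Every planted signal is
echoed to truth tables so downstream callers can be scored without touching
generator internals.

Context baselines default to the typical plant profile (CG 40%, CHG 11%,
CHH 2%) with ~10 reads per strand and a 0.4% bisulfite conversion failure
rate.  Methylated counts are beta-binomial around the target level with a
single shared dispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .methylome import MethylomeTable

__all__ = [
    "SimulationSpec",
    "PlantedDMR",
    "SirnaPlan",
    "DegPlan",
    "SyntheticStudy",
    "generate_reference",
    "plan_dmrs",
    "generate_study",
    "simulate_methylome",
    "simulate_sirna_and_deg",
    "simulate_smallrna_records",
    "write_study",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_BASELINES = {"CG": 0.40, "CHG": 0.11, "CHH": 0.02}
# Elevated levels inside hypo-planted footprints in the immature condition,
# so that a subtraction of delta is observable in every context.
DEFAULT_DMR_BASELINES = {"CG": 0.80, "CHG": 0.60, "CHH": 0.40}


@dataclass
class PlantedDMR:
    chrom: str
    start: int  # 0-based half-open
    end: int
    direction: str  # hypo | hyper
    delta: float  # magnitude of the per-context level shift in condition B
    placement: str  # promoter | body | intergenic
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.delta <= 0:
            raise ValueError("delta is a positive magnitude; direction carries the sign")


@dataclass
class SirnaPlan:
    frac_colocated: float = 0.7
    fold_decrease: float = 4.0
    background_per_mb: float = 200.0
    cluster_len: tuple[int, int] = (150, 400)

    def validate(self) -> None:
        if not 0 <= self.frac_colocated <= 1:
            raise ValueError("frac_colocated must be in [0, 1]")
        if self.fold_decrease < 1:
            raise ValueError("fold_decrease must be >= 1")


@dataclass
class DegPlan:
    n_up: int = 6
    n_down: int = 6
    frac_hypo_linked: float = 0.5
    n_go_terms: int = 20
    go_background_rate: float = 0.05
    go_planted_enrichment: float = 5.0


@dataclass
class SimulationSpec:
    seed: int = 0
    genome_length: int = 200_000
    n_chromosomes: int = 2
    gc_content: float = 0.4
    baseline_levels: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    dmr_baseline_levels: dict = field(default_factory=lambda: dict(DEFAULT_DMR_BASELINES))
    mean_coverage: float = 10.0
    conversion_failure: float = 0.004
    n_replicates: int = 2
    dispersion: float = 0.02
    n_genes: int | None = None  # default: one gene slot per 10 kb
    te_per_mb: float = 30.0
    control_contig: str = "chloroplast"
    control_length: int = 20_000
    dmr_plan: list = field(default_factory=list)  # list[PlantedDMR]; may be auto-planned
    n_hypo: int = 10
    n_hyper: int = 2
    dmr_delta: float = 0.3
    dmr_width: tuple[int, int] = (300, 1500)
    sirna_plan: SirnaPlan = field(default_factory=SirnaPlan)
    deg_plan: DegPlan = field(default_factory=DegPlan)
    conditions: tuple[str, str] = ("immature", "ripe")

    def __post_init__(self) -> None:
        for name, v in [("gc_content", self.gc_content),
                        ("conversion_failure", self.conversion_failure)]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for d in (self.baseline_levels, self.dmr_baseline_levels):
            if any(not 0 <= x <= 1 for x in d.values()):
                raise ValueError("methylation levels must be fractions in [0, 1]")
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        self.sirna_plan.validate()

    @property
    def gene_count(self) -> int:
        return self.n_genes if self.n_genes is not None else max(self.genome_length // 10_000, 4)

    def chrom_sizes(self) -> dict[str, int]:
        per = self.genome_length // self.n_chromosomes
        sizes = {f"chr{i + 1}": per for i in range(self.n_chromosomes)}
        sizes[f"chr{self.n_chromosomes}"] += self.genome_length - per * self.n_chromosomes
        return sizes


@dataclass
class SyntheticStudy:
    spec: SimulationSpec
    reference: dict  # chrom -> sequence string (includes control contig)
    catalogue: pd.DataFrame  # chrom, pos (1-based), strand, context
    genes: pd.DataFrame
    tes: pd.DataFrame
    planted: pd.DataFrame  # truth table of planted DMRs
    chrom_sizes: dict

    # per-catalogue-row target methylation level for each condition
    _levels: dict = field(default_factory=dict, repr=False)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _catalogue_for(seq: str, chrom: str) -> pd.DataFrame:
    """Vectorised cytosine catalogue (both strands) for one contig."""
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    # A=65 C=67 G=71 T=84
    is_c = code == 67
    is_g = code == 71
    n = len(code)

    def ctx_plus(idx: np.ndarray) -> np.ndarray:
        n1 = np.where(idx + 1 < n, code[np.minimum(idx + 1, n - 1)], 0)
        n2 = np.where(idx + 2 < n, code[np.minimum(idx + 2, n - 1)], 0)
        out = np.full(len(idx), "CHH", dtype=object)
        out[(n1 != 71) & (n2 == 71) & (n1 != 0)] = "CHG"
        out[n1 == 71] = "CG"
        return out

    def ctx_minus(idx: np.ndarray) -> np.ndarray:
        # read 3' on the minus strand = leftwards on the reference;
        # a reference C complements to G on the minus strand
        n1 = np.where(idx - 1 >= 0, code[np.maximum(idx - 1, 0)], 0)
        n2 = np.where(idx - 2 >= 0, code[np.maximum(idx - 2, 0)], 0)
        out = np.full(len(idx), "CHH", dtype=object)
        out[(n1 != 67) & (n2 == 67) & (n1 != 0)] = "CHG"
        out[n1 == 67] = "CG"
        return out

    pi = np.flatnonzero(is_c)
    mi = np.flatnonzero(is_g)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.concatenate([pi, mi]) + 1,
        "strand": np.concatenate([np.full(len(pi), "+"), np.full(len(mi), "-")]),
        "context": np.concatenate([ctx_plus(pi), ctx_minus(mi)]),
    })
    return df.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)


def generate_reference(spec: SimulationSpec) -> tuple[dict, pd.DataFrame]:
    """Random reference (chromosomes + unmethylated control) and catalogue."""
    rng = np.random.default_rng([spec.seed, 0])
    reference = {}
    frames = []
    for chrom, size in spec.chrom_sizes().items():
        seq = _random_sequence(rng, size, spec.gc_content)
        reference[chrom] = seq
        frames.append(_catalogue_for(seq, chrom))
    ctrl = _random_sequence(rng, spec.control_length, spec.gc_content)
    reference[spec.control_contig] = ctrl
    frames.append(_catalogue_for(ctrl, spec.control_contig))
    catalogue = pd.concat(frames, ignore_index=True)
    catalogue = catalogue.sort_values(
        ["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
    return reference, catalogue


def _plan_annotation(spec: SimulationSpec, rng: np.random.Generator):
    """Genes on a jittered grid of slots; TEs scattered in the gaps."""
    sizes = spec.chrom_sizes()
    chroms = list(sizes)
    n_genes = spec.gene_count
    slot = spec.genome_length // n_genes
    if slot < 7000:
        raise ValueError(
            f"genome too short for {n_genes} gene slots (slot {slot} bp < 7 kb)")
    genes = []
    offsets = np.cumsum([0] + [sizes[c] for c in chroms])
    for i in range(n_genes):
        g_start_abs = i * slot + 2500  # leave room for a promoter DMR
        length = int(rng.integers(1000, 3001))
        ci = int(np.searchsorted(offsets, g_start_abs, side="right") - 1)
        start = g_start_abs - int(offsets[ci])
        if start + length + 2500 > sizes[chroms[ci]]:
            continue
        genes.append({
            "chrom": chroms[ci], "start": start, "end": start + length,
            "strand": "+" if rng.random() < 0.5 else "-",
            "kind": "gene", "id": f"gene{i + 1:05d}",
        })
    genes_df = pd.DataFrame(genes)
    tes = []
    n_tes = int(spec.te_per_mb * spec.genome_length / 1e6)
    for i in range(n_tes):
        length = int(rng.integers(500, 8001))
        ci = int(rng.integers(0, len(chroms)))
        if sizes[chroms[ci]] <= length:
            continue
        start = int(rng.integers(0, sizes[chroms[ci]] - length))
        tes.append({
            "chrom": chroms[ci], "start": start, "end": start + length,
            "strand": "+" if rng.random() < 0.5 else "-",
            "kind": "TE", "id": f"te{i + 1:05d}",
        })
    tes_df = pd.DataFrame(tes, columns=["chrom", "start", "end", "strand", "kind", "id"])
    return genes_df, tes_df


def plan_dmrs(
    spec: SimulationSpec,
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> list[PlantedDMR]:
    """Place hypo and hyper DMRs, preferentially near TSSs.

    One planted DMR per gene slot (promoter/body alternating with a minority
    of intergenic placements) guarantees non-overlapping, recoverable
    signal.  Raises when the plan needs more slots than genes exist.
    """
    n_total = spec.n_hypo + spec.n_hyper
    if n_total > len(genes):
        raise ValueError(
            f"genome too short to host dmr_plan: {n_total} DMRs > {len(genes)} gene slots")
    order = rng.permutation(len(genes))[:n_total]
    directions = ["hypo"] * spec.n_hypo + ["hyper"] * spec.n_hyper
    placements = []
    for i in range(n_total):
        placements.append("promoter" if i % 10 < 6 else ("body" if i % 10 < 9 else "intergenic"))
    plan = []
    lo_w, hi_w = spec.dmr_width
    sizes = spec.chrom_sizes()
    slot = spec.genome_length // len(genes) if len(genes) else spec.genome_length
    for gi, direction, placement in zip(order, directions, placements):
        g = genes.iloc[int(gi)]
        width = int(rng.integers(lo_w, hi_w + 1))
        gene_id = g["id"]
        if placement == "promoter":
            # overlap the 2 kb upstream of the strand-aware TSS
            if g["strand"] == "+":
                end = int(g["start"]) - int(rng.integers(0, 200))
                start = max(end - width, 0)
            else:
                start = int(g["end"]) + int(rng.integers(0, 200))
                end = start + width
        elif placement == "body":
            width = min(width, int(g["end"] - g["start"]))
            start = int(g["start"])
            end = start + width
        else:
            # in the slot gap downstream of the gene, clear of the next
            # slot's promoter zone and regulatory window
            start = int(g["end"]) + 2600
            end = min(start + width,
                      start + (slot - 2600 - 3400),
                      sizes[g["chrom"]])
            gene_id = ""
        if end - start < 100:  # degenerate placement: fall back to the body
            start = int(g["start"])
            end = min(start + lo_w, int(g["end"]))
            placement, gene_id = "body", g["id"]
        plan.append(PlantedDMR(g["chrom"], start, end, direction,
                               spec.dmr_delta, placement, gene_id))
    return plan


def generate_study(spec: SimulationSpec) -> SyntheticStudy:
    """Reference + annotation + DMR plan + per-condition target levels."""
    reference, catalogue = generate_reference(spec)
    rng = np.random.default_rng([spec.seed, 1])
    genes, tes = _plan_annotation(spec, rng)
    plan = list(spec.dmr_plan) if spec.dmr_plan else plan_dmrs(spec, genes, rng)
    planted = pd.DataFrame(
        [asdict(d) for d in plan],
        columns=["chrom", "start", "end", "direction", "delta", "placement", "gene_id"])

    cond_a, cond_b = spec.conditions
    ctx = catalogue["context"].to_numpy()
    base = np.array([spec.baseline_levels[c] for c in ctx])
    level_a = base.copy()
    level_b = base.copy()
    chrom_arr = catalogue["chrom"].to_numpy()
    pos0 = catalogue["pos"].to_numpy() - 1
    in_planted = np.zeros(len(catalogue), dtype=bool)
    for d in plan:
        m = (chrom_arr == d.chrom) & (pos0 >= d.start) & (pos0 < d.end)
        if d.direction == "hypo":
            high = np.array([spec.dmr_baseline_levels[c] for c in ctx[m]])
            level_a[m] = high
            level_b[m] = np.clip(high - d.delta, 0.0, 1.0)
        else:
            level_b[m] = np.clip(base[m] + d.delta, 0.0, 1.0)
        in_planted |= m
    ctrl = chrom_arr == spec.control_contig
    level_a[ctrl] = spec.conversion_failure
    level_b[ctrl] = spec.conversion_failure

    study = SyntheticStudy(spec, reference, catalogue, genes, tes, planted,
                           spec.chrom_sizes())
    study._levels = {cond_a: level_a, cond_b: level_b,
                     "_in_planted": in_planted, "_control": ctrl}
    return study


def simulate_methylome(
    study: SyntheticStudy,
    condition: str,
    replicate: int,
) -> MethylomeTable:
    """One replicate library: Poisson coverage, beta-binomial methylation.

    Coverage is Poisson(mean_coverage) per cytosine-strand, forced to >= 1
    inside planted DMR footprints so the planted signal stays observable.
    Control-contig counts are plain binomial at the conversion-failure rate.
    """
    spec = study.spec
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}; expected {spec.conditions}")
    cond_idx = spec.conditions.index(condition)
    rng = np.random.default_rng([spec.seed, 100 + cond_idx, replicate])
    n = len(study.catalogue)
    level = study._levels[condition]
    cov = rng.poisson(spec.mean_coverage, size=n)
    planted = study._levels["_in_planted"]
    cov[planted] = np.maximum(cov[planted], 1)

    rho = spec.dispersion
    control = study._levels["_control"]
    p_eff = level.copy()
    if rho > 0:
        varying = (~control) & (level > 0) & (level < 1)
        a = level[varying] * (1 - rho) / rho
        b = (1 - level[varying]) * (1 - rho) / rho
        p_eff[varying] = rng.beta(a, b)
    c = rng.binomial(cov, p_eff)
    data = study.catalogue.copy()
    data["c_count"] = c
    data["ct_count"] = cov
    return MethylomeTable(f"{condition}_rep{replicate}", condition, replicate, data)


def simulate_sirna_and_deg(study: SyntheticStudy):
    """Clusters, DEG table, and GO map consistent with the planted truth.

    Returns (clusters, degs, go_map).  Exactly
    round(frac_colocated * n_hypo) planted hypo DMRs receive a co-located
    cluster whose abundance drops by the planned fold in the ripe
    condition; background clusters avoid planted hypo footprints and keep
    their abundance.  The DEG table holds exactly n_up + n_down significant
    genes, the planned fraction of which carry a promoter hypo-DMR.
    """
    spec = study.spec
    plan = spec.sirna_plan
    rng = np.random.default_rng([spec.seed, 2])
    hypo = study.planted[study.planted["direction"] == "hypo"].reset_index(drop=True)
    n_coloc = int(round(plan.frac_colocated * len(hypo)))
    chosen = rng.permutation(len(hypo))[:n_coloc]
    rows = []
    lo_c, hi_c = plan.cluster_len
    for i in chosen:
        d = hypo.iloc[int(i)]
        width = min(int(rng.integers(lo_c, hi_c + 1)), int(d["end"] - d["start"]))
        start = int(d["start"]) + int(rng.integers(0, d["end"] - d["start"] - width + 1))
        rows.append({"chrom": d["chrom"], "start": start, "end": start + width,
                     "colocated": True})
    sizes = {c: s for c, s in study.chrom_sizes.items() if c != spec.control_contig}
    chroms = list(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    n_bg = int(plan.background_per_mb * sum(sizes.values()) / 1e6)
    hypo_iv = {
        c: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for c, sub in hypo.groupby("chrom")
    }
    placed = 0
    while placed < n_bg:
        width = int(rng.integers(lo_c, hi_c + 1))
        ci = int(rng.choice(len(chroms), p=weights / weights.sum()))
        start = int(rng.integers(0, sizes[chroms[ci]] - width))
        st, en = hypo_iv.get(chroms[ci], (np.array([]), np.array([])))
        if len(st) and ((start < en) & (start + width > st)).any():
            continue  # keep background clusters clear of planted hypo DMRs
        rows.append({"chrom": chroms[ci], "start": start, "end": start + width,
                     "colocated": False})
        placed += 1
    clusters = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    clusters["name"] = [f"cluster_{i + 1}" for i in range(len(clusters))]
    imm = rng.uniform(20, 100, size=len(clusters))
    ripe = np.where(clusters["colocated"], imm / plan.fold_decrease, imm)
    clusters["rpm_immature"] = imm
    clusters["rpm_ripe"] = ripe
    clusters["n_reads"] = np.round(imm * 10).astype(int)

    degs, go_map = _simulate_degs(study, rng)
    return clusters, degs, go_map


def _simulate_degs(study: SyntheticStudy, rng: np.random.Generator):
    spec = study.spec
    dp = spec.deg_plan
    genes = study.genes["id"].tolist()
    promoter_hypo = study.planted[
        (study.planted["direction"] == "hypo")
        & (study.planted["placement"].isin(["promoter", "body"]))
    ]["gene_id"].tolist()
    planted_genes = set(study.planted["gene_id"]) - {""}
    n_deg = dp.n_up + dp.n_down
    n_linked = int(round(dp.frac_hypo_linked * n_deg))
    if n_linked > len(promoter_hypo):
        raise ValueError(
            f"deg_plan needs {n_linked} hypo-linked genes but only "
            f"{len(promoter_hypo)} genes carry a planted hypo DMR")
    linked = [promoter_hypo[i] for i in rng.permutation(len(promoter_hypo))[:n_linked]]
    unlinked_pool = [g for g in genes if g not in planted_genes]
    need = n_deg - n_linked
    if need > len(unlinked_pool):
        raise ValueError("not enough unplanted genes for the DEG plan")
    others = [unlinked_pool[i] for i in rng.permutation(len(unlinked_pool))[:need]]
    deg_genes = linked + others
    order = rng.permutation(n_deg)
    rows = []
    for rank, gi in enumerate(order):
        gene = deg_genes[int(gi)]
        up = rank < dp.n_up
        rows.append({
            "gene": gene,
            "log2fc": float(rng.uniform(1, 4)) * (1 if up else -1),
            "padj": float(10 ** rng.uniform(-6, np.log10(0.005))),
            "truth_class": "up" if up else "down",
            "truth_hypo_linked": gene in set(linked),
        })
    ns_pool = [g for g in genes if g not in set(deg_genes)]
    for gene in ns_pool:
        rows.append({
            "gene": gene,
            "log2fc": float(rng.normal(0, 0.3)),
            "padj": float(rng.uniform(0.02, 1.0)),
            "truth_class": "ns",
            "truth_hypo_linked": False,
        })
    degs = pd.DataFrame(rows)

    q = dp.go_background_rate
    terms = [f"GO:{i + 1:07d}" for i in range(dp.n_go_terms)]
    planted_term = "GO:PLANTED"
    hypo_up = set(degs[(degs["truth_class"] == "up") & degs["truth_hypo_linked"]]["gene"])
    go_rows = []
    for gene in degs["gene"]:
        for t in terms:
            if rng.random() < q:
                go_rows.append({"gene": gene, "term": t})
        rate = min(1.0, q * dp.go_planted_enrichment) if gene in hypo_up else q
        if rng.random() < rate:
            go_rows.append({"gene": gene, "term": planted_term})
    go_map = pd.DataFrame(go_rows, columns=["gene", "term"])
    return degs, go_map


def simulate_smallrna_records(
    spec: SimulationSpec,
    n_records: int = 5000,
    frac_24nt: float = 0.6,
    first_nt_bias_a: float = 0.6,
) -> pd.DataFrame:
    """Small-RNA read summaries with a 24-nt mode and 5'-A bias at 24 nt."""
    rng = np.random.default_rng([spec.seed, 3])
    sizes = {c: s for c, s in spec.chrom_sizes().items()}
    chroms = list(sizes)
    lengths = np.where(rng.random(n_records) < frac_24nt, 24,
                       rng.integers(16, 33, size=n_records))
    is24 = lengths == 24
    other = np.array(["A", "C", "G", "U"])
    first = np.where(
        is24 & (rng.random(n_records) < first_nt_bias_a), "A",
        other[rng.integers(0, 4, size=n_records)])
    ci = rng.integers(0, len(chroms), size=n_records)
    starts = np.array([int(rng.integers(0, sizes[chroms[i]] - 40)) for i in ci])
    return pd.DataFrame({
        "sample": "pooled",
        "length": lengths,
        "first_nt": first,
        "chrom": [chroms[i] for i in ci],
        "start": starts,
        "end": starts + lengths,
        "count": rng.integers(1, 20, size=n_records),
    })


def _write_fasta(reference: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_gff3(genes: pd.DataFrame, tes: pd.DataFrame, path: Path) -> None:
    type_of = {"gene": "gene", "TE": "transposable_element"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        both = pd.concat([genes, tes], ignore_index=True)
        both = both.sort_values(["chrom", "start"])
        for row in both.itertuples():
            fh.write("\t".join([
                row.chrom, "dmrscan_sim", type_of[row.kind],
                str(int(row.start) + 1), str(int(row.end)), ".",
                row.strand, ".", f"ID={row.id}",
            ]) + "\n")


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict:
    """Write the complete study to disk; returns the run manifest."""
    from .methylome import write_methylation_calls
    from .sirna import write_clusters_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = study.spec
    paths = {}

    _write_fasta(study.reference, outdir / "reference.fa")
    paths["reference"] = "reference.fa"
    _write_gff3(study.genes, study.tes, outdir / "annotation.gff3")
    paths["annotation"] = "annotation.gff3"

    methylomes = {}
    for condition in spec.conditions:
        for rep in range(1, spec.n_replicates + 1):
            table = simulate_methylome(study, condition, rep)
            name = f"methylome_{condition}_rep{rep}.tsv"
            write_methylation_calls(table, outdir / name)
            methylomes[table.sample] = name
    paths["methylomes"] = methylomes

    clusters, degs, go_map = simulate_sirna_and_deg(study)
    write_clusters_bed(clusters, outdir / "sirna_clusters.bed",
                       outdir / "sirna_abundance.tsv",
                       ["rpm_immature", "rpm_ripe"])
    paths["sirna_clusters"] = "sirna_clusters.bed"
    paths["sirna_abundance"] = "sirna_abundance.tsv"
    degs.drop(columns=["truth_class", "truth_hypo_linked"]).to_csv(
        outdir / "deg_table.tsv", sep="\t", index=False, float_format="%.6g")
    paths["deg_table"] = "deg_table.tsv"
    go_map.to_csv(outdir / "go_map.tsv", sep="\t", index=False)
    paths["go_map"] = "go_map.tsv"

    study.planted.to_csv(outdir / "truth_planted_dmrs.tsv", sep="\t", index=False)
    degs[["gene", "truth_class", "truth_hypo_linked"]].to_csv(
        outdir / "truth_degs.tsv", sep="\t", index=False)
    clusters[["name", "colocated"]].to_csv(
        outdir / "truth_clusters.tsv", sep="\t", index=False)
    paths["truth"] = {
        "planted_dmrs": "truth_planted_dmrs.tsv",
        "degs": "truth_degs.tsv",
        "clusters": "truth_clusters.tsv",
    }

    manifest = {"spec": _spec_dict(spec), "paths": paths}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def _spec_dict(spec: SimulationSpec) -> dict:
    d = asdict(spec)
    d["dmr_plan"] = [asdict(p) if isinstance(p, PlantedDMR) else p for p in spec.dmr_plan]
    return d
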
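"""End-to-end orchestration: detect -> conservation -> similarity ->
hybridize -> stats, with deterministic seeded outputs.

Given a GTF, a genome FASTA and a conserved-element BED (or a synthetic
cohort emitted by :mod:`mxefold.simulate`), ``run_all`` produces the
cluster table, the conservation and similarity tables, the ΔΔG table,
docker-site BED records and a report with one row per statistical
comparison. Re-running with an identical config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .duplex import PairClass, cluster_hybridization_scan, docker_site_map
from .energies import EnergyParams
from .genome import GeneModelSet, IntervalSet, SequenceStore, read_gene_models
from .graph import MxeCluster, find_all_clusters
from .similarity import (
    AlignScoring,
    build_intron_pool,
    consecutive_pair_table,
    conservation_table,
)
from .stats import (
    TestResult,
    mann_whitney_one_sided,
    pearson_r_t_test,
    wilcoxon_signed_rank_one_sided,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    gtf: str = ""
    fasta: str = ""
    bed: str = ""
    outdir: str = "mxefold_out"
    seed: int = 1
    control: str = "shuffle"  # or "length_matched"
    engine: str = "builtin"
    ddg_threshold: float = 30.0  # kcal/mol discard bound on |ΔΔG|
    max_align_len: int = 10_000
    strict_mxe: bool = False
    n_controls: int = 1
    exclude_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.ddg_threshold <= 0 or self.max_align_len <= 0:
            raise ValueError("threshold and length cap must be positive")


def clusters_frame(clusters: list[MxeCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append(
            dict(
                cluster_id=c.id, gene_id=c.gene_id, chrom=c.chrom,
                strand=c.strand, n=c.n,
                flank_left=f"{c.flank_left_exon.start}-{c.flank_left_exon.end}",
                variable_exons=",".join(
                    f"{e.start}-{e.end}" for e in c.variable_exons
                ),
                flank_right=(
                    f"{c.flank_right_exon.start}-{c.flank_right_exon.end}"
                ),
                introns=",".join(f"{i.start}-{i.end}" for i in c.introns),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "gene_id", "chrom", "strand", "n",
                 "flank_left", "variable_exons", "flank_right", "introns"],
    )


def ddg_frame(rows) -> pd.DataFrame:
    out = []
    for r in rows:
        out.append(
            dict(
                cluster_id=r.cluster_id, gene_id=r.gene_id,
                pair_class=r.pair_class.value, i=r.i, j=r.j,
                dG=r.result.dG, dG0=r.result.dG0, ddG=r.result.ddG,
                discarded=int(r.result.discarded),
                sites_x=";".join(f"{iv.chrom}:{iv.start}-{iv.end}"
                                 for iv in r.sites_x_genomic),
                sites_y=";".join(f"{iv.chrom}:{iv.start}-{iv.end}"
                                 for iv in r.sites_y_genomic),
            )
        )
    return pd.DataFrame(
        out,
        columns=["cluster_id", "gene_id", "pair_class", "i", "j",
                 "dG", "dG0", "ddG", "discarded", "sites_x", "sites_y"],
    )


def _report_row(name: str, res: TestResult | None, test: str) -> dict:
    if res is None:
        return dict(comparison=name, test=test, direction="NA",
                    n=0, statistic="NA", p_one_sided="NA")
    return dict(comparison=name, test=test, direction=res.direction,
                n=res.n, statistic=f"{res.statistic:.6g}",
                p_one_sided=f"{res.p_one_sided:.6g}")


def build_report(
    cons: pd.DataFrame, sim: pd.DataFrame, ddg: pd.DataFrame
) -> pd.DataFrame:
    """One row per comparison: conservation (MXE > control, Mann-Whitney),
    Δσ > 0 (Wilcoxon), ΔΔG < 0 per pair class (Wilcoxon, discarded rows
    excluded), exon-intron similarity correlation (Pearson)."""
    rows = []

    res = None
    if len(cons):
        a = cons.loc[cons.role == "mxe_flanking", "fraction"].to_numpy()
        b = cons.loc[cons.role == "control", "fraction"].to_numpy()
        if a.size and b.size:
            res = mann_whitney_one_sided(list(a), list(b), "greater")
    rows.append(_report_row("conservation_mxe_vs_control", res, "mann_whitney"))

    res = None
    if len(sim):
        res = wilcoxon_signed_rank_one_sided(
            list(sim["delta_sigma"].dropna()), "greater"
        )
    rows.append(_report_row("delta_sigma_gt_zero", res, "wilcoxon"))

    for pc in (PairClass.L_to_i, PairClass.i_to_j, PairClass.j_to_R):
        res = None
        if len(ddg):
            vals = ddg.loc[
                (ddg.pair_class == pc.value) & (ddg.discarded == 0), "ddG"
            ].to_numpy()
            if vals.size:
                res = wilcoxon_signed_rank_one_sided(list(vals), "less")
        rows.append(_report_row(f"ddg_{pc.value}_lt_zero", res, "wilcoxon"))

    res = None
    if len(sim):
        sub = sim.dropna(subset=["sigma_exons", "sigma_introns"])
        if len(sub) >= 3 and sub["sigma_exons"].std() > 0 and (
            sub["sigma_introns"].std() > 0
        ):
            res = pearson_r_t_test(
                list(sub["sigma_exons"]), list(sub["sigma_introns"]), "greater"
            )
    rows.append(_report_row("exon_intron_similarity_corr", res, "pearson_t"))

    return pd.DataFrame(
        rows,
        columns=["comparison", "test", "direction", "n", "statistic",
                 "p_one_sided"],
    )


def run_all_from_objects(
    models: GeneModelSet,
    store: SequenceStore,
    elems: IntervalSet,
    cfg: RunConfig,
) -> dict[str, pd.DataFrame]:
    """The full analysis on in-memory inputs; returns all tables."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_cons, rng_sim, rng_ddg = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    params = EnergyParams()
    sc = AlignScoring()

    clusters = find_all_clusters(models, strict=cfg.strict_mxe)
    log.info("called %d MXE clusters", len(clusters))

    cons = conservation_table(clusters, models, elems, rng_cons)
    pool = build_intron_pool(models, store, cfg.max_align_len)
    sim = consecutive_pair_table(
        clusters, store, pool, rng_sim, sc=sc, max_len=cfg.max_align_len,
        exclude_genes=set(cfg.exclude_genes) or None,
    )

    scan_rows = []
    ddg_pool = pool if cfg.control == "length_matched" else None
    for cluster in clusters:
        scan_rows.extend(
            cluster_hybridization_scan(
                cluster, elems, store, params=params, rng=rng_ddg,
                control=cfg.control, threshold=cfg.ddg_threshold,
                pool=ddg_pool, n_controls=cfg.n_controls,
                max_len=cfg.max_align_len,
            )
        )
    ddg = ddg_frame(scan_rows)
    sites = docker_site_map(scan_rows)
    sites_df = pd.DataFrame(
        sites, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    report = build_report(cons, sim, ddg)
    return dict(
        clusters=clusters_frame(clusters), cons=cons, sim=sim, ddg=ddg,
        docker_sites=sites_df, report=report,
    )


def run_all(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Read inputs from cfg paths, run everything, write the output
    directory (TSV tables, docker-site BED, run.log)."""
    for label in ("gtf", "fasta", "bed"):
        path = getattr(cfg, label)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing {label} input: {path!r}")
    models = read_gene_models(cfg.gtf)
    store = SequenceStore.from_fasta(cfg.fasta)
    elems = IntervalSet.from_bed(cfg.bed)
    tables = run_all_from_objects(models, store, elems, cfg)
    write_outputs(tables, cfg)
    return tables


def write_outputs(tables: dict[str, pd.DataFrame], cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("clusters", "cons", "sim", "ddg", "report"):
        tables[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                            float_format="%.6g")
    tables["docker_sites"].to_csv(
        outdir / "docker_sites.bed", sep="\t", index=False, header=False
    )
    with open(outdir / "run.log", "w") as fh:
        fh.write("mxefold run\n")
        for key, value in asdict(cfg).items():
            fh.write(f"{key} = {value}\n")
    return outdir


def clusters_bed12(clusters: list[MxeCluster]) -> list[str]:
    """BED12 lines for genome-browser viewing: one record per cluster
    spanning flank to flank, with the flanking and variable exons as
    blocks."""
    lines = []
    for c in clusters:
        exons = sorted(
            [c.flank_left_exon, c.flank_right_exon, *c.variable_exons],
            key=lambda e: e.start,
        )
        start, end = exons[0].start, exons[-1].end
        sizes = ",".join(str(len(e)) for e in exons)
        offsets = ",".join(str(e.start - start) for e in exons)
        lines.append(
            "\t".join(map(str, [
                c.chrom, start, end, c.id, c.n, c.strand, start, end,
                "0,0,0", len(exons), sizes, offsets,
            ]))
        )
    return lines
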
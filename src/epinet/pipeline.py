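"""End-to-end orchestration of the epigenetic-network analysis.

Stage order mirrors the study: differential methylation calls → weighted
methylation network (WMPN) → seed subnetwork (TMSN) → topology + global and
local nulls → chromatin peak mapping → weighted chromatin network (WCPN) →
chromatin subnetwork (TCSN, the WCPN induced on the TMSN gene set) →
topology + nulls → dense modules on both giant components → interplay test
→ methylation-expression regression. Every intermediate is written to the
output directory and the summary report is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from . import chromatin, diffmeth, io_formats as io, methexpr, modules as mod
from . import network as netmod, nulls, synthetic
from .types import CASE

logger = logging.getLogger(__name__)

STAGE_NAMES = (
    "data", "diff", "wmpn_nulls", "tmsn_local", "wcpn_nulls", "tcsn_local",
)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one analysis run.

    Either ``synthetic`` holds a :class:`SyntheticConfig` (everything is
    generated) or ``paths`` names the on-disk inputs: ``sif``,
    ``methylation``, ``methylation_groups``, ``expression``,
    ``expression_groups``, ``tss`` and ``peaks`` (mark name -> BED path).
    """

    synthetic: synthetic.SyntheticConfig | None = None
    paths: dict | None = None
    fdr: float = 0.05
    n_perm: int = 200
    r_cut: float = 0.8
    alpha: float = 0.05
    flank: int = 2000
    B: int = 1000
    swap_fraction: float = 0.5
    min_module_size: int = 3
    min_overlap: int = 3
    interplay_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and self.paths is None:
            raise ValueError("config needs either a synthetic block or paths")
        for name, lo, hi in (
            ("fdr", 0.0, 1.0), ("r_cut", 0.0, 1.0), ("alpha", 0.0, 1.0),
            ("swap_fraction", 0.0, 1.0), ("interplay_alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.B < 1 or self.n_perm < 20 or self.flank < 0:
            raise ValueError("invalid B, n_perm or flank")
        if self.paths is not None:
            required = {"sif", "methylation", "methylation_groups",
                        "expression", "expression_groups", "tss", "peaks"}
            missing = required - set(self.paths)
            if missing:
                raise ValueError(f"paths block missing {sorted(missing)}")
            flat = [v for k, v in self.paths.items() if k != "peaks"]
            flat += list(self.paths["peaks"].values())
            for p in flat:
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = synthetic.SyntheticConfig(**syn)
        return cls(synthetic=syn, **raw)


def _stage_seeds(rng_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from the top-level seed."""
    ss = np.random.SeedSequence(rng_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.synthetic is not None:
        cfg = dataclasses.replace(config.synthetic, rng_seed=config.synthetic.rng_seed)
        data = synthetic.generate_dataset(cfg)
        data.save(outdir / "data")
        return (data.interactome, data.methylation, data.expression,
                data.tss, data.peaks_by_mark)
    p = config.paths
    interactome = io.read_sif(p["sif"])
    meth = io.read_matrix(p["methylation"], p["methylation_groups"])
    expr = io.read_matrix(p["expression"], p["expression_groups"])
    tss = io.read_tss(p["tss"])
    peaks = {mark: io.read_bed(path) for mark, path in p["peaks"].items()}
    return interactome, meth, expr, tss, peaks


def _null_table(dists: dict) -> dict:
    return {
        name: {
            "observed": d.observed,
            "null_mean": float(np.nanmean(d.values)),
            "tail": d.tail,
            "p": d.p,
        }
        for name, d in dists.items()
    }


def _module_table(mset) -> list[dict]:
    return [
        {"module_id": m.module_id, "size": m.size, "score": round(m.score, 6),
         "genes": sorted(m.genes)}
        for m in mset
    ]


def run(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns (and writes) the summary report."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.rng_seed)
    report: dict = {"config": {
        k: v for k, v in dataclasses.asdict(config).items() if k != "synthetic"
    }}
    if config.synthetic is not None:
        report["config"]["synthetic"] = dataclasses.asdict(config.synthetic)

    logger.info("stage data: loading inputs")
    interactome, meth, expr, tss, peaks = _load_inputs(config, outdir)
    report["background"] = {
        "genes": len(interactome.genes), "interactions": len(interactome)
    }

    # ---- differential methylation
    logger.info("stage diff: SAM-style permutation test")
    diff = diffmeth.sam_fdr(
        meth, n_perm=config.n_perm, fdr_cutoff=config.fdr, rng_seed=seeds[1]
    )
    diff.to_csv(outdir / "differential_methylation.tsv", sep="\t")
    seed_genes = set(diff.index[diff["called"]])
    report["differential"] = {
        "n_called": len(seed_genes),
        "s0": diff.attrs["s0"],
        "n_perm": diff.attrs["n_perm"],
        "class_counts_control": diff["class_control"].value_counts().to_dict(),
        "class_counts_case": diff["class_case"].value_counts().to_dict(),
    }
    if not seed_genes:
        report["status"] = "no differentially methylated genes at the FDR cutoff; stopping"
        io.write_report(report, outdir / "report.json")
        return report

    # ---- WMPN / TMSN
    logger.info("stage wmpn: weighting %d background edges", len(interactome))
    wmpn = netmod.weight_network(interactome, meth.values, config.r_cut, config.alpha)
    io.write_network(wmpn, outdir / "wmpn.tsv")
    tmsn = netmod.extract_seed_subnetwork(wmpn, seed_genes)
    io.write_network(tmsn, outdir / "tmsn.tsv")
    report["wmpn"] = {"nodes": wmpn.number_of_nodes(), "edges": wmpn.number_of_edges()}
    report["tmsn"] = {"nodes": tmsn.number_of_nodes(), "edges": tmsn.number_of_edges(),
                      "seeds_in_network": len(seed_genes & set(wmpn.nodes()))}
    if tmsn.number_of_nodes() == 0:
        report["status"] = "empty methylation seed subnetwork; stopping"
        io.write_report(report, outdir / "report.json")
        return report

    tmsn_summary = netmod.topology_summary(tmsn)
    report["tmsn"]["topology"] = tmsn_summary.as_dict()
    tmsn_giant = netmod.giant_component(tmsn)
    report["tmsn"]["giant"] = {
        "nodes": tmsn_giant.number_of_nodes(),
        "edges": tmsn_giant.number_of_edges(),
    }

    logger.info("stage nulls: global null on WMPN (B=%d)", config.B)
    gnull_m = nulls.global_null(
        wmpn, seed_size=len(seed_genes & set(wmpn.nodes())), B=config.B,
        rng_seed=seeds[2], observed=tmsn_summary,
    )
    report["tmsn"]["global_null"] = _null_table(gnull_m)
    if tmsn_giant.number_of_edges() >= 2:
        lnull_m = nulls.local_null(
            tmsn_giant, B=config.B, swap_fraction=config.swap_fraction,
            rng_seed=seeds[3], observed=netmod.topology_summary(tmsn_giant),
        )
        report["tmsn"]["local_null"] = _null_table(lnull_m)

    # ---- chromatin mapping / WCPN / TCSN
    logger.info("stage chromatin: mapping %d marks", len(peaks))
    chrom_matrix = chromatin.build_chromatin_matrix(peaks, tss, config.flank)
    io.write_matrix(chrom_matrix, outdir / "chromatin_matrix.tsv")
    wcpn = netmod.weight_network(
        interactome, chrom_matrix, config.r_cut, config.alpha
    )
    io.write_network(wcpn, outdir / "wcpn.tsv")
    tcsn = wcpn.subgraph(set(tmsn.nodes()) & set(wcpn.nodes())).copy()
    nx.set_node_attributes(
        tcsn, {v: (v in seed_genes) for v in tcsn}, "seed"
    )
    io.write_network(tcsn, outdir / "tcsn.tsv")
    report["wcpn"] = {"nodes": wcpn.number_of_nodes(), "edges": wcpn.number_of_edges()}
    report["tcsn"] = {"nodes": tcsn.number_of_nodes(), "edges": tcsn.number_of_edges()}

    if tcsn.number_of_nodes() > 0:
        tcsn_summary = netmod.topology_summary(tcsn)
        report["tcsn"]["topology"] = tcsn_summary.as_dict()
        gnull_c = nulls.global_null(
            wcpn, seed_size=min(tmsn.number_of_nodes(), wcpn.number_of_nodes()),
            B=config.B, rng_seed=seeds[4], observed=tcsn_summary, mode="induced",
        )
        report["tcsn"]["global_null"] = _null_table(gnull_c)
        tcsn_giant = netmod.giant_component(tcsn)
        report["tcsn"]["giant"] = {
            "nodes": tcsn_giant.number_of_nodes(),
            "edges": tcsn_giant.number_of_edges(),
        }
        if tcsn_giant.number_of_edges() >= 2:
            lnull_c = nulls.local_null(
                tcsn_giant, B=config.B, swap_fraction=config.swap_fraction,
                rng_seed=seeds[5], observed=netmod.topology_summary(tcsn_giant),
            )
            report["tcsn"]["local_null"] = _null_table(lnull_c)
    else:
        tcsn_giant = tcsn

    # ---- modules + interplay
    logger.info("stage modules: dense-module mining")
    meth_modules = mod.mcode_modules(
        tmsn_giant, min_size=config.min_module_size, source="TMSN"
    )
    chrom_modules = mod.mcode_modules(
        tcsn_giant, min_size=config.min_module_size, source="TCSN"
    )
    io.write_modules(meth_modules, outdir / "modules_methylation.tsv")
    io.write_modules(chrom_modules, outdir / "modules_chromatin.tsv")
    background = set(tmsn.nodes()) | set(tcsn.nodes())
    results = mod.interplay(
        meth_modules, chrom_modules, background,
        min_overlap=config.min_overlap, alpha=config.interplay_alpha,
    )
    _write_interplay(results, outdir / "interplay.tsv")
    report["modules"] = {
        "methylation": _module_table(meth_modules),
        "chromatin": _module_table(chrom_modules),
    }
    report["interplay"] = {
        "n_pairs": len(results),
        "n_tested": sum(r.tested for r in results),
        "background_size": len(background),
        "significant": [
            {
                "meth_module": r.meth_module, "chrom_module": r.chrom_module,
                "M": r.meth_size, "H": r.chrom_size, "overlap": r.overlap_size,
                "p_raw": r.p_raw, "p_bonferroni": r.p_bonferroni,
                "genes": sorted(r.overlap_genes),
            }
            for r in results if r.significant
        ],
    }

    # ---- methylation-expression regression
    logger.info("stage meth-expr: regression")
    pairs = methexpr.gene_level_pairs(meth, expr, group=CASE)
    if len(pairs) >= 3:
        fit = methexpr.fit_line(pairs)
        flags, n_within = methexpr.flag_within_interval(fit, pairs)
        pairs.assign(within_interval=flags).to_csv(
            outdir / "meth_expr_pairs.tsv", sep="\t", index_label="gene"
        )
        report["meth_expr"] = {
            "n_genes": fit.n,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "resid_sd": fit.resid_sd,
            "spearman_rho": fit.spearman_rho,
            "spearman_p": fit.spearman_p,
            "n_within_interval": n_within,
            "frac_within_interval": n_within / fit.n,
        }
        try:
            methexpr.plot_fit(fit, pairs, outdir / "meth_expr.png")
        except Exception:  # plotting is best-effort
            logger.exception("meth-expr plot failed")

    report["status"] = "complete"
    report["runtime_s"] = round(time.time() - t0, 2)
    io.write_report(report, outdir / "report.json")
    return report


def _write_interplay(results, path) -> None:
    """Columns mirror the published interplay table: chromatin module and
    size, methylation module and size, overlap, corrected p."""
    with open(path, "w") as fh:
        fh.write(
            "chrom_module\tchrom_size\tmeth_module\tmeth_size\toverlap\t"
            "p_raw\tp_bonferroni\tsignificant\tgenes\n"
        )
        for r in sorted(results, key=lambda r: (r.p_raw, r.meth_module)):
            bonf = "" if np.isnan(r.p_bonferroni) else f"{r.p_bonferroni:.3g}"
            fh.write(
                f"{r.chrom_module}\t{r.chrom_size}\t{r.meth_module}\t"
                f"{r.meth_size}\t{r.overlap_size}\t{r.p_raw:.3g}\t{bonf}\t"
                f"{int(r.significant)}\t{','.join(sorted(r.overlap_genes))}\n"
            )


def demo_config(rng_seed: int = 0, B: int = 200) -> PipelineConfig:
    """The bundled end-to-end demonstration on generated data: the default
    synthetic study conditions with a null-replicate count sized for a
    quick run."""
    return PipelineConfig(
        synthetic=synthetic.SyntheticConfig(rng_seed=rng_seed),
        B=B,
        rng_seed=rng_seed,
    )
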
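"""Full-pipeline orchestration: simulate/load -> DE -> inheritance -> ASE.

``run_pipeline`` executes every stage, writes each stage's table under the
output directory, and records a run manifest (seed, thresholds, input
hashes, package version) so any classification can be traced back to its
inputs — inheritance calls are threshold-sensitive, so provenance is not
optional. ``summary_report`` rebuilds the human-readable report purely from
the written tables, never from in-memory state, so regenerating it cannot
drift from what was saved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from . import ase as ase_mod
from . import inheritance as inh_mod
from .iomod import (
    CountMatrix,
    HeteroseqError,
    read_allele_counts,
    read_counts,
    read_design,
    read_results,
    truth_to_frame,
    write_design,
    write_results,
)
from .models import AllelicImbalanceModel, TrioExpressionModel
from .simulate import SimulationParams, generate_dataset, truth_confusion

logger = logging.getLogger("heteroseq")


@dataclasses.dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Exactly one of ``input_paths`` (counts/allele_counts/design TSV+YAML
    paths) or ``simulation`` (SimulationParams) must be given.
    """

    outdir: Path
    input_paths: Mapping[str, Any] | None = None
    simulation: SimulationParams | None = None
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    min_snp_reads: int = 5
    similarity_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise HeteroseqError(
                "config must provide exactly one of input paths or a simulation block"
            )
        if min(self.fc_threshold, self.fdr_threshold, self.similarity_alpha) <= 0:
            raise HeteroseqError("thresholds must be positive")
        if self.min_snp_reads < 1:
            raise HeteroseqError("min_snp_reads must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write tables + manifest under config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    truth_df = None
    if config.simulation is not None:
        params = dataclasses.replace(config.simulation, seed=config.seed)
        logger.info("simulating %d genes (seed=%d)", params.n_genes, params.seed)
        counts, allele_counts, truth, design = generate_dataset(params)
        truth_df = truth_to_frame(truth)
        counts_path = outdir / "counts.tsv"
        counts.df.rename_axis("gene_id").reset_index().to_csv(counts_path, sep="\t", index=False)
        allele_path = outdir / "allele_counts.tsv"
        write_results(allele_counts, allele_path)
        design_path = outdir / "design.yaml"
        write_design(design, design_path)
        write_results(truth_df, outdir / "truth.tsv")
    else:
        paths = dict(config.input_paths)
        counts_path = Path(paths["counts"])
        allele_path = Path(paths["allele_counts"]) if paths.get("allele_counts") else None
        design_path = Path(paths["design"])
        design = read_design(design_path)
        counts = read_counts(counts_path, design)
        allele_counts = read_allele_counts(allele_path) if allele_path else pd.DataFrame()

    # expression stages
    model = TrioExpressionModel(counts, design)
    fit = model.fit(config.fc_threshold, config.fdr_threshold)
    write_results(
        fit.size_factors.rename_axis("sample_id").reset_index(), outdir / "size_factors.tsv"
    )
    for name, tbl in fit.de_tables.items():
        write_results(tbl, outdir / f"de_{name}.tsv")
    summaries = []
    for hyb, rec in fit.inheritance.items():
        write_results(rec, outdir / f"inheritance_{hyb}.tsv")
        if hyb in fit.class_summaries:
            summaries.append(inh_mod.summary_to_frame(fit.class_summaries[hyb]))
    if summaries:
        write_results(pd.concat(summaries, ignore_index=True), outdir / "class_summary.tsv")
    if fit.reciprocal is not None:
        write_results(pd.DataFrame([fit.reciprocal]), outdir / "reciprocal_summary.tsv")

    # ASE stages, per hybrid with allele counts
    genotypes = {d.genotype for d in design}
    for hyb in ("F1a", "F1b"):
        if hyb not in genotypes or not len(allele_counts):
            continue
        ai = AllelicImbalanceModel(allele_counts, counts, design, hyb)
        if not len(ai.allele_counts):
            continue
        res = ai.fit(
            config.min_snp_reads, config.fdr_threshold, config.similarity_alpha, expression=fit
        )
        write_results(res.snp_tests, outdir / f"snp_tests_{hyb}.tsv")
        write_results(res.ase_results, outdir / f"ase_{hyb}.tsv")
        write_results(res.regulatory, outdir / f"regulatory_{hyb}.tsv")
        if len(res.volcano):
            write_results(res.volcano, outdir / f"ase_volcano_{hyb}.tsv")

    # simulation-mode accuracy tables
    if truth_df is not None:
        for hyb, rec in fit.inheritance.items():
            conf = truth_confusion(truth_df, rec)
            conf.reset_index().to_csv(outdir / f"confusion_{hyb}.tsv", sep="\t", index=False)

    manifest = {
        "package": "heteroseq",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "fdr_threshold": config.fdr_threshold,
            "min_snp_reads": config.min_snp_reads,
            "similarity_alpha": config.similarity_alpha,
        },
        "mode": "simulation" if config.simulation is not None else "files",
        "inputs": {
            "counts": _sha256(counts_path),
            "design": _sha256(design_path),
            "allele_counts": _sha256(allele_path) if allele_path and allele_path.exists() else None,
        },
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    report = summary_report(outdir)
    (outdir / "report.md").write_text(report)
    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, outdir)
    return manifest


def summary_report(outdir: Path | str) -> str:
    """Markdown report assembled only from the tables saved in ``outdir``."""
    outdir = Path(outdir)
    lines = ["# Pipeline summary report", ""]

    de_files = sorted(outdir.glob("de_*.tsv"))
    if de_files:
        lines += ["## Differentially expressed genes", "", "| contrast | DEGs | genes |", "|---|---|---|"]
        for f in de_files:
            tbl = read_results(f)
            name = f.stem.removeprefix("de_")
            lines.append(f"| {name} | {int(tbl['is_deg'].sum())} | {len(tbl)} |")
        lines.append("")

    cs = outdir / "class_summary.tsv"
    if cs.exists():
        tbl = read_results(cs)
        lines += ["## Expression-inheritance classes", ""]
        for hyb, grp in tbl.groupby("hybrid", sort=True):
            total = int(grp["count"].sum())
            lines += [f"### {hyb} ({total} divergent genes)", "", "| class | count | % |", "|---|---|---|"]
            for rec in grp.itertuples(index=False):
                lines.append(f"| {rec.klass} | {rec.count} | {rec.percentage:.2f} |")
            lines.append("")

    rs = outdir / "reciprocal_summary.tsv"
    if rs.exists():
        tbl = read_results(rs)
        if len(tbl) and pd.notna(tbl.at[0, "pct_up"]):
            r = tbl.iloc[0]
            lines += [
                "## Reciprocal-hybrid direction",
                "",
                f"{int(r['n_up'])} DEGs up ({r['pct_up']}%) and {int(r['n_down'])} down "
                f"({r['pct_down']}%) in F1a relative to F1b.",
                "",
            ]

    for hyb in ("F1a", "F1b"):
        af = outdir / f"ase_{hyb}.tsv"
        if not af.exists():
            continue
        ase_tbl = read_results(af)
        n_ase = int(ase_tbl["is_ase"].sum()) if len(ase_tbl) else 0
        lines += [f"## Allele-specific expression, {hyb}", "", f"{n_ase} ASE genes of {len(ase_tbl)} tested."]
        rf = outdir / f"regulatory_{hyb}.tsv"
        if rf.exists():
            reg = read_results(rf)
            tally = reg["category"].value_counts().to_dict()
            lines += ["", "| category | genes |", "|---|---|"]
            for k in ("CIS", "TRANS", "CONSERVED", "AMBIGUOUS"):
                if k in tally:
                    lines.append(f"| {k} | {tally[k]} |")
        lines.append("")

    for hyb in ("F1a", "F1b"):
        cf = outdir / f"confusion_{hyb}.tsv"
        if not cf.exists():
            continue
        conf = read_results(cf)
        lines += [f"## Truth-vs-call confusion, {hyb}", ""]
        cols = list(conf.columns)
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "---|" * len(cols))
        for rec in conf.itertuples(index=False):
            lines.append("| " + " | ".join(str(v) for v in rec) + " |")
        lines.append("")

    return "\n".join(lines) + "\n"
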
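"""Model/Results layer tying the pipeline stages together.

Two fitted-model entry points, in the statsmodels idiom:

``TrioExpressionModel(counts, design).fit()`` normalizes the count matrix
(median-of-ratios), estimates dispersions, runs every pairwise NB Wald
contrast, classifies expression inheritance for each hybrid and summarizes
the class shares. ``AllelicImbalanceModel(allele_counts, counts, design,
hybrid).fit()`` applies the SNP depth filter, calls gene-level ASE, and
classifies cis/trans regulatory divergence against the parental expression
proportions. Both return Results objects with the stage tables as
attributes and a ``summary()`` text table.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from . import ase as ase_mod
from . import de as de_mod
from . import inheritance as inh_mod
from .iomod import CountMatrix, HeteroseqError, SampleDesign, validate_design


def _pairwise_contrasts(genotypes: Sequence[str]) -> list[tuple[str, str]]:
    # fixed, design-independent order: hybrids as numerators where present
    preferred = [
        ("P2", "P1"),
        ("F1a", "P1"),
        ("F1a", "P2"),
        ("F1b", "P1"),
        ("F1b", "P2"),
        ("F1a", "F1b"),
    ]
    return [c for c in preferred if c[0] in genotypes and c[1] in genotypes]


class TrioExpressionModel:
    """Hybrid/parent expression model over a raw count matrix."""

    def __init__(self, counts: CountMatrix, design: Sequence[SampleDesign]):
        validate_design(design)
        known = set(counts.sample_ids)
        self.design = [d for d in design if d.sample_id in known]
        if not self.design:
            raise HeteroseqError("no design sample appears in the count matrix")
        self.counts = counts

    @classmethod
    def from_files(cls, counts_path, design_path) -> "TrioExpressionModel":
        from .iomod import read_counts, read_design

        design = read_design(design_path)
        return cls(read_counts(counts_path, design), design)

    def fit(self, fc_threshold: float = 2.0, fdr_threshold: float = 0.05) -> "TrioExpressionResults":
        size_factors = de_mod.estimate_size_factors(self.counts)
        norm = de_mod.normalize(self.counts, size_factors)
        dispersions = de_mod.estimate_dispersion(norm, self.design)
        genotypes = {d.genotype for d in self.design}
        de_tables: dict[str, pd.DataFrame] = {}
        for contrast in _pairwise_contrasts(genotypes):
            tbl = de_mod.run_contrast(
                norm, self.design, contrast, dispersions, fc_threshold, fdr_threshold
            )
            de_tables[f"{contrast[0]}_vs_{contrast[1]}"] = tbl

        inheritance: dict[str, pd.DataFrame] = {}
        class_summaries: dict[str, dict] = {}
        for hyb in ("F1a", "F1b"):
            if hyb not in genotypes or not {"P1", "P2"} <= genotypes:
                continue
            # union of the two hybrid-vs-parent DEG sets
            f1 = de_tables[f"{hyb}_vs_P1"].set_index("gene_id")["is_deg"]
            f2 = de_tables[f"{hyb}_vs_P2"].set_index("gene_id")["is_deg"]
            flags = f1 | f2
            rec = inh_mod.classify_hybrid(norm, self.design, hyb, flags)
            inheritance[hyb] = rec
            if rec["in_summary"].any():
                class_summaries[hyb] = inh_mod.summarize_classes(rec)

        reciprocal = None
        if "F1a_vs_F1b" in de_tables:
            reciprocal = inh_mod.reciprocal_direction_summary(de_tables["F1a_vs_F1b"])

        return TrioExpressionResults(
            model=self,
            size_factors=size_factors,
            norm_counts=norm,
            dispersions=dispersions,
            de_tables=de_tables,
            inheritance=inheritance,
            class_summaries=class_summaries,
            reciprocal=reciprocal,
            fc_threshold=fc_threshold,
            fdr_threshold=fdr_threshold,
        )


@dataclasses.dataclass
class TrioExpressionResults:
    """Fitted trio-expression pipeline: normalized data, DE and inheritance."""

    model: TrioExpressionModel
    size_factors: pd.Series
    norm_counts: pd.DataFrame
    dispersions: pd.Series
    de_tables: dict[str, pd.DataFrame]
    inheritance: dict[str, pd.DataFrame]
    class_summaries: dict[str, dict]
    reciprocal: dict | None
    fc_threshold: float
    fdr_threshold: float

    def deg_counts(self) -> dict[str, int]:
        return {name: int(tbl["is_deg"].sum()) for name, tbl in self.de_tables.items()}

    def hybrid_parent_deg_flags(self, hybrid: str) -> pd.Series:
        f1 = self.de_tables[f"{hybrid}_vs_P1"].set_index("gene_id")["is_deg"]
        f2 = self.de_tables[f"{hybrid}_vs_P2"].set_index("gene_id")["is_deg"]
        return f1 | f2

    def parent_deg_flags(self) -> pd.Series:
        return self.de_tables["P2_vs_P1"].set_index("gene_id")["is_deg"]

    def summary(self) -> str:
        lines = ["Trio expression analysis", "=" * 24, ""]
        lines.append(f"genes: {self.model.counts.shape[0]}  samples: {self.model.counts.shape[1]}")
        lines.append(
            f"DEG thresholds: fold change > {self.fc_threshold:g}, FDR < {self.fdr_threshold:g}"
        )
        lines.append("")
        lines.append("DEGs per contrast:")
        for name, n in self.deg_counts().items():
            lines.append(f"  {name:12s} {n:6d}")
        for hyb, summ in self.class_summaries.items():
            lines.append("")
            lines.append(f"Inheritance classes, {hyb} (n={summ['total']} divergent genes):")
            for k in inh_mod.EIGHT_CLASSES:
                lines.append(f"  {k:14s} {summ['counts'][k]:6d}  {summ['percentages'][k]:6.2f}%")
            lines.append(f"  dominance-up share: {summ['dominance_up_share']:.2f}%")
            lines.append(
                f"  dominance-up-or-higher share: {summ['dominance_up_or_higher_share']:.2f}%"
            )
        if self.reciprocal and self.reciprocal["pct_up"] is not None:
            r = self.reciprocal
            lines.append("")
            lines.append(
                f"Reciprocal-hybrid DEGs: {r['n_up']} up ({r['pct_up']}%), "
                f"{r['n_down']} down ({r['pct_down']}%) in F1a vs F1b"
            )
        return "\n".join(lines)


class AllelicImbalanceModel:
    """ASE + cis/trans model over SNP-level hybrid allele counts."""

    def __init__(
        self,
        allele_counts: pd.DataFrame,
        counts: CountMatrix,
        design: Sequence[SampleDesign],
        hybrid: str = "F1a",
    ):
        if hybrid not in ("F1a", "F1b"):
            raise HeteroseqError(f"hybrid must be F1a or F1b, got {hybrid!r}")
        self.hybrid = hybrid
        self.design = list(design)
        self.counts = counts
        geno = {d.sample_id: d.genotype for d in design}
        self.allele_counts = allele_counts[
            allele_counts["sample_id"].map(geno).eq(hybrid)
        ].reset_index(drop=True)

    def fit(
        self,
        min_reads: int = 5,
        fdr_threshold: float = 0.05,
        similarity_alpha: float = 0.05,
        expression: TrioExpressionResults | None = None,
    ) -> "AllelicImbalanceResults":
        if expression is None:
            expression = TrioExpressionModel(self.counts, self.design).fit()
        filtered = ase_mod.filter_snps(self.allele_counts, min_reads, self.design)
        snp_tests = ase_mod.run_snp_tests(filtered)
        ase_results = ase_mod.call_ase(snp_tests, fdr_threshold)
        props = ase_mod.parental_proportions(
            expression.norm_counts, self.design, expression.dispersions
        )
        regulatory = ase_mod.classify_regulation_table(
            ase_results, props, expression.parent_deg_flags(), similarity_alpha
        )
        volcano = ase_mod.ase_volcano_table(ase_results) if len(ase_results) else pd.DataFrame()
        return AllelicImbalanceResults(
            model=self,
            snp_tests=snp_tests,
            ase_results=ase_results,
            regulatory=regulatory,
            volcano=volcano,
            expression=expression,
        )


@dataclasses.dataclass
class AllelicImbalanceResults:
    """Fitted ASE pipeline for one hybrid."""

    model: AllelicImbalanceModel
    snp_tests: pd.DataFrame
    ase_results: pd.DataFrame
    regulatory: pd.DataFrame
    volcano: pd.DataFrame
    expression: TrioExpressionResults

    def n_ase(self) -> int:
        return int(self.ase_results["is_ase"].sum()) if len(self.ase_results) else 0

    def regulatory_tally(self) -> dict[str, int]:
        if not len(self.regulatory):
            return {}
        return self.regulatory["category"].value_counts().to_dict()

    def summary(self) -> str:
        lines = [f"Allele-specific expression, hybrid {self.model.hybrid}", "=" * 40, ""]
        lines.append(f"SNPs passing depth filter: {len(self.snp_tests)}")
        lines.append(f"genes tested: {len(self.ase_results)}")
        lines.append(f"ASE genes (FDR<0.05, direction-consistent): {self.n_ase()}")
        tally = self.regulatory_tally()
        if tally:
            lines.append("regulatory categories:")
            for k in ("CIS", "TRANS", "CONSERVED", "AMBIGUOUS"):
                if k in tally:
                    lines.append(f"  {k:10s} {tally[k]:6d}")
        return "\n".join(lines)
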
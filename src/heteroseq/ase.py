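"""Allele-specific expression calling and cis/trans regulatory classification.

In an F1 hybrid, reads overlapping parent-distinguishing SNPs can be
assigned to the maternal (P1) or paternal (P2) allele. A gene shows
allele-specific expression (ASE) when the two alleles' read counts deviate
significantly from the 1:1 expectation. Three filters are applied:

1. every SNP must be supported by at least ``min_reads`` (default 5) reads
   after pooling the hybrid replicates;
2. the pooled per-gene allele counts must deviate significantly from 0.5
   (two-sided exact binomial, BH FDR < 0.05 across genes);
3. SNPs within one gene must not be significantly biased in opposite
   directions (unadjusted p < 0.05 per SNP — a consistency filter, not an
   inference).

A biased gene whose hybrid allelic ratio is statistically indistinguishable
from the parents' relative expression is cis-regulated (the causal variant
travels with the allele); a gene whose parents differ but whose hybrid
alleles are balanced is trans-regulated (a diffusible factor acts on both
alleles equally).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .iomod import HeteroseqError, SampleDesign

SNP_TEST_COLUMNS = [
    "gene_id", "snp_id", "pooled_p1", "pooled_p2", "prop_p1", "pvalue", "direction", "passed_depth",
]
ASE_COLUMNS = [
    "gene_id", "n_snps_used", "gene_p1", "gene_p2", "gene_prop_p1",
    "pvalue", "fdr", "direction_consistent", "is_ase", "bias",
]
REGULATORY_COLUMNS = [
    "gene_id", "parental_prop_p1", "hybrid_prop_p1", "category", "similarity_p",
]


def exact_binomial_p(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value for k successes out of n."""
    return float(stats.binomtest(k, n, p, alternative="two-sided").pvalue)


def filter_snps(
    records: pd.DataFrame,
    min_reads: int = 5,
    design: Sequence[SampleDesign] | None = None,
) -> pd.DataFrame:
    """Pool SNP counts across hybrid replicates and apply the depth filter.

    Input rows must all come from a single hybrid genotype; if a design is
    supplied this is verified. Returns one row per (gene, SNP) with counts
    summed over replicates, keeping SNPs whose pooled total is at least
    ``min_reads`` ("at least five reads" at the default).
    """
    if design is not None and len(records):
        geno = {d.sample_id: d.genotype for d in design}
        present = {geno.get(s) for s in records["sample_id"].unique()}
        unknown = {s for s in records["sample_id"].unique() if s not in geno}
        if unknown:
            raise HeteroseqError(f"allele-count samples not in design: {sorted(unknown)}")
        if len(present) > 1:
            raise HeteroseqError(f"allele counts mix hybrid genotypes: {sorted(present)}")
        if not present <= {"F1a", "F1b"}:
            raise HeteroseqError(f"allele counts must come from a hybrid, got {sorted(present)}")
    if not len(records):
        return records.drop(columns=["sample_id"], errors="ignore").head(0)
    pooled = (
        records.groupby(["gene_id", "snp_id", "chrom", "pos"], as_index=False, sort=True)[
            ["count_p1", "count_p2"]
        ].sum()
    )
    total = pooled["count_p1"] + pooled["count_p2"]
    return pooled[total >= min_reads].reset_index(drop=True)


def snp_binomial_test(count_p1: int, count_p2: int, alpha: float = 0.05) -> tuple[float, float, str]:
    """Exact binomial deviation test for one SNP against a 1:1 ratio.

    Returns (prop_p1, two-sided p-value, direction). Direction is
    P1_BIASED/P2_BIASED only when p < alpha, else NONE.
    """
    n = count_p1 + count_p2
    if n < 1:
        raise HeteroseqError("cannot test a SNP with zero reads on both alleles")
    prop = count_p1 / n
    p = exact_binomial_p(count_p1, n, 0.5)
    if p < alpha and prop > 0.5:
        direction = "P1_BIASED"
    elif p < alpha and prop < 0.5:
        direction = "P2_BIASED"
    else:
        direction = "NONE"
    return prop, p, direction


def run_snp_tests(filtered: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP deviation tests on depth-filtered, replicate-pooled counts."""
    rows = []
    for rec in filtered.itertuples(index=False):
        prop, p, direction = snp_binomial_test(int(rec.count_p1), int(rec.count_p2), alpha)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "snp_id": rec.snp_id,
                "pooled_p1": int(rec.count_p1),
                "pooled_p2": int(rec.count_p2),
                "prop_p1": prop,
                "pvalue": p,
                "direction": direction,
                "passed_depth": True,
            }
        )
    return pd.DataFrame(rows, columns=SNP_TEST_COLUMNS)


def call_ase(
    snp_results: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-level ASE calls from per-SNP tests.

    Counts are summed over the gene's passing SNPs; the gene p-value is the
    two-sided exact binomial on the pooled counts vs 0.5; BH is applied
    across genes. A gene is ASE iff FDR < ``fdr_threshold`` AND its
    significant SNPs do not point in opposite directions.
    """
    if not len(snp_results):
        return pd.DataFrame(columns=ASE_COLUMNS)
    rows = []
    for gene_id, grp in snp_results.groupby("gene_id", sort=True):
        dirs = set(grp["direction"]) - {"NONE"}
        consistent = not ({"P1_BIASED", "P2_BIASED"} <= dirs)
        g1 = int(grp["pooled_p1"].sum())
        g2 = int(grp["pooled_p2"].sum())
        p = exact_binomial_p(g1, g1 + g2, 0.5)
        rows.append(
            {
                "gene_id": gene_id,
                "n_snps_used": len(grp),
                "gene_p1": g1,
                "gene_p2": g2,
                "gene_prop_p1": g1 / (g1 + g2),
                "pvalue": p,
                "direction_consistent": consistent,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["is_ase"] = (out["fdr"] < fdr_threshold) & out["direction_consistent"]
    out["bias"] = np.where(
        ~out["is_ase"], "NONE", np.where(out["gene_prop_p1"] > 0.5, "P1_BIASED", "P2_BIASED")
    )
    return out[ASE_COLUMNS]


def parental_proportion(
    norm_counts: pd.DataFrame, design: Sequence[SampleDesign], gene_id: str
) -> tuple[float, bool]:
    """P1 inbred's share of total parental normalized expression.

    The inbreds are homozygous, so whole-gene expression stands in for
    allele expression. Returns (proportion, degenerate_flag); the flag is
    set, and 0.5 returned, when both parents have zero mean.
    """
    props = parental_proportions(norm_counts, design)
    if gene_id not in props.index:
        raise HeteroseqError(f"gene {gene_id!r} absent from count matrix")
    row = props.loc[gene_id]
    return float(row["parental_prop_p1"]), bool(row["degenerate"])


def parental_proportions(
    norm_counts: pd.DataFrame,
    design: Sequence[SampleDesign],
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Vectorised parental P1-share for every gene.

    When per-gene NB dispersions are supplied, the delta-method variance of
    the parental log-odds log(mean_P1/mean_P2) is also returned
    (``logodds_var`` = sum over parents of (1/m_i + alpha)/n_i), so the
    cis-similarity test can propagate the parents' replicate noise instead
    of treating their proportion as exact.
    """
    from .de import genotype_means

    means = genotype_means(norm_counts, design)
    for g in ("P1", "P2"):
        if g not in means.columns:
            raise HeteroseqError(f"parent {g!r} missing from design")
    m1 = means["P1"].to_numpy(dtype=float)
    m2 = means["P2"].to_numpy(dtype=float)
    tot = m1 + m2
    degenerate = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(degenerate, 0.5, m1 / np.where(tot == 0, 1.0, tot))
    out = pd.DataFrame({"parental_prop_p1": prop, "degenerate": degenerate}, index=means.index)
    if dispersions is not None:
        n1 = sum(1 for d in design if d.genotype == "P1" and d.sample_id in norm_counts.columns)
        n2 = sum(1 for d in design if d.genotype == "P2" and d.sample_id in norm_counts.columns)
        alpha = dispersions.loc[means.index].to_numpy(dtype=float)
        f1 = np.where(m1 == 0, 0.5, m1)
        f2 = np.where(m2 == 0, 0.5, m2)
        out["logodds_var"] = (1.0 / f1 + alpha) / max(n1, 1) + (1.0 / f2 + alpha) / max(n2, 1)
    return out


def similarity_test(
    gene_p1: int, gene_p2: int, parental_prop_p1: float, parental_logodds_var: float | None = None
) -> float:
    """Two-sided p-value for hybrid allelic ratio == parental proportion.

    With ``parental_logodds_var`` (the delta-method variance of the
    parental log-odds, from replicate noise) the test is a Wald z on the
    difference of log-odds, with variance 1/(g1+0.5) + 1/(g2+0.5) (Haldane
    correction) plus the parental term — both sides of the comparison are
    estimates, and ignoring the parental noise would reject true
    cis-regulated genes far above the nominal rate. Without it the test
    degrades to the exact binomial against a fixed proportion.
    """
    p0 = min(max(float(parental_prop_p1), 1e-12), 1 - 1e-12)
    if parental_logodds_var is None:
        return exact_binomial_p(gene_p1, gene_p1 + gene_p2, p0)
    d = np.log((gene_p1 + 0.5) / (gene_p2 + 0.5)) - np.log(p0 / (1 - p0))
    var = 1.0 / (gene_p1 + 0.5) + 1.0 / (gene_p2 + 0.5) + float(parental_logodds_var)
    z = d / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def classify_regulation(
    ase_row: Mapping,
    parental_prop_p1: float,
    parent_deg: bool,
    similarity_alpha: float = 0.05,
    parental_logodds_var: float | None = None,
) -> tuple[str, float]:
    """Cis/trans call for one gene.

    CIS: allelically biased in the hybrid AND the hybrid ratio matches the
    parental proportion (similarity test not rejected at
    ``similarity_alpha``). TRANS: not biased, but the parents differ
    (parent_deg). CONSERVED: neither. AMBIGUOUS: biased but deviating from
    the parental proportion (unresolved cis+trans mixtures).
    """
    g1, g2 = int(ase_row["gene_p1"]), int(ase_row["gene_p2"])
    similarity_p = similarity_test(g1, g2, parental_prop_p1, parental_logodds_var)
    if ase_row["is_ase"]:
        category = "CIS" if similarity_p >= similarity_alpha else "AMBIGUOUS"
    else:
        category = "TRANS" if parent_deg else "CONSERVED"
    return category, similarity_p


def classify_regulation_table(
    ase_results: pd.DataFrame,
    parental_props: pd.DataFrame,
    parent_deg_flags: Mapping[str, bool] | pd.Series,
    similarity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Cis/trans calls for every ASE-tested gene."""
    flags = pd.Series(parent_deg_flags)
    has_var = "logodds_var" in parental_props.columns
    rows = []
    for rec in ase_results.to_dict("records"):
        gid = rec["gene_id"]
        if gid not in parental_props.index:
            raise HeteroseqError(f"gene {gid!r} has allele counts but no expression counts")
        prop = float(parental_props.loc[gid, "parental_prop_p1"])
        lov = float(parental_props.loc[gid, "logodds_var"]) if has_var else None
        category, sim_p = classify_regulation(
            rec, prop, bool(flags.get(gid, False)), similarity_alpha, lov
        )
        rows.append(
            {
                "gene_id": gid,
                "parental_prop_p1": prop,
                "hybrid_prop_p1": rec["gene_prop_p1"],
                "category": category,
                "similarity_p": sim_p,
            }
        )
    return pd.DataFrame(rows, columns=REGULATORY_COLUMNS)


def ase_volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: per-gene allelic log-ratio vs -log10 FDR.

    Zero counts on either allele are handled with a +0.5 Haldane correction
    applied to both alleles before the ratio.
    """
    if not len(results):
        raise HeteroseqError("no ASE results to tabulate")
    g1 = results["gene_p1"].to_numpy(dtype=float)
    g2 = results["gene_p2"].to_numpy(dtype=float)
    zero = (g1 == 0) | (g2 == 0)
    num = np.where(zero, g1 + 0.5, g1)
    den = np.where(zero, g2 + 0.5, g2)
    with np.errstate(divide="ignore"):
        neglog_fdr = -np.log10(results["fdr"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "gene_id": results["gene_id"],
            "log2_allele_ratio": np.log2(num / den),
            "neg_log10_fdr": neglog_fdr,
            "bias": results["bias"],
        }
    ).reset_index(drop=True)
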
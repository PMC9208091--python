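"""Synthetic hybrid/parent RNA-seq datasets with known ground truth.

The generator emulates the four-genotype germinating-embryo design: two
inbred parents (P1, P2) and their reciprocal F1 hybrids (F1a, F1b), three
biological replicates each. Every gene is given a true inheritance class;
noise-free genotype means are constructed so the log2 hybrid/parent ratios
sit at +-``log2_effect`` (default 2.0, i.e. 4-fold — a 1.0-log2 margin
beyond the unit classification thresholds) or at 0. Counts are negative
binomial with mean m and dispersion alpha (variance m + alpha*m^2), the
standard RNA-seq overdispersion form. Per-sample library-size multipliers
drawn log-uniform make size-factor estimation non-trivial.

Hybrid allele counts are binomial: per SNP per hybrid replicate, a Poisson
total depth is split between the P1 and P2 alleles with a probability set
by the gene's regulatory architecture — the parental mean proportion for
cis-regulated genes, 0.5 for trans-regulated and conserved genes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inheritance import ALL_CLASSES, EIGHT_CLASSES
from .iomod import (
    ALLELE_COLUMNS,
    CountMatrix,
    HeteroseqError,
    SampleDesign,
    SyntheticTruth,
)

#: noise-free (log2(F1/P1), log2(F1/P2)) offsets per class, in units of the
#: effect size e = log2_effect
_CLASS_OFFSETS: dict[str, tuple[float, float]] = {
    "ADD_P2_GT_P1": (1.0, -1.0),
    "ADD_P1_GT_P2": (-1.0, 1.0),
    "P2_DOM_UP": (1.0, 0.0),
    "P2_DOM_DOWN": (-1.0, 0.0),
    "P1_DOM_UP": (0.0, 1.0),
    "P1_DOM_DOWN": (0.0, -1.0),
    "TRANS_UP": (1.0, 1.0),
    "TRANS_DOWN": (-1.0, -1.0),
    "CONSERVED": (0.0, 0.0),
}

#: divergent-class composition observed in the motivating maize study
#: (Z58 x C72 tallies 222,160,527,67,797,229,442,357 over 2801 genes),
#: scaled to half the genes; the other half is conserved.
_STUDY_TALLIES = (222, 160, 527, 67, 797, 229, 442, 357)


def default_class_proportions() -> dict[str, float]:
    total = sum(_STUDY_TALLIES)
    props = {k: 0.5 * t / total for k, t in zip(EIGHT_CLASSES, _STUDY_TALLIES)}
    props["CONSERVED"] = 0.5
    return props


@dataclasses.dataclass
class SimulationParams:
    """Knobs for :func:`generate_dataset`; defaults mirror the study design."""

    n_genes: int = 2000
    replicates_per_genotype: int = 3
    class_proportions: Mapping[str, float] = dataclasses.field(default_factory=default_class_proportions)
    log2_effect: float = 2.0
    dispersion: float = 0.05
    base_mean_log_mean: float = 5.0
    base_mean_log_sd: float = 1.5
    snps_per_gene: int = 2
    mean_allele_depth: float = 50.0
    cis_fraction: float = 0.5
    reciprocal_fraction: float = 0.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def validate(self) -> None:
        total = float(sum(self.class_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise HeteroseqError(f"class_proportions must sum to 1 (got {total})")
        unknown = set(self.class_proportions) - set(_CLASS_OFFSETS)
        if unknown:
            raise HeteroseqError(f"unknown class label(s) in class_proportions: {sorted(unknown)}")
        if any(v < 0 for v in self.class_proportions.values()):
            raise HeteroseqError("class_proportions must be non-negative")
        if self.dispersion <= 0:
            raise HeteroseqError("dispersion must be positive")
        if self.n_genes < 1 or self.replicates_per_genotype < 1:
            raise HeteroseqError("n_genes and replicates_per_genotype must be positive")
        if self.snps_per_gene < 0 or self.mean_allele_depth <= 0:
            raise HeteroseqError("invalid allele-count parameters")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, alpha) with variance mean + alpha*mean^2; Poisson limit for tiny alpha."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-7:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def make_design(replicates_per_genotype: int = 3) -> list[SampleDesign]:
    return [
        SampleDesign(sample_id=f"{g}_r{r}", genotype=g, replicate=r)
        for g in ("P1", "P2", "F1a", "F1b")
        for r in range(1, replicates_per_genotype + 1)
    ]


def generate_dataset(
    params: SimulationParams,
) -> tuple[CountMatrix, pd.DataFrame, list[SyntheticTruth], list[SampleDesign]]:
    """Simulate (counts, allele counts, truth, design) for one run.

    Identical params (including seed) give byte-identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    gene_ids = [f"gene{str(i + 1).zfill(5)}" for i in range(n)]
    design = make_design(params.replicates_per_genotype)

    labels = sorted(params.class_proportions)
    probs = np.array([params.class_proportions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    classes = rng.choice(labels, size=n, p=probs)

    base = rng.lognormal(params.base_mean_log_mean, params.base_mean_log_sd, size=n)
    e = params.log2_effect
    a = np.array([_CLASS_OFFSETS[c][0] for c in classes]) * e  # log2(F1/P1)
    b = np.array([_CLASS_OFFSETS[c][1] for c in classes]) * e  # log2(F1/P2)

    mean_f1 = base
    mean_p1 = base / np.exp2(a)
    mean_p2 = base / np.exp2(b)
    mean_f1b = mean_f1.copy()
    if params.reciprocal_fraction > 0:
        flip = rng.random(n) < params.reciprocal_fraction
        sign = rng.choice([-1.0, 1.0], size=n)
        mean_f1b = np.where(flip, mean_f1 * np.exp2(sign * e), mean_f1b)

    # regulatory architecture: parents equal -> conserved regulation;
    # otherwise cis (allele ratio mirrors parents) or trans (balanced)
    parents_equal = a == b
    is_cis = (~parents_equal) & (rng.random(n) < params.cis_fraction)
    regulation = np.where(parents_equal, "CONSERVED", np.where(is_cis, "CIS", "TRANS"))
    parental_prop = mean_p1 / (mean_p1 + mean_p2)
    allele_prop = np.where(regulation == "CIS", parental_prop, 0.5)

    lo, hi = params.size_factor_range
    multipliers = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(design)))
    geno_mean = {"P1": mean_p1, "P2": mean_p2, "F1a": mean_f1, "F1b": mean_f1b}
    cols = {}
    for d, mult in zip(design, multipliers):
        cols[d.sample_id] = _nb_draw(rng, geno_mean[d.genotype] * mult, params.dispersion)
    counts = CountMatrix(pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")))

    allele_rows = []
    hybrid_samples = [d.sample_id for d in design if d.genotype in ("F1a", "F1b")]
    for gi, gid in enumerate(gene_ids):
        for s in range(params.snps_per_gene):
            snp_id = f"{gid}_snp{s + 1}"
            pos = gi * 1000 + s * 100 + 1
            for sid in hybrid_samples:
                depth = int(rng.poisson(params.mean_allele_depth))
                k = int(rng.binomial(depth, allele_prop[gi])) if depth else 0
                allele_rows.append((gid, snp_id, "chr1", pos, sid, k, depth - k))
    allele_counts = pd.DataFrame(allele_rows, columns=ALLELE_COLUMNS)

    truth = [
        SyntheticTruth(
            gene_id=gid,
            true_class=str(classes[i]),
            true_hybrid_allele_prop=float(allele_prop[i]),
            true_regulation=str(regulation[i]),
            base_mean=float(base[i]),
            dispersion=params.dispersion,
        )
        for i, gid in enumerate(gene_ids)
    ]
    return counts, allele_counts, truth, design


def truth_confusion(
    truth: Sequence[SyntheticTruth] | pd.DataFrame,
    calls: pd.DataFrame,
    call_column: str = "klass",
) -> pd.DataFrame:
    """True-class x called-class contingency table.

    ``calls`` needs gene_id plus the call column; gene sets must match the
    truth exactly. Row sums equal the truth class tallies.
    """
    if isinstance(truth, pd.DataFrame):
        tdf = truth[["gene_id", "true_class"]]
    else:
        tdf = pd.DataFrame({"gene_id": [t.gene_id for t in truth], "true_class": [t.true_class for t in truth]})
    if set(tdf["gene_id"]) != set(calls["gene_id"]):
        raise HeteroseqError("truth and calls cover different gene sets")
    merged = tdf.merge(calls[["gene_id", call_column]], on="gene_id")
    order = {k: i for i, k in enumerate(ALL_CLASSES)}
    seen = sorted(
        set(merged["true_class"]) | set(merged[call_column]),
        key=lambda k: (order.get(k, len(order)), k),
    )
    table = pd.crosstab(merged["true_class"], merged[call_column])
    table = table.reindex(index=seen, columns=seen, fill_value=0)
    table.index.name = "true_class"
    table.columns.name = "called_class"
    return table
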
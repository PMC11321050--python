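"""Gene-set module scores with expression-matched control genes.

The per-cell score of a gene program (e.g. the p53 pathway set CDKN1A,
GADD45A, PLK2, MDM2, RPS27L, TRIAP1, FAS) is the mean log-normalized
expression of the program genes minus the mean of control genes drawn
from the same average-expression bins, which removes the component of
the signal explained by overall expression level.  Concretely: all
genes are ranked by mean expression across cells and cut into
``n_bins`` equal-size bins; for each program gene, ``n_ctrl`` control
genes are sampled without replacement from its bin (program genes are
excluded from the candidate pool, so adding a constant to the program
genes of one cell shifts that cell's score by exactly that constant);
the score is mean(program) - mean(pooled controls), per cell.

Input is expected to be log-normalized expression (log1p of the
equal-total normalized matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .constants import P53_PATHWAY_GENES
from .karyotype import CountMatrix, KaryotypeCallSet


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be nonempty")


#: Default p53 pathway program.
P53_GENE_SET = GeneSet(name="p53_pathway", genes=P53_PATHWAY_GENES)


@dataclass
class ModuleScoreVector:
    scores: pd.Series              # per-cell score
    gene_set: GeneSet
    n_bins: int
    n_ctrl: int
    seed: int
    missing_genes: list[str] = field(default_factory=list)
    control_genes: dict[str, list[str]] = field(default_factory=dict)


def log_normalize(m: CountMatrix) -> CountMatrix:
    """log1p of the matrix, gene/cell identities preserved."""
    return CountMatrix(
        counts=np.log1p(np.asarray(m.counts, dtype=float)),
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        gene_chromosome=m.gene_chromosome,
    )


def module_score(
    m: CountMatrix,
    gene_set: GeneSet = P53_GENE_SET,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreVector:
    """Per-cell module score with expression-matched controls.

    ``m`` must hold log-normalized expression.  Program genes absent
    from the matrix are reported in ``missing_genes``, never silently
    dropped; if every program gene is missing, an error is raised.  If a
    bin holds fewer than ``n_ctrl`` candidate controls, sampling falls
    back to with-replacement and a warning is emitted.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_ctrl < 1:
        raise ValueError("n_ctrl must be >= 1")
    expr = m.to_frame()
    present = [g for g in gene_set.genes if g in expr.index]
    missing = [g for g in gene_set.genes if g not in expr.index]
    if not present:
        raise ValueError(
            f"none of the {len(gene_set.genes)} genes of set "
            f"{gene_set.name!r} are present in the matrix"
        )

    avg = expr.mean(axis=1)
    # Equal-size expression bins over the rank of the average.
    ranks = avg.rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)

    rng = np.random.default_rng(seed)
    program = set(present)
    control_pool: list[str] = []
    control_by_gene: dict[str, list[str]] = {}
    for g in present:
        b = bins.loc[g]
        candidates = bins.index[(bins == b) & ~bins.index.isin(program)]
        candidates = list(candidates)
        if len(candidates) == 0:
            raise ValueError(
                f"expression bin of gene {g} contains no control candidates"
            )
        if len(candidates) < n_ctrl:
            warnings.warn(
                f"bin of gene {g} has {len(candidates)} control candidates "
                f"< n_ctrl={n_ctrl}; sampling with replacement",
                stacklevel=2,
            )
            chosen = rng.choice(candidates, size=n_ctrl, replace=True)
        else:
            chosen = rng.choice(candidates, size=n_ctrl, replace=False)
        chosen = [str(x) for x in chosen]
        control_by_gene[g] = chosen
        control_pool.extend(chosen)

    program_mean = expr.loc[present].mean(axis=0)
    control_mean = expr.loc[control_pool].mean(axis=0)
    scores = (program_mean - control_mean).rename("score")
    return ModuleScoreVector(
        scores=scores,
        gene_set=gene_set,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        missing_genes=missing,
        control_genes=control_by_gene,
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def score_vs_aneuploidy(
    scores: ModuleScoreVector, calls: KaryotypeCallSet
) -> RegressionResult:
    """OLS of module score on the number of aneuploid chromosomes,
    over the cells shared between the two inputs; Pearson r reported."""
    common = scores.scores.index.intersection(calls.per_cell.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared cells for regression")
    x = calls.per_cell.loc[common, "n_aneuploid"].to_numpy(dtype=float)
    y = scores.scores.loc[common].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("n_aneuploid is constant; regression undefined")
    fit = _stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(common),
    )


@dataclass
class GroupComparison:
    summary: pd.DataFrame          # per-class mean / sd / n
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame            # pairwise comparisons
    dropped_classes: list[str]


def group_scores(
    scores: pd.Series, classes: pd.Series, order: Sequence[str] = ("euploid", "simple", "complex")
) -> GroupComparison:
    """Per-class score summaries with ANOVA and post-hoc Tukey HSD.

    ANOVA and Tukey are delegated to scipy/statsmodels.  Classes absent
    from the data are dropped with a warning.
    """
    common = scores.index.intersection(classes.index)
    scores = scores.loc[common]
    classes = classes.loc[common]
    present = [c for c in order if (classes == c).any()]
    dropped = [c for c in order if c not in present]
    if dropped:
        warnings.warn(f"classes with no cells dropped: {dropped}", stacklevel=2)
    if len(present) < 2:
        raise ValueError("need at least 2 ploidy classes for comparison")

    groups = [scores[classes == c].to_numpy(dtype=float) for c in present]
    summary = pd.DataFrame(
        {
            "mean": [g.mean() for g in groups],
            "sd": [g.std(ddof=1) if len(g) > 1 else 0.0 for g in groups],
            "n": [len(g) for g in groups],
        },
        index=pd.Index(present, name="ploidy_class"),
    )
    F, p = _stats.f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    mask = classes.isin(present)
    tk = pairwise_tukeyhsd(
        scores[mask].to_numpy(dtype=float), classes[mask].to_numpy(), alpha=0.05
    )
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return GroupComparison(
        summary=summary,
        anova_F=float(F),
        anova_p=float(p),
        tukey=tukey,
        dropped_classes=dropped,
    )
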
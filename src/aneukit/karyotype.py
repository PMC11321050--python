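"""Whole-chromosome karyotype inference from single-cell RNA-seq counts.

The method aggregates normalized expression per chromosome and tests
each cell's deviation from the population against a permutation null:

1. QC: drop cells with too few detected genes or too high a
   mitochondrial read fraction.
2. Normalize every cell to the same total count (the median raw library
   size), so dosage effects appear as relative shifts.
3. Chromosome score ``s[c,k]`` = sum of normalized counts of the genes
   on chromosome ``k`` in cell ``c``; deviation
   ``r[c,k] = s[c,k] / median_c s[.,k]``.  A trisomy in an otherwise
   diploid cell produces ``r = 1.5 / (1 + 0.5 f_k)`` where ``f_k`` is
   the chromosome's share of the library (renormalization shrinks the
   apparent gain); a monosomy produces ``0.5 / (1 - 0.5 f_k)``.
4. Significance: gene -> chromosome labels are permuted (chromosome
   gene-set sizes preserved), deviations recomputed, and a two-sided
   add-one permutation p-value assigned to each (cell, chromosome) pair
   on the ``|log r|`` scale.
5. Calls: Benjamini-Hochberg over all pairs; a pair is a gain iff
   ``q <= alpha`` and ``r >= gain_min``, a loss iff ``q <= alpha`` and
   ``r <= loss_max``, else neutral.  Each gained or lost chromosome
   counts as one aneuploid chromosome; cells are classed euploid
   (0), simple (1-3) or complex (>=4).

Only whole-chromosome events are modeled; segmental changes are out of
scope by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .constants import classify_n_aneuploid

DEFAULT_EXCLUDED_CHROMOSOMES: tuple[str, ...] = ("Y", "MT")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x cell expression matrix with a gene -> chromosome map.

    ``counts`` is nonnegative; integer for raw data, float after
    normalization.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    gene_chromosome: pd.Series

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match gene/cell ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        missing = [g for g in self.gene_ids if g not in self.gene_chromosome.index]
        if missing:
            raise ValueError(
                f"{len(missing)} gene(s) lack a chromosome assignment, "
                f"e.g. {missing[:3]}"
            )
        self.gene_chromosome = self.gene_chromosome.loc[self.gene_ids]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, keep: Sequence[str]) -> "CountMatrix":
        idx = [self.cell_ids.index(c) for c in keep]
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=list(keep),
            gene_chromosome=self.gene_chromosome,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class QCFilterSpec:
    """Cell-level QC thresholds.

    Defaults mirror full-length scRNA-seq practice for high-depth data:
    exclude cells with fewer than 5000 detected genes or more than 20%
    mitochondrial reads.
    """

    min_genes_detected: int = 5000
    max_mito_fraction: float = 0.20
    mito_gene_prefix: str = "MT-"
    mito_genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be >= 0")


@dataclass
class ChromosomeScoreMatrix:
    """Per-cell, per-chromosome expression scores and deviations."""

    score: pd.DataFrame      # cells x chromosomes, summed normalized counts
    deviation: pd.DataFrame  # score / per-chromosome population median
    n_genes: pd.Series       # genes per included chromosome
    low_confidence: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


@dataclass
class KaryotypeCallSet:
    """Gain/loss/neutral calls with permutation p and BH q values."""

    calls: pd.DataFrame      # long: cell_id, chromosome, deviation, p, q, call
    per_cell: pd.DataFrame   # index cell_id: n_aneuploid, ploidy_class
    alpha: float
    gain_min: float
    loss_max: float


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_filter(
    m: CountMatrix, spec: QCFilterSpec = QCFilterSpec()
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop cells failing QC; report every exclusion with its reason."""
    if spec.mito_genes is not None:
        mito_mask = np.array([g in set(spec.mito_genes) for g in m.gene_ids])
    else:
        mito_mask = np.array(
            [g.startswith(spec.mito_gene_prefix) for g in m.gene_ids]
        )
    totals = m.counts.sum(axis=0).astype(float)
    genes_detected = (m.counts > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, m.counts[mito_mask].sum(axis=0) / totals, 1.0
        )

    records = []
    keep = []
    for i, cell in enumerate(m.cell_ids):
        reasons = []
        if genes_detected[i] < spec.min_genes_detected:
            reasons.append(f"genes_detected<{spec.min_genes_detected}")
        if mito_frac[i] > spec.max_mito_fraction:
            reasons.append(f"mito_fraction>{spec.max_mito_fraction}")
        if reasons:
            records.append(
                {
                    "cell_id": cell,
                    "n_genes_detected": int(genes_detected[i]),
                    "mito_fraction": float(mito_frac[i]),
                    "reason": ";".join(reasons),
                }
            )
        else:
            keep.append(cell)
    if not keep:
        raise ValueError(
            f"all {m.n_cells} cells excluded by QC "
            f"(min_genes_detected={spec.min_genes_detected}, "
            f"max_mito_fraction={spec.max_mito_fraction})"
        )
    report = pd.DataFrame(
        records, columns=["cell_id", "n_genes_detected", "mito_fraction", "reason"]
    )
    return m.subset_cells(keep), report


def normalize(m: CountMatrix) -> CountMatrix:
    """Scale every cell to the same total count (median raw library size)."""
    totals = m.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = [m.cell_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"cells with zero total count: {bad[:5]}")
    target = float(np.median(totals))
    normalized = m.counts * (target / totals)
    return CountMatrix(
        counts=normalized,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        gene_chromosome=m.gene_chromosome,
    )


# ---------------------------------------------------------------------------
# Chromosome scores and deviations
# ---------------------------------------------------------------------------


def _chromosome_groups(
    m: CountMatrix, exclude: Iterable[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Sort included genes by chromosome; return (chromosomes, gene index
    into ``m.counts`` rows, reduceat offsets)."""
    excluded = set(exclude)
    chrom = m.gene_chromosome.to_numpy()
    included = ~np.isin(chrom, list(excluded))
    order = np.lexsort((np.arange(m.n_genes), chrom))
    order = order[included[order]]
    sorted_chrom = chrom[order]
    chroms, starts = np.unique(sorted_chrom, return_index=True)
    return list(chroms), order, starts


def _scores(matrix: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Chromosome sums (chromosomes x cells) over contiguous row groups."""
    return np.add.reduceat(matrix, offsets, axis=0)


def chromosome_scores(
    m: CountMatrix,
    min_genes: int = 25,
    exclude: Iterable[str] = DEFAULT_EXCLUDED_CHROMOSOMES,
) -> ChromosomeScoreMatrix:
    """Sum normalized counts per chromosome and divide by the population
    median to obtain per-cell deviations ``r[c,k]``.

    Chromosomes with fewer than ``min_genes`` genes are retained but
    flagged low-confidence; chromosomes with no genes at all are
    excluded with a warning.
    """
    chroms, order, starts = _chromosome_groups(m, exclude)
    if not chroms:
        raise ValueError("no chromosomes left after exclusions")
    mat = np.asarray(m.counts, dtype=float)[order]
    s = _scores(mat, starts)  # chrom x cells
    sizes = np.diff(np.append(starts, len(order)))

    score = pd.DataFrame(s.T, index=m.cell_ids, columns=chroms)
    med = score.median(axis=0)
    zero_med = med[med == 0].index.tolist()
    if zero_med:
        warnings.warn(
            f"chromosome(s) with zero median score excluded: {zero_med}",
            stacklevel=2,
        )
        score = score.drop(columns=zero_med)
        med = med.drop(zero_med)
        keepmask = [c not in zero_med for c in chroms]
        sizes = sizes[keepmask]
        chroms = [c for c in chroms if c not in zero_med]
    deviation = score / med
    n_genes = pd.Series(sizes, index=chroms, name="n_genes")
    low_conf = n_genes[n_genes < min_genes].index.tolist()
    return ChromosomeScoreMatrix(
        score=score,
        deviation=deviation,
        n_genes=n_genes,
        low_confidence=low_conf,
        excluded=sorted(set(exclude)) + zero_med,
    )


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def permutation_null(
    m: CountMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exclude: Iterable[str] = DEFAULT_EXCLUDED_CHROMOSOMES,
) -> pd.DataFrame:
    """Two-sided permutation p-values for every (cell, chromosome) pair.

    Gene -> chromosome labels are shuffled (chromosome gene-set sizes
    preserved), deviations recomputed per permutation, and

        p = (1 + #{permutations with |log r_perm| >= |log r_obs|})
            / (1 + n_perm)

    so p is in (0, 1] with minimum 1/(1+n_perm).  ``m`` must be the
    normalized matrix.  Reproducible from ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable p-value resolution")
    chroms, order, starts = _chromosome_groups(m, exclude)
    mat = np.ascontiguousarray(np.asarray(m.counts, dtype=float)[order])

    def deviations(x: np.ndarray) -> np.ndarray:
        s = _scores(x, starts)  # chrom x cells
        med = np.median(s, axis=1, keepdims=True)
        if np.any(med <= 0):
            raise ValueError("chromosome with non-positive median score")
        return s / med

    r_obs = deviations(mat)
    obs_stat = np.abs(np.log(r_obs))
    exceed = np.zeros_like(obs_stat, dtype=np.int64)
    rng = np.random.default_rng(seed)
    n_rows = mat.shape[0]
    with np.errstate(divide="ignore"):
        for _ in range(n_perm):
            perm = rng.permutation(n_rows)
            r_perm = deviations(mat[perm])
            exceed += np.abs(np.log(r_perm)) >= obs_stat
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(p.T, index=m.cell_ids, columns=chroms)


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------


def call_karyotypes(
    scores: ChromosomeScoreMatrix,
    pvals: pd.DataFrame,
    alpha: float = 0.05,
    gain_min: float = 1.25,
    loss_max: float = 0.75,
) -> KaryotypeCallSet:
    """Assign gain/loss/neutral per (cell, chromosome) and class per cell.

    BH-FDR is applied over all pairs; significant pairs must also clear
    the effect-size gates (``r >= gain_min`` for gains,
    ``r <= loss_max`` for losses) so significant-but-tiny deviations are
    not called.
    """
    if not (gain_min > 1 > loss_max > 0):
        raise ValueError("need gain_min > 1 > loss_max > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    common = [c for c in scores.deviation.columns if c in pvals.columns]
    dev = scores.deviation[common]
    p = pvals.loc[dev.index, common]

    long = (
        dev.stack().rename("deviation").to_frame()
        .join(p.stack().rename("p"))
        .reset_index()
        .rename(columns={"level_0": "cell_id", "level_1": "chromosome"})
    )
    _, q, _, _ = multipletests(long["p"].to_numpy(), method="fdr_bh")
    long["q"] = np.maximum(q, long["p"])  # BH q is >= p by construction; guard fp
    sig = long["q"] <= alpha
    long["call"] = "neutral"
    long.loc[sig & (long["deviation"] >= gain_min), "call"] = "gain"
    long.loc[sig & (long["deviation"] <= loss_max), "call"] = "loss"

    n_aneu = (
        long.assign(event=(long["call"] != "neutral").astype(int))
        .groupby("cell_id", sort=False)["event"]
        .sum()
    )
    per_cell = pd.DataFrame(
        {
            "n_aneuploid": n_aneu,
            "ploidy_class": n_aneu.map(classify_n_aneuploid),
        }
    ).loc[dev.index]
    return KaryotypeCallSet(
        calls=long,
        per_cell=per_cell,
        alpha=alpha,
        gain_min=gain_min,
        loss_max=loss_max,
    )


def per_chromosome_event_counts(
    calls: KaryotypeCallSet, cells: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tally gain and loss calls per chromosome over the selected cells."""
    tbl = calls.calls
    if cells is not None:
        if len(cells) == 0:
            raise ValueError("empty cell subset")
        missing = set(cells) - set(tbl["cell_id"])
        if missing:
            raise ValueError(f"unknown cell ids: {sorted(missing)[:5]}")
        tbl = tbl[tbl["cell_id"].isin(set(cells))]
    out = (
        tbl.assign(
            n_gain=(tbl["call"] == "gain").astype(int),
            n_loss=(tbl["call"] == "loss").astype(int),
        )
        .groupby("chromosome", sort=False)[["n_gain", "n_loss"]]
        .sum()
    )
    return out


def infer_karyotypes(
    m: CountMatrix,
    qc: QCFilterSpec | None = QCFilterSpec(),
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    gain_min: float = 1.25,
    loss_max: float = 0.75,
    min_genes: int = 25,
    exclude: Iterable[str] = DEFAULT_EXCLUDED_CHROMOSOMES,
) -> tuple[KaryotypeCallSet, ChromosomeScoreMatrix, pd.DataFrame]:
    """End-to-end convenience: QC -> normalize -> scores -> permutation
    null -> calls.  Returns (calls, scores, QC exclusion report).

    Pass ``qc=None`` to skip cell filtering.
    """
    if qc is not None:
        m, report = qc_filter(m, qc)
    else:
        report = pd.DataFrame(
            columns=["cell_id", "n_genes_detected", "mito_fraction", "reason"]
        )
    norm = normalize(m)
    scores = chromosome_scores(norm, min_genes=min_genes, exclude=exclude)
    pvals = permutation_null(norm, n_perm=n_perm, seed=seed, exclude=exclude)
    calls = call_karyotypes(
        scores, pvals, alpha=alpha, gain_min=gain_min, loss_max=loss_max
    )
    return calls, scores, report
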
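"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Three generators emulate the three raw data modalities the toolkit
analyzes, each returning the simulated data together with a truth record
so downstream calls can be scored against a known answer:

* :func:`simulate_counts` — a gene x cell scRNA-seq count matrix in which
  whole-chromosome copy-number changes scale expected expression by
  ``copies / 2`` (1.5x for a trisomy, 0.5x for a monosomy), with
  negative-binomial sampling noise and log-normal library-size factors.
* :func:`simulate_spreads` — integer metaphase-spread chromosome counts
  clustered at the euploid number with a configurable deviation
  distribution.
* :func:`simulate_foci_image` — a 3-channel 2D fluorescence image
  (nucleus marker / centromere spots / immunostain) with diffraction-
  limited Gaussian foci, a configurable fraction of which are placed
  within one PSF width of another spot so they merge into clusters.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_CHROMOSOMES,
    GENES_PER_CHROMOSOME_GRCH38,
    classify_n_aneuploid,
)
from .karyotype import CountMatrix
from .spreads import SpreadSet, nearest_euploid

# ---------------------------------------------------------------------------
# Seed fan-out
# ---------------------------------------------------------------------------

#: Fixed stage indices for deriving per-stage child seeds from one global
#: seed. The child stream for stage ``s`` is ``default_rng([seed, STAGE[s]])``.
STAGE_INDEX: dict[str, int] = {
    "counts": 0,
    "spreads": 1,
    "foci": 2,
    "permutation": 3,
    "module_score": 4,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child random generator for a named pipeline stage.

    Uses the fixed scheme ``default_rng([seed, STAGE_INDEX[stage]])`` so
    that each stage's stream is reproducible from the global seed alone
    and independent of execution order.
    """
    if stage not in STAGE_INDEX:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_INDEX)}")
    return np.random.default_rng([int(seed), STAGE_INDEX[stage]])


# ---------------------------------------------------------------------------
# scRNA-seq count simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KaryotypeTruth:
    """True karyotype of one simulated cell."""

    cell_id: str
    copies_per_chromosome: dict[str, int]
    n_aneuploid: int
    ploidy_class: str

    def __post_init__(self) -> None:
        n = sum(1 for c in self.copies_per_chromosome.values() if c != 2)
        if n != self.n_aneuploid:
            raise ValueError("n_aneuploid inconsistent with copy-number map")
        if classify_n_aneuploid(self.n_aneuploid) != self.ploidy_class:
            raise ValueError("ploidy_class inconsistent with n_aneuploid")


def default_genes_per_chromosome(
    n_genes: int, chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES
) -> dict[str, int]:
    """Apportion ``n_genes`` over chromosomes proportionally to the
    GRCh38 protein-coding gene counts (largest-remainder rounding)."""
    if n_genes < len(chromosomes):
        raise ValueError("need at least one gene per chromosome")
    weights = np.array([GENES_PER_CHROMOSOME_GRCH38[c] for c in chromosomes], float)
    ideal = n_genes * weights / weights.sum()
    base = np.floor(ideal).astype(int)
    base = np.maximum(base, 1)
    remainder = ideal - np.floor(ideal)
    deficit = n_genes - int(base.sum())
    if deficit > 0:
        for i in np.argsort(-remainder)[:deficit]:
            base[i] += 1
    elif deficit < 0:
        for i in np.argsort(remainder):
            if deficit == 0:
                break
            if base[i] > 1:
                base[i] -= 1
                deficit += 1
    return dict(zip(chromosomes, (int(b) for b in base)))


@dataclass(frozen=True)
class CountSimParams:
    """Parameters of the scRNA-seq count simulator.

    Expected count of gene ``g`` in cell ``c`` is
    ``lambda_g * (copies_{c,chrom(g)} / 2) * L_c`` where ``lambda_g`` is
    log-normal with parameters (``baseline_mean_logmean``,
    ``baseline_mean_logsd``) and ``L_c`` is a log-normal library-size
    factor.  Counts are negative-binomial with
    ``var = mu + dispersion * mu**2`` (``dispersion=0`` is Poisson).
    """

    n_cells: int = 200
    n_genes: int = 2000
    genes_per_chromosome: Mapping[str, int] | None = None
    baseline_mean_logmean: float = math.log(8.0)
    baseline_mean_logsd: float = 1.0
    dispersion: float = 0.1
    libsize_logsd: float = 0.2
    aneuploid_fraction_simple: float = 0.20
    aneuploid_fraction_complex: float = 0.05
    n_mito_genes: int = 13
    seed: int = 0

    def resolved_genes_per_chromosome(self) -> dict[str, int]:
        if self.genes_per_chromosome is not None:
            gpc = dict(self.genes_per_chromosome)
            if sum(gpc.values()) != self.n_genes:
                raise ValueError("genes_per_chromosome must sum to n_genes")
            return gpc
        return default_genes_per_chromosome(self.n_genes)

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.libsize_logsd < 0 or self.baseline_mean_logsd < 0:
            raise ValueError("log-sd parameters must be >= 0")
        if self.n_mito_genes < 0:
            raise ValueError("n_mito_genes must be >= 0")
        fs, fc = self.aneuploid_fraction_simple, self.aneuploid_fraction_complex
        if not (0 <= fs <= 1 and 0 <= fc <= 1 and fs + fc <= 1):
            raise ValueError("aneuploid fractions must be in [0,1] and sum <= 1")
        self.resolved_genes_per_chromosome()


def simulate_counts(
    params: CountSimParams,
    return_baseline: bool = False,
):
    """Simulate a gene x cell count matrix with planted aneuploidies.

    Simple aneuploid cells carry 1-3 whole-chromosome changes, complex
    cells 4-8; each affected chromosome is a gain (3 copies, 1.5x
    dosage) or a loss (1 copy, 0.5x dosage) with equal probability.
    Mitochondrial genes (``MT-`` prefix, chromosome label ``MT``) are
    appended outside the karyotype model so QC filters can be exercised.

    Returns ``(matrix, truths)``, one :class:`KaryotypeTruth` per cell;
    with ``return_baseline=True`` also the per-gene baseline expected
    counts (the law-of-large-numbers reference for noise tests).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    gpc = params.resolved_genes_per_chromosome()
    chromosomes = list(gpc)

    gene_ids: list[str] = []
    gene_chrom: list[str] = []
    for chrom in chromosomes:
        for j in range(gpc[chrom]):
            gene_ids.append(f"{chrom}-g{j:04d}")
            gene_chrom.append(chrom)
    for j in range(params.n_mito_genes):
        gene_ids.append(f"MT-g{j:02d}")
        gene_chrom.append("MT")
    n_genes_total = len(gene_ids)

    lam = rng.lognormal(
        params.baseline_mean_logmean, params.baseline_mean_logsd, size=n_genes_total
    )
    lib = (
        rng.lognormal(0.0, params.libsize_logsd, size=params.n_cells)
        if params.libsize_logsd > 0
        else np.ones(params.n_cells)
    )

    n_simple = int(round(params.aneuploid_fraction_simple * params.n_cells))
    n_complex = int(round(params.aneuploid_fraction_complex * params.n_cells))
    labels = np.array(
        ["simple"] * n_simple
        + ["complex"] * n_complex
        + ["euploid"] * (params.n_cells - n_simple - n_complex)
    )
    rng.shuffle(labels)

    chrom_of_gene = np.array(gene_chrom)
    chrom_index = {c: np.flatnonzero(chrom_of_gene == c) for c in chromosomes}

    counts = np.empty((n_genes_total, params.n_cells), dtype=np.int64)
    truths: list[KaryotypeTruth] = []
    max_simple = min(3, len(chromosomes))
    max_complex = min(8, len(chromosomes))
    if max_complex < 4 and n_complex > 0:
        raise ValueError(
            "complex aneuploidy (>=4 events) needs at least 4 chromosomes"
        )
    for c in range(params.n_cells):
        copies = {chrom: 2 for chrom in chromosomes}
        if labels[c] == "simple":
            n_events = int(rng.integers(1, max_simple + 1))
        elif labels[c] == "complex":
            n_events = int(rng.integers(4, max_complex + 1))
        else:
            n_events = 0
        affected = rng.choice(len(chromosomes), size=n_events, replace=False)
        for a in affected:
            copies[chromosomes[a]] = 3 if rng.random() < 0.5 else 1

        dosage = np.ones(n_genes_total)
        for chrom, cp in copies.items():
            if cp != 2:
                dosage[chrom_index[chrom]] = cp / 2.0
        mu = lam * dosage * lib[c]
        if params.dispersion == 0:
            counts[:, c] = rng.poisson(mu)
        else:
            r = 1.0 / params.dispersion
            p = r / (r + mu)
            counts[:, c] = rng.negative_binomial(r, p)

        cell_id = f"cell{c:04d}"
        n_aneu = sum(1 for v in copies.values() if v != 2)
        truths.append(
            KaryotypeTruth(
                cell_id=cell_id,
                copies_per_chromosome=copies,
                n_aneuploid=n_aneu,
                ploidy_class=classify_n_aneuploid(n_aneu),
            )
        )

    matrix = CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=[f"cell{c:04d}" for c in range(params.n_cells)],
        gene_chromosome=pd.Series(gene_chrom, index=gene_ids),
    )
    if return_baseline:
        return matrix, truths, lam
    return matrix, truths


def truth_frame(truths: Sequence[KaryotypeTruth]) -> pd.DataFrame:
    """Tabulate truth records: one row per cell, one column per chromosome."""
    chroms = list(truths[0].copies_per_chromosome)
    rows = []
    for t in truths:
        row: dict[str, object] = {
            "cell_id": t.cell_id,
            "n_aneuploid": t.n_aneuploid,
            "ploidy_class": t.ploidy_class,
        }
        for c in chroms:
            row[f"copies_{c}"] = t.copies_per_chromosome[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")


def noise_free_trisomy_matrix(
    n_cells: int = 41,
    n_genes: int = 2000,
    trisomy_chromosome: str = "7",
    trisomy_cells: Sequence[int] = (0,),
    baseline_mean_logmean: float = 2.0,
    baseline_mean_logsd: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, float]:
    """Deterministic expected-count matrix with planted trisomies.

    The zero-noise limit of the count model (dispersion -> 0, infinite
    depth): entries are the expected counts themselves, so downstream
    deviations can be checked against closed forms.  Returns the matrix
    and ``f_k``, the trisomic chromosome's share of the disomic library;
    after equal-total normalization the trisomic cells' deviation on
    that chromosome is exactly ``1.5 / (1 + 0.5 * f_k)``.
    """
    rng = np.random.default_rng(seed)
    gpc = default_genes_per_chromosome(n_genes)
    if trisomy_chromosome not in gpc:
        raise ValueError(f"unknown chromosome {trisomy_chromosome!r}")
    gene_ids, gene_chrom = [], []
    for chrom in gpc:
        for j in range(gpc[chrom]):
            gene_ids.append(f"{chrom}-g{j:04d}")
            gene_chrom.append(chrom)
    lam = rng.lognormal(baseline_mean_logmean, baseline_mean_logsd, len(gene_ids))
    chrom_arr = np.array(gene_chrom)
    mask = chrom_arr == trisomy_chromosome
    f_k = float(lam[mask].sum() / lam.sum())
    counts = np.tile(lam[:, None], (1, n_cells))
    for c in trisomy_cells:
        counts[mask, c] *= 1.5
    m = CountMatrix(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=[f"cell{c:04d}" for c in range(n_cells)],
        gene_chromosome=pd.Series(gene_chrom, index=gene_ids),
    )
    return m, f_k


# ---------------------------------------------------------------------------
# Metaphase spread simulation
# ---------------------------------------------------------------------------


def simulate_spreads(
    n: int,
    base_ploidy: int = 2,
    deviation_distribution: Mapping[int, float] | None = None,
    seed: int = 0,
    condition: str = "simulated",
) -> tuple[SpreadSet, np.ndarray]:
    """Simulate per-spread chromosome counts around the euploid number.

    Counts are ``23 * base_ploidy`` plus a deviation sampled from
    ``deviation_distribution`` (map signed integer -> probability).
    Returns the :class:`~aneukit.spreads.SpreadSet` and the array of true
    deviations.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if base_ploidy <= 0:
        raise ValueError("base_ploidy must be positive")
    if deviation_distribution is None:
        deviation_distribution = {0: 1.0}
    devs = np.array(sorted(deviation_distribution), dtype=int)
    probs = np.array([deviation_distribution[int(d)] for d in devs], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("deviation probabilities must be >= 0 and sum to 1")
    base = 23 * base_ploidy
    if base + devs.min() <= 0:
        raise ValueError("configuration would produce non-positive counts")
    rng = np.random.default_rng(seed)
    sampled = rng.choice(devs, size=n, p=probs)
    counts = base + sampled
    return SpreadSet(condition=condition, counts=counts.tolist()), sampled


# ---------------------------------------------------------------------------
# Fluorescence image simulation
# ---------------------------------------------------------------------------


@dataclass
class NucleusTruth:
    """Ground truth for one simulated nucleus."""

    nucleus_id: int
    center: tuple[float, float]
    radius: float
    spot_centers: np.ndarray  # (n_spots, 2) row/col coordinates
    spot_amplitudes: np.ndarray
    cluster_assignments: np.ndarray  # group label per spot
    true_foci_count: int
    p53_level: float

    @property
    def n_true_clusters(self) -> int:
        return len(np.unique(self.cluster_assignments))


@dataclass
class FociImageTruth:
    nuclei: list[NucleusTruth] = field(default_factory=list)

    @property
    def total_spots(self) -> int:
        return sum(t.true_foci_count for t in self.nuclei)


def _place_spots(
    rng: np.random.Generator,
    n_spots: int,
    cluster_fraction: float,
    usable_radius: float,
    min_sep: float,
    cluster_dist_range: tuple[float, float],
    max_tries: int = 20000,
) -> tuple[np.ndarray, np.ndarray]:
    """Place spot centers in a disk: seed spots pairwise >= min_sep apart,
    clustered spots within ``cluster_dist_range`` of a random seed while
    keeping >= min_sep from every spot outside their own group."""
    n_clustered = int(round(cluster_fraction * n_spots))
    n_seed = n_spots - n_clustered
    if n_seed < 1:
        raise ValueError("cluster_fraction too high: no seed spots left")
    centers: list[np.ndarray] = []
    groups: list[int] = []

    def sample_in_disk() -> np.ndarray:
        while True:
            p = rng.uniform(-usable_radius, usable_radius, size=2)
            if p @ p <= usable_radius**2:
                return p

    for i in range(n_seed):
        for _ in range(max_tries):
            p = sample_in_disk()
            if all(np.hypot(*(p - q)) >= min_sep for q in centers):
                centers.append(p)
                groups.append(i)
                break
        else:
            raise RuntimeError(
                "could not place non-overlapping spots at the requested density"
            )

    for _ in range(n_clustered):
        for _ in range(max_tries):
            target = int(rng.integers(0, n_seed))
            d = rng.uniform(*cluster_dist_range)
            theta = rng.uniform(0, 2 * np.pi)
            p = centers[target] + d * np.array([np.cos(theta), np.sin(theta)])
            if p @ p > usable_radius**2:
                continue
            ok = True
            for q, g in zip(centers, groups):
                if g == groups[target]:
                    continue
                if np.hypot(*(p - q)) < min_sep:
                    ok = False
                    break
            if ok:
                centers.append(p)
                groups.append(groups[target])
                break
        else:
            raise RuntimeError("could not place clustered spot")

    return np.array(centers), np.array(groups)


def simulate_foci_image(
    n_nuclei: int,
    foci_counts: Sequence[int],
    cluster_fraction: float = 0.0,
    psf_sigma_px: float = 1.5,
    spot_intensity_cv: float = 0.0,
    background_level: float = 0.0,
    noise_sd: float = 0.0,
    p53_levels: Sequence[float] | None = None,
    seed: int = 0,
    nucleus_radius_px: float = 50.0,
    spacing_px: float = 24.0,
    image_shape: tuple[int, int] | None = None,
) -> tuple["FociImage", FociImageTruth]:
    """Render a 3-channel image of nuclei with centromere spots.

    Channel 0 is a uniform nucleus fill (Cdt1-like), channel 1 the sum of
    Gaussian centromere spots of width ``psf_sigma_px`` over a uniform
    background (CENPA-like), channel 2 a uniform per-nucleus immunostain
    at ``p53_levels`` (p53-like).  ``cluster_fraction`` of the spots are
    placed within one PSF width (FWHM = 2.355 sigma) of another spot so
    they are unresolvable by thresholding.  Gaussian read noise of SD
    ``noise_sd`` is added to every channel; intensities are clipped at 0.

    Nuclei are laid out on a non-overlapping grid; if ``image_shape`` is
    given and cannot host the grid, a ``ValueError`` is raised.
    """
    from .foci import FociImage  # local import to avoid cycle

    if len(foci_counts) != n_nuclei:
        raise ValueError("foci_counts must have length n_nuclei")
    if not 0 <= cluster_fraction < 1:
        raise ValueError("cluster_fraction must be in [0, 1)")
    if p53_levels is None:
        p53_levels = [1.0] * n_nuclei
    if len(p53_levels) != n_nuclei:
        raise ValueError("p53_levels must have length n_nuclei")

    rng = np.random.default_rng(seed)
    ncols = int(math.ceil(math.sqrt(n_nuclei)))
    nrows = int(math.ceil(n_nuclei / ncols))
    cell = 2 * nucleus_radius_px + spacing_px
    shape = (
        int(math.ceil(nrows * cell + spacing_px)),
        int(math.ceil(ncols * cell + spacing_px)),
    )
    if image_shape is not None:
        if image_shape[0] < shape[0] or image_shape[1] < shape[1]:
            raise ValueError(
                f"image_shape {image_shape} cannot host {n_nuclei} "
                f"non-overlapping nuclei of radius {nucleus_radius_px}"
            )
        shape = tuple(image_shape)

    nucleus = np.zeros(shape, dtype=np.float64)
    centromere = np.full(shape, background_level, dtype=np.float64)
    immunostain = np.zeros(shape, dtype=np.float64)

    fwhm = 2.355 * psf_sigma_px
    # "PSF width" follows the 1/e^2 beam-diameter convention (4 sigma):
    # clustered spots land inside it, from heavily overlapping (half a
    # FWHM) out to 0.8 widths -- merged into one component at threshold,
    # sometimes showing two intensity maxima, as in real foci clusters.
    psf_width = 4.0 * psf_sigma_px
    min_sep = 4.0 * psf_sigma_px
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]

    truth = FociImageTruth()
    for i in range(n_nuclei):
        r, c = divmod(i, ncols)
        cy = spacing_px + nucleus_radius_px + r * cell
        cx = spacing_px + nucleus_radius_px + c * cell
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius_px**2
        nucleus[disk] = 1.0
        immunostain[disk] = p53_levels[i]

        k = int(foci_counts[i])
        if k <= 0:
            raise ValueError("foci counts must be positive")
        rel_centers, groups = _place_spots(
            rng,
            k,
            cluster_fraction,
            usable_radius=nucleus_radius_px - 3.0 * psf_sigma_px,
            min_sep=min_sep,
            cluster_dist_range=(0.5 * fwhm, 0.8 * psf_width),
        )
        centers = rel_centers + np.array([cy, cx])
        if spot_intensity_cv > 0:
            amps = np.maximum(
                0.05, 1.0 + spot_intensity_cv * rng.standard_normal(k)
            )
        else:
            amps = np.ones(k)

        half = int(math.ceil(4 * psf_sigma_px))
        for (sy, sx), a in zip(centers, amps):
            y0, y1 = int(sy) - half, int(sy) + half + 1
            x0, x1 = int(sx) - half, int(sx) + half + 1
            ys, xs = np.mgrid[y0:y1, x0:x1]
            centromere[y0:y1, x0:x1] += a * np.exp(
                -((ys - sy) ** 2 + (xs - sx) ** 2) / (2 * psf_sigma_px**2)
            )

        truth.nuclei.append(
            NucleusTruth(
                nucleus_id=i + 1,
                center=(cy, cx),
                radius=nucleus_radius_px,
                spot_centers=centers,
                spot_amplitudes=amps,
                cluster_assignments=groups,
                true_foci_count=k,
                p53_level=float(p53_levels[i]),
            )
        )

    if noise_sd > 0:
        nucleus = nucleus + rng.normal(0, noise_sd, shape)
        centromere = centromere + rng.normal(0, noise_sd, shape)
        immunostain = immunostain + rng.normal(0, noise_sd, shape)
    img = FociImage(
        nucleus=np.clip(nucleus, 0, None),
        centromere=np.clip(centromere, 0, None),
        immunostain=np.clip(immunostain, 0, None),
    )
    return img, truth
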
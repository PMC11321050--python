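"""Chromosome counting from centromere-marker fluorescence images.

Counting proceeds in two phases.  Segmentation: nuclei are thresholded
on the nucleus-marker channel by Otsu's method and kept as connected
components above a minimum area; within each nucleus the centromere
channel is Otsu-thresholded again and its connected components become
centromere *clusters* (one or more chromosomes whose foci touch).
Counting: the median cluster intensity is taken as the intensity of a
single centromere (most centromeres are separated), each cluster's base
count is its total background-subtracted intensity divided by the
median and rounded; because very bright and very dim clusters carry the
largest ratio errors, the three brightest clusters per nucleus and all
clusters dimmer than the mean are instead counted by their number of
local intensity maxima (at least 1).  The nucleus total N is the sum of
cluster counts.

Ploidy classes from N: <=47 euploid, 48-49 simple aneuploid,
>=50 complex aneuploid.  Mean immunostain (p53) intensity is measured
over each nucleus mask.

All processing is 2D (projected images) with 8-connectivity; the count
is invariant to a positive rescaling of the centromere channel because
every decision is ratio- or rank-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

#: Ploidy classification thresholds on the chromosome count N.
EUPLOID_MAX = 47
SIMPLE_MAX = 49


@dataclass
class FociImage:
    """Co-registered 2D channels: nucleus marker, centromere marker and
    an optional immunostain."""

    nucleus: np.ndarray
    centromere: np.ndarray
    immunostain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nucleus = np.asarray(self.nucleus, dtype=float)
        self.centromere = np.asarray(self.centromere, dtype=float)
        if self.nucleus.shape != self.centromere.shape:
            raise ValueError("nucleus and centromere channels differ in shape")
        if self.immunostain is not None:
            self.immunostain = np.asarray(self.immunostain, dtype=float)
            if self.immunostain.shape != self.nucleus.shape:
                raise ValueError("immunostain channel differs in shape")
        for name in ("nucleus", "centromere"):
            if getattr(self, name).min() < 0:
                raise ValueError(f"{name} channel has negative intensities")

    def to_stack(self) -> np.ndarray:
        chans = [self.nucleus, self.centromere]
        if self.immunostain is not None:
            chans.append(self.immunostain)
        return np.stack(chans).astype(np.float32)


@dataclass
class Cluster:
    """One connected centromere component within a nucleus."""

    nucleus_id: int
    cluster_id: int
    pixels: tuple[np.ndarray, np.ndarray]   # row, col index arrays
    total_intensity: float                  # background-subtracted


@dataclass
class ClusterSet:
    clusters_by_nucleus: dict[int, list[Cluster]] = field(default_factory=dict)
    background_by_nucleus: dict[int, float] = field(default_factory=dict)
    empty_nuclei: list[int] = field(default_factory=list)

    def intensities(self, nucleus_id: int) -> np.ndarray:
        return np.array(
            [c.total_intensity for c in self.clusters_by_nucleus[nucleus_id]]
        )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_nuclei(img: FociImage, min_area_px: int = 200) -> np.ndarray:
    """Label nuclei by Otsu thresholding of the nucleus channel.

    Connected components (8-connectivity) smaller than ``min_area_px``
    are discarded; surviving components are relabeled 1..n.
    """
    chan = img.nucleus
    if np.all(chan == chan.flat[0]):
        raise ValueError("nucleus channel is constant; cannot threshold")
    t = threshold_otsu(chan)
    binary = chan > t
    labels = label(binary, connectivity=2)
    out = np.zeros_like(labels)
    next_id = 1
    for region in regionprops(labels):
        if region.area >= min_area_px:
            out[labels == region.label] = next_id
            next_id += 1
    if next_id == 1:
        warnings.warn("no nuclei found above the minimum area", stacklevel=2)
    return out


def segment_clusters(img: FociImage, nucleus_labels: np.ndarray) -> ClusterSet:
    """Per-nucleus Otsu segmentation of the centromere channel.

    Cluster intensity is the sum of pixel values minus the per-nucleus
    background (the median of sub-threshold centromere pixels inside the
    nucleus mask); without this subtraction the intensity-ratio count
    would be offset-sensitive.  Nuclei with no suprathreshold pixels are
    flagged and get zero clusters.
    """
    cs = ClusterSet()
    cenp = img.centromere
    for nid in range(1, int(nucleus_labels.max()) + 1):
        mask = nucleus_labels == nid
        vals = cenp[mask]
        cs.clusters_by_nucleus[nid] = []
        if vals.size == 0 or np.all(vals == vals[0]):
            cs.background_by_nucleus[nid] = float(vals[0]) if vals.size else 0.0
            cs.empty_nuclei.append(nid)
            continue
        t = threshold_otsu(vals)
        sub = vals[vals <= t]
        background = float(np.median(sub)) if sub.size else 0.0
        cs.background_by_nucleus[nid] = background
        fg = (cenp > t) & mask
        labels = label(fg, connectivity=2)
        if labels.max() == 0:
            cs.empty_nuclei.append(nid)
            continue
        for region in regionprops(labels):
            rows, cols = region.coords[:, 0], region.coords[:, 1]
            total = float((cenp[rows, cols] - background).sum())
            if total <= 0:
                continue
            cs.clusters_by_nucleus[nid].append(
                Cluster(
                    nucleus_id=nid,
                    cluster_id=region.label,
                    pixels=(rows, cols),
                    total_intensity=total,
                )
            )
        if not cs.clusters_by_nucleus[nid]:
            cs.empty_nuclei.append(nid)
    return cs


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def _n_local_maxima(
    img: FociImage,
    cluster: Cluster,
    background: float,
    log_sigma: float,
    min_peak_distance: int,
    rel_threshold: float = 0.2,
) -> int:
    """Count local intensity maxima within one cluster's pixel set.

    Maxima are detected on the negated Laplacian-of-Gaussian response of
    the background-subtracted patch (standard blob enhancement, which
    sharpens near-touching foci close to the diffraction limit), with a
    relative peak threshold to suppress noise maxima.  Both the filter
    and the threshold are scale-free, preserving the count's invariance
    to a positive rescaling of the channel.
    """
    rows, cols = cluster.pixels
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    pad = max(4, min_peak_distance)
    r0p, c0p = max(0, r0 - pad), max(0, c0 - pad)
    patch = img.centromere[r0p : r1 + pad + 1, c0p : c1 + pad + 1] - background
    patch = np.clip(patch, 0, None)
    mask = np.zeros_like(patch, dtype=bool)
    mask[rows - r0p, cols - c0p] = True
    if log_sigma > 0:
        resp = -ndimage.gaussian_laplace(patch, sigma=log_sigma)
    else:
        resp = patch
    peaks = peak_local_max(
        resp,
        min_distance=min_peak_distance,
        labels=mask,
        exclude_border=False,
        threshold_abs=rel_threshold * max(float(resp.max()), 1e-300),
    )
    return max(1, len(peaks))


def count_foci(
    cs: ClusterSet,
    img: FociImage,
    log_sigma: float = 0.6,
    min_peak_distance: int = 1,
) -> pd.DataFrame:
    """Chromosome count N per nucleus from cluster intensities.

    Base count per cluster = round(I_i / I_median) with I_median the
    median cluster intensity (single-centromere proxy).  For the three
    brightest clusters of each nucleus and for every cluster with
    I_i < I_mean the count is replaced by the number of local intensity
    maxima in the cluster (>= 1).  Median and mean are computed once
    from all clusters, before any mitigation.  A nucleus with a single
    cluster is counted by local maxima alone and flagged.

    Returns a frame indexed by nucleus id with columns ``n_clusters``,
    ``N``, ``ploidy_class`` and ``flag``.
    """
    rows = []
    for nid, clusters in sorted(cs.clusters_by_nucleus.items()):
        background = cs.background_by_nucleus.get(nid, 0.0)
        if not clusters:
            rows.append(
                {"nucleus_id": nid, "n_clusters": 0, "N": 0,
                 "ploidy_class": classify_ploidy(0), "flag": "no_clusters"}
            )
            continue
        I = np.array([c.total_intensity for c in clusters])
        flag = ""
        if len(clusters) == 1:
            n = _n_local_maxima(
                img, clusters[0], background, log_sigma, min_peak_distance
            )
            rows.append(
                {"nucleus_id": nid, "n_clusters": 1, "N": int(n),
                 "ploidy_class": classify_ploidy(int(n)),
                 "flag": "single_cluster"}
            )
            continue
        I_median = float(np.median(I))
        I_mean = float(np.mean(I))
        base = np.rint(I / I_median).astype(int)
        # Ties in the top 3 resolve by cluster label order (stable sort
        # on descending intensity).
        order = np.argsort(-I, kind="stable")
        top3 = set(order[:3].tolist())
        counts = np.empty(len(clusters), dtype=int)
        for i, cl in enumerate(clusters):
            if i in top3 or I[i] < I_mean:
                counts[i] = _n_local_maxima(
                    img, cl, background, log_sigma, min_peak_distance
                )
            else:
                counts[i] = max(base[i], 0)
        N = int(counts.sum())
        rows.append(
            {"nucleus_id": nid, "n_clusters": len(clusters), "N": N,
             "ploidy_class": classify_ploidy(N), "flag": flag}
        )
    return pd.DataFrame(rows).set_index("nucleus_id")


def classify_ploidy(n: int) -> str:
    """<=47 euploid; 48-49 simple aneuploid; >=50 complex aneuploid."""
    if n < 0:
        raise ValueError("chromosome count must be >= 0")
    if n <= EUPLOID_MAX:
        return "euploid"
    if n <= SIMPLE_MAX:
        return "simple"
    return "complex"


def mean_nuclear_intensity(
    img: FociImage, nucleus_labels: np.ndarray
) -> pd.Series:
    """Mean immunostain intensity over each nucleus mask."""
    if img.immunostain is None:
        raise ValueError("image has no immunostain channel")
    ids = np.arange(1, int(nucleus_labels.max()) + 1)
    if len(ids) == 0:
        raise ValueError("no nuclei in the label image")
    for nid in ids:
        if not np.any(nucleus_labels == nid):
            raise ValueError(f"nucleus {nid} has an empty mask")
    means = ndimage.mean(img.immunostain, labels=nucleus_labels, index=ids)
    return pd.Series(means, index=pd.Index(ids, name="nucleus_id"), name="mean_immunostain")


def analyze_image(
    img: FociImage,
    min_area_px: int = 200,
    log_sigma: float = 0.6,
    min_peak_distance: int = 1,
) -> pd.DataFrame:
    """Full per-image analysis: segment nuclei and clusters, count
    chromosomes, classify ploidy, and (if present) measure mean nuclear
    immunostain intensity."""
    nuclei = segment_nuclei(img, min_area_px=min_area_px)
    cs = segment_clusters(img, nuclei)
    out = count_foci(
        cs, img, log_sigma=log_sigma, min_peak_distance=min_peak_distance
    )
    if img.immunostain is not None and nuclei.max() > 0:
        out = out.join(mean_nuclear_intensity(img, nuclei))
    return out
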
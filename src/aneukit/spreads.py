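"""Statistics on metaphase-spread chromosome counts.

Karyotype complexity/heterogeneity: for each spread with count ``n_i``,
the deviation is ``d_i = |n_i - nearest(46, 92, 184)| / ploidy(2, 4, 8)``
(the ploidy of the nearest euploid number).  Complexity is the mean of
the ``d_i`` for a condition and heterogeneity their sample SD.  Spreads
are also classed by the raw distance ``|n_i - nearest euploid|``:
0 euploid, 1-3 simple aneuploid, >=4 complex aneuploid.  Note this
cannot detect balanced gain+loss events (a cell with one gain and one
loss still counts 46); spread karyotyping is inherently error-prone.

The missegregation test asks, chromosome by chromosome, whether the
observed number of gain-or-loss events among ``n`` cells departs from
Binomial(n, P), where P is the overall per-(cell, chromosome) aneuploidy
probability.  P is user input; :func:`estimate_aneuploidy_probability`
offers the natural estimator total events / (n_cells * n_chromosomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CHROMOSOME_LENGTHS_GRCH38, EUPLOID_COUNTS, PLOIDIES

#: Minimum spreads per condition before statistics are flagged low-n.
RECOMMENDED_MIN_SPREADS = 30


def nearest_euploid(count: int) -> tuple[int, int]:
    """Nearest euploid chromosome number among 46/92/184 and its ploidy.

    Ties (e.g. 69, equidistant from 46 and 92) resolve to the lower
    euploid number.
    """
    if count < 1:
        raise ValueError("chromosome count must be >= 1")
    dists = [abs(count - e) for e in EUPLOID_COUNTS]
    i = int(np.argmin(dists))  # first minimum -> lower euploid on ties
    return EUPLOID_COUNTS[i], PLOIDIES[i]


def spread_class(count: int) -> str:
    """Euploid / simple / complex from |count - nearest euploid|."""
    e, _ = nearest_euploid(count)
    dev = abs(count - e)
    if dev == 0:
        return "euploid"
    if dev <= 3:
        return "simple"
    return "complex"


@dataclass
class SpreadSet:
    """Integer chromosome counts from one condition's metaphase spreads."""

    condition: str
    counts: list[int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts):
            raise ValueError("all spread counts must be >= 1")

    @property
    def low_n(self) -> bool:
        return len(self.counts) < RECOMMENDED_MIN_SPREADS


@dataclass
class ComplexityStats:
    condition: str
    n: int
    deviations: np.ndarray
    complexity: float        # mean of per-spread deviations
    heterogeneity: float     # sample SD (ddof=1) of per-spread deviations
    class_fractions: dict[str, float] = field(default_factory=dict)
    low_n: bool = False


def complexity_heterogeneity(s: SpreadSet) -> ComplexityStats:
    """Karyotype complexity (mean) and heterogeneity (sample SD) of the
    ploidy-normalized deviations, plus euploid/simple/complex fractions.

    With a single spread the SD is undefined and reported as 0.
    """
    if not s.counts:
        raise ValueError("empty spread set")
    devs = []
    classes = []
    for c in s.counts:
        e, p = nearest_euploid(c)
        devs.append(abs(c - e) / p)
        classes.append(spread_class(c))
    devs = np.array(devs, dtype=float)
    complexity = float(devs.mean())
    heterogeneity = float(devs.std(ddof=1)) if len(devs) > 1 else 0.0
    n = len(devs)
    fractions = {
        k: classes.count(k) / n for k in ("euploid", "simple", "complex")
    }
    return ComplexityStats(
        condition=s.condition,
        n=n,
        deviations=devs,
        complexity=complexity,
        heterogeneity=heterogeneity,
        class_fractions=fractions,
        low_n=s.low_n,
    )


# ---------------------------------------------------------------------------
# Binomial missegregation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinomialTestSpec:
    """Per-chromosome event counts to test against Binomial(n, P)."""

    n: int
    P: float
    observed: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.P <= 1:
            raise ValueError("P must be in [0, 1]")
        for chrom, k in self.observed.items():
            if k < 0 or k > self.n:
                raise ValueError(
                    f"observed events for chromosome {chrom} must be in [0, n]"
                )


def binomial_expected_events(spec: BinomialTestSpec) -> tuple[float, int]:
    """Expected gain-or-loss events per chromosome: (n*P, rounded display).

    E.g. n=116, P=0.21826 gives 25.32, displayed as 25.
    """
    raw = spec.n * spec.P
    return raw, int(round(raw))


def significance_tier(p: float) -> str:
    """Star annotation at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def binomial_missegregation_test(spec: BinomialTestSpec) -> pd.DataFrame:
    """Exact two-sided binomial p-value per chromosome.

    Sidedness follows the minimum-likelihood convention: p is the sum of
    the probabilities of all outcomes no more likely than the observed
    count (scipy's two-sided exact binomial test).
    """
    if not spec.observed:
        raise ValueError("no observed event counts supplied")
    expected_raw, _ = binomial_expected_events(spec)
    rows = []
    for chrom, k in spec.observed.items():
        p = stats.binomtest(int(k), spec.n, spec.P).pvalue
        rows.append(
            {
                "chromosome": chrom,
                "observed": int(k),
                "expected": expected_raw,
                "p_value": float(p),
                "tier": significance_tier(float(p)),
            }
        )
    return pd.DataFrame(rows).set_index("chromosome")


def size_missegregation_correlation(
    observed: Mapping[str, int],
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation of event counts with chromosome length.

    Tests whether larger chromosomes missegregate more often.  Lengths
    default to the embedded GRCh38 table.
    """
    if chrom_lengths is None:
        chrom_lengths = CHROMOSOME_LENGTHS_GRCH38
    chroms = [c for c in observed if c in chrom_lengths]
    if len(chroms) < 5:
        raise ValueError("need event counts for at least 5 known chromosomes")
    events = np.array([observed[c] for c in chroms], dtype=float)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    if np.all(events == events[0]):
        raise ValueError("event counts are constant; correlation undefined")
    rho, p = stats.spearmanr(events, lengths)
    return float(rho), float(p)


def estimate_aneuploidy_probability(
    n_events_total: int, n_cells: int, n_chromosomes: int
) -> float:
    """Plug-in estimate of the per-(cell, chromosome) aneuploidy
    probability: total events / (cells x chromosomes)."""
    if n_cells <= 0 or n_chromosomes <= 0:
        raise ValueError("n_cells and n_chromosomes must be positive")
    if n_events_total < 0:
        raise ValueError("n_events_total must be >= 0")
    return n_events_total / (n_cells * n_chromosomes)


def spreads_to_frame(stats_list: Sequence[ComplexityStats]) -> pd.DataFrame:
    """Summary table: one row per condition."""
    rows = []
    for st in stats_list:
        rows.append(
            {
                "condition": st.condition,
                "n_spreads": st.n,
                "complexity": st.complexity,
                "heterogeneity": st.heterogeneity,
                "frac_euploid": st.class_fractions["euploid"],
                "frac_simple": st.class_fractions["simple"],
                "frac_complex": st.class_fractions["complex"],
                "low_n": st.low_n,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
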
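"""Embedded genome reference tables and shared classification rules.

Shipped as static constants so that nothing in the package requires a
download: per-chromosome protein-coding gene counts (used to apportion
genes in the count simulator) and chromosome lengths (used for the
chromosome-size vs missegregation correlation), both for GRCh38.
"""

from __future__ import annotations

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: Chromosomes used by default for karyotype work: 22 autosomes + X.
#: Y is excluded by default (near-zero expression makes its chromosome
#: score unstable); MT is never a karyotype target.
DEFAULT_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X",)

#: Approximate protein-coding gene counts per chromosome (GRCh38 / Ensembl).
GENES_PER_CHROMOSOME_GRCH38: dict[str, int] = {
    "1": 2046, "2": 1255, "3": 1076, "4": 751, "5": 876, "6": 1048,
    "7": 909, "8": 676, "9": 781, "10": 732, "11": 1286, "12": 1034,
    "13": 321, "14": 604, "15": 597, "16": 866, "17": 1197, "18": 268,
    "19": 1472, "20": 544, "21": 234, "22": 488, "X": 842, "Y": 71,
    "MT": 13,
}

#: Chromosome lengths in base pairs (GRCh38 primary assembly).
CHROMOSOME_LENGTHS_GRCH38: dict[str, int] = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468, "X": 156040895, "Y": 57227415,
}

#: p53 pathway gene program used for the per-cell module score.
P53_PATHWAY_GENES: tuple[str, ...] = (
    "CDKN1A", "GADD45A", "PLK2", "MDM2", "RPS27L", "TRIAP1", "FAS",
)

#: Euploid chromosome totals for human cells at ploidy 2 / 4 / 8.
EUPLOID_COUNTS: tuple[int, ...] = (46, 92, 184)
PLOIDIES: tuple[int, ...] = (2, 4, 8)


def classify_n_aneuploid(n_aneuploid: int) -> str:
    """Ploidy class from the number of gained-or-lost chromosomes.

    0 -> ``euploid``; 1-3 -> ``simple``; >=4 -> ``complex``.
    """
    if n_aneuploid < 0:
        raise ValueError("n_aneuploid must be >= 0")
    if n_aneuploid == 0:
        return "euploid"
    if n_aneuploid <= 3:
        return "simple"
    return "complex"
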
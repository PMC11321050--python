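"""Readers and writers for the toolkit's on-disk formats.

Count matrices travel as MatrixMarket (.mtx) plus ``genes.tsv``
(gene_id, chromosome) and ``cells.tsv`` (cell_id), or as a dense TSV
with genes as rows; spread counts as CSV (condition, count); images as
multi-channel TIFF; calls, scores and truth tables as CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .foci import FociImage
from .karyotype import CountMatrix, KaryotypeCallSet
from .spreads import SpreadSet

#: Fixed float format for CSV output so that reruns are byte-identical.
FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def write_count_matrix(m: CountMatrix, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = outdir / "matrix.mtx"
    genes = outdir / "genes.tsv"
    cells = outdir / "cells.tsv"
    spio.mmwrite(str(mtx), sparse.csr_matrix(m.counts))
    pd.DataFrame(
        {"gene_id": m.gene_ids, "chromosome": m.gene_chromosome.loc[m.gene_ids].values}
    ).to_csv(genes, sep="\t", index=False)
    pd.DataFrame({"cell_id": m.cell_ids}).to_csv(cells, sep="\t", index=False)
    return {"matrix": mtx, "genes": genes, "cells": cells}


def read_count_matrix(indir: str | Path) -> CountMatrix:
    indir = Path(indir)
    counts = np.asarray(spio.mmread(str(indir / "matrix.mtx")).todense())
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t")
    return CountMatrix(
        counts=counts,
        gene_ids=genes["gene_id"].tolist(),
        cell_ids=cells["cell_id"].tolist(),
        gene_chromosome=pd.Series(
            genes["chromosome"].values, index=genes["gene_id"].values
        ),
    )


def write_dense_counts(m: CountMatrix, path: str | Path) -> None:
    """Dense TSV: genes as rows, a ``chromosome`` column, cells as columns."""
    df = m.to_frame()
    df.insert(0, "chromosome", m.gene_chromosome.loc[m.gene_ids].values)
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_dense_counts(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    chrom = df.pop("chromosome").astype(str)
    return CountMatrix(
        counts=df.to_numpy(),
        gene_ids=df.index.tolist(),
        cell_ids=df.columns.tolist(),
        gene_chromosome=chrom,
    )


# ---------------------------------------------------------------------------
# Spreads and small tables
# ---------------------------------------------------------------------------


def write_spreads_csv(spreads: Sequence[SpreadSet], path: str | Path) -> None:
    rows = [
        {"condition": s.condition, "count": c} for s in spreads for c in s.counts
    ]
    pd.DataFrame(rows, columns=["condition", "count"]).to_csv(path, index=False)


def read_spreads_csv(path: str | Path) -> list[SpreadSet]:
    df = pd.read_csv(path)
    return [
        SpreadSet(condition=str(cond), counts=[int(x) for x in grp["count"]])
        for cond, grp in df.groupby("condition", sort=False)
    ]


def write_calls_csv(calls: KaryotypeCallSet, path: str | Path) -> None:
    calls.calls.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_per_cell_csv(calls: KaryotypeCallSet, path: str | Path) -> None:
    calls.per_cell.to_csv(path, index_label="cell_id", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def write_foci_image(img: FociImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), img.to_stack(), photometric="minisblack")


def read_foci_image(
    path: str | Path, channels: dict[str, int] | None = None
) -> FociImage:
    """Read a multi-channel TIFF.  ``channels`` maps channel roles
    (``nucleus``/``centromere``/``immunostain``) to plane indices;
    default order is 0, 1, 2."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        raise ValueError("expected a multi-channel image, got a single plane")
    if channels is None:
        channels = {"nucleus": 0, "centromere": 1}
        if stack.shape[0] > 2:
            channels["immunostain"] = 2
    immu = (
        stack[channels["immunostain"]] if "immunostain" in channels else None
    )
    return FociImage(
        nucleus=stack[channels["nucleus"]],
        centromere=stack[channels["centromere"]],
        immunostain=immu,
    )
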
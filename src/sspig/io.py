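"""Plain-text readers/writers for the simulator and evaluation artifacts.

Genotypes use a PLINK-RAW-like dialect: a header line of marker ids, then
one row per animal with the animal id followed by 0/1/2 calls (NA for
missing).  The sparse pedigree inverse is persisted in 1-based lower-
triangle coordinate format (i, j, value).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .simdata import GenotypeMatrix, MarkerMap, Pedigree


def write_pedigree(pedigree: Pedigree, path):
    pedigree.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path))


def write_marker_map(marker_map: MarkerMap, path):
    marker_map.to_frame().to_csv(path, index=False)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path)
    return MarkerMap(
        marker_id=df["marker"].to_numpy(str),
        chromosome=df["chrom"].to_numpy(np.int64),
        position_bp=df["pos"].to_numpy(np.int64),
        is_chip=df["is_chip"].to_numpy(bool),
        is_qtl=df["is_qtl"].to_numpy(bool),
        founder_af=df["founder_af"].to_numpy(float),
    )


def write_genotypes(genotypes: GenotypeMatrix, path):
    with open(path, "w") as fh:
        fh.write("ANIMAL\t" + "\t".join(map(str, genotypes.marker_ids)) + "\n")
        for aid, row in zip(genotypes.animal_ids, genotypes.calls):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(aid) + "\t" + "\t".join(cells) + "\n")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    return GenotypeMatrix(
        animal_ids=df["ANIMAL"].to_numpy(),
        marker_ids=np.array(df.columns[1:], dtype=object),
        calls=df.iloc[:, 1:].to_numpy(float),
    )


def write_phenotypes(records: pd.DataFrame, path):
    records.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_panel(panel, path):
    Path(path).write_text("\n".join(map(str, panel.marker_ids)) + "\n")


def write_sparse_lower(matrix: sp.spmatrix, path):
    """1-based lower-triangle (i, j, value) coordinate text."""
    coo = sp.tril(matrix).tocoo()
    with open(path, "w") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1} {j + 1} {v:.12g}\n")


def read_sparse_lower(path, n: int) -> sp.csr_matrix:
    i, j, v = np.loadtxt(path, unpack=True, ndmin=2)
    i = i.astype(int) - 1
    j = j.astype(int) - 1
    off = i != j
    rows = np.concatenate([i, j[off]])
    cols = np.concatenate([j, i[off]])
    vals = np.concatenate([v, v[off]])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
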
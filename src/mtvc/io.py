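"""Plain-text readers and writers for the package's file formats.

Genotypes come in two dialects: (a) a headerless whitespace- or
comma-separated 0/1/2 matrix with ``NA`` for missing calls plus sidecar
ID files, and (b) the PLINK ``.raw`` dialect (header row, six leading
metadata columns, then one column per SNP).  Phenotypes, GRMs, chain
dumps and result tables are CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .nuts import ChainResult

__all__ = [
    "read_genotypes_matrix",
    "write_genotypes_matrix",
    "read_genotypes_raw",
    "write_grm",
    "read_grm",
    "write_phenotypes",
    "read_phenotypes",
    "write_chain",
    "write_report",
]


def read_genotypes_matrix(
    path: str | Path,
    animal_ids_path: str | Path | None = None,
    snp_ids_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Dialect (a): headerless matrix of 0/1/2 with NA for missing."""
    raw = pd.read_csv(path, header=None, sep=None, engine="python", na_values=["NA"])
    codes = raw.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    animal_ids = (
        Path(animal_ids_path).read_text().split() if animal_ids_path else []
    )
    snp_ids = Path(snp_ids_path).read_text().split() if snp_ids_path else []
    return GenotypeMatrix(codes=codes, animal_ids=animal_ids, snp_ids=snp_ids)


def write_genotypes_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Writer mirroring dialect (a); sidecar ID files sit next to the
    matrix with ``.animals`` / ``.snps`` suffixes appended."""
    path = Path(path)
    out = g.codes.astype(object)
    out[g.codes == MISSING] = "NA"
    pd.DataFrame(out).to_csv(path, header=False, index=False)
    Path(str(path) + ".animals").write_text("\n".join(g.animal_ids) + "\n")
    Path(str(path) + ".snps").write_text("\n".join(g.snp_ids) + "\n")


def read_genotypes_raw(path: str | Path) -> GenotypeMatrix:
    """PLINK .raw dialect: header row, columns FID IID PAT MAT SEX
    PHENOTYPE then one 0/1/2 column per SNP (NA = missing)."""
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    meta_cols = df.columns[:6]
    snp_cols = df.columns[6:]
    if len(snp_cols) == 0:
        raise ValueError("no SNP columns after the six metadata columns")
    codes = df[snp_cols].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(
        codes=codes,
        animal_ids=[str(v) for v in df[meta_cols[1]]],
        snp_ids=[str(c) for c in snp_cols],
    )


def write_grm(A: np.ndarray, animal_ids: list[str], path: str | Path) -> None:
    """Dense GRM as CSV with animal IDs as header row and first column."""
    pd.DataFrame(A, index=animal_ids, columns=animal_ids).to_csv(path)


def read_grm(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_phenotypes(
    y: np.ndarray, animal_ids: list[str], path: str | Path,
    a_true: np.ndarray | None = None, e_true: np.ndarray | None = None,
) -> None:
    """Phenotype CSV (animal_id, trait_1..trait_t); optional true-value
    sidecar ``<path>.truth.csv`` with a_true/e_true for evaluation."""
    t = y.shape[1]
    cols = [f"trait_{j + 1}" for j in range(t)]
    df = pd.DataFrame(y, columns=cols)
    df.insert(0, "animal_id", animal_ids)
    df.to_csv(path, index=False)
    if a_true is not None:
        truth = pd.DataFrame(
            np.hstack([a_true, e_true if e_true is not None else np.full_like(a_true, np.nan)]),
            columns=[f"a_true_{j + 1}" for j in range(t)]
            + [f"e_true_{j + 1}" for j in range(t)],
        )
        truth.insert(0, "animal_id", animal_ids)
        truth.to_csv(str(path) + ".truth.csv", index=False)


def read_phenotypes(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    ids = [str(v) for v in df["animal_id"]]
    y = df.drop(columns=["animal_id"]).to_numpy(dtype=float)
    return y, ids


def write_chain(
    result: ChainResult | None,
    param_frame: pd.DataFrame,
    path: str | Path,
) -> None:
    """Chain dump: one row per kept draw; named model parameters followed
    by the sampler-statistic columns (left empty for samplers without
    trajectory statistics, e.g. Gibbs)."""
    if result is None:
        stats = pd.DataFrame(
            {
                c: [np.nan] * len(param_frame)
                for c in ("n_leapfrog", "tree_depth", "divergent",
                          "accept_stat", "step_size")
            }
        )
    else:
        stats = pd.DataFrame(
            {
                "n_leapfrog": result.n_leapfrog,
                "tree_depth": result.tree_depth,
                "divergent": result.divergent.astype(int),
                "accept_stat": result.accept_stat,
                "step_size": result.step_size,
            }
        )
    pd.concat([param_frame.reset_index(drop=True), stats], axis=1).to_csv(
        path, index=False
    )


def write_report(report: dict, path: str | Path) -> None:
    """Flat key-value diagnostics report (JSON)."""
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
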
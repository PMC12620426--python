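"""Readers and writers for the pipeline's plain-text interchange formats.

Reports and molecule tables are TSV; gene sets are GMT; expression arrives
either as a genes x samples TSV or as an MTX triplet (matrix.mtx, genes.tsv,
barcodes.tsv) with a separate annotation TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .signature import ExpressionBundle

__all__ = [
    "read_reports", "write_reports", "read_molecules", "write_molecules",
    "read_gmt", "write_gmt", "read_expression_tsv", "read_expression_mtx",
    "write_expression_mtx", "read_gene_list", "read_scored_gene_list",
    "write_json",
]


def read_reports(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"CASEID": str}, keep_default_na=True)


def write_reports(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_molecules(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"cid", "drugname", "smiles"}
    if not required.issubset(df.columns):
        raise ValueError(f"molecule table needs columns {sorted(required)}")
    return df


def write_molecules(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description or name, *genes]) + "\n")


def read_expression_tsv(matrix_path: str | Path, annotation_path: str | Path,
                        mode: str = "bulk") -> ExpressionBundle:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return ExpressionBundle(matrix=matrix, annotation=ann, mode=mode)


def read_expression_mtx(mtx_path: str | Path, genes_path: str | Path,
                        barcodes_path: str | Path,
                        annotation_path: str | Path,
                        mode: str = "single_cell") -> ExpressionBundle:
    mat = mmread(mtx_path).toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
    matrix = pd.DataFrame(mat, index=genes, columns=cells)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return ExpressionBundle(matrix=matrix, annotation=ann, mode=mode)


def write_expression_mtx(bundle: ExpressionBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", csr_matrix(bundle.matrix.to_numpy()))
    pd.Series(bundle.matrix.index).to_csv(out / "genes.tsv", sep="\t",
                                          index=False, header=False)
    pd.Series(bundle.matrix.columns).to_csv(out / "barcodes.tsv", sep="\t",
                                            index=False, header=False)
    bundle.annotation.to_csv(out / "annotation.tsv", sep="\t")


def read_gene_list(path: str | Path) -> set[str]:
    return {ln.strip().upper() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")}


def read_scored_gene_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "score"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
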
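"""Reading and writing the pipeline's on-disk formats.

Expression travels as MatrixMarket MTX (+ genes.tsv / cells.tsv index files)
or as a dense TSV; metadata as CSV; detections, tracks and result tables as
TSV; the manifest and ground truth as JSON; chamber images as 16-bit
grayscale TIFF named ``chip{c}_chamber{n}_{channel}_t{h}.tif``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .qc import ExpressionMatrix

__all__ = [
    "write_expression",
    "read_expression",
    "write_metadata",
    "read_metadata",
    "write_image",
    "write_json",
    "sha256_of",
]


def write_expression(expr: ExpressionMatrix, out_dir, fmt: str = "mtx", prefix: str = "expr"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        spio.mmwrite(str(out_dir / f"{prefix}.mtx"), sparse.coo_matrix(expr.values))
        pd.Series(expr.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t",
                                        index=False, header=False)
        pd.Series(expr.cell_ids).to_csv(out_dir / "cells.tsv", sep="\t",
                                        index=False, header=False)
        return out_dir / f"{prefix}.mtx"
    if fmt == "tsv":
        path = out_dir / f"{prefix}.tsv"
        expr.to_frame().to_csv(path, sep="\t", float_format="%.10g")
        return path
    raise ValueError("fmt must be 'mtx' or 'tsv'")


def read_expression(path, unit: str = "counts") -> ExpressionMatrix:
    path = Path(path)
    if path.suffix == ".mtx":
        values = np.asarray(spio.mmread(str(path)).todense(), dtype=float)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(path.parent / "cells.tsv", sep="\t", header=None)[0].tolist()
        return ExpressionMatrix(values, genes, cells, unit=unit)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(frame.to_numpy(dtype=float), list(frame.index),
                            list(frame.columns), unit=unit)


def write_metadata(meta: pd.DataFrame, path):
    meta.to_csv(path, float_format="%.10g")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_image(image, path):
    import tifffile

    tifffile.imwrite(str(path), np.clip(image.pixels, 0, 65535).astype(np.uint16))


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
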
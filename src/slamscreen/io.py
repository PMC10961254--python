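"""On-disk formats: MTX count bundles and stage manifests.

Count matrices travel as a directory of MatrixMarket files plus row/column
TSVs (``cells.tsv`` = obs including QC columns, ``genes.tsv`` = var), so
every artifact stays plain text and round-trips through ``scipy.io``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import pandas as pd
from scipy import io as scio
from scipy import sparse

_LAYERS = ("nascent", "exonic_whole", "exonic_nascent")


def save_matrices(adata: ad.AnnData, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(str(outdir / "whole.mtx"), sparse.csr_matrix(adata.X))
    for layer in _LAYERS:
        if layer in adata.layers:
            scio.mmwrite(
                str(outdir / f"{layer}.mtx"),
                sparse.csr_matrix(adata.layers[layer]),
            )
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    return outdir


def load_matrices(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(scio.mmread(str(indir / "whole.mtx")))
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    layers = {}
    for layer in _LAYERS:
        path = indir / f"{layer}.mtx"
        if path.exists():
            layers[layer] = sparse.csr_matrix(scio.mmread(str(path)))
    return ad.AnnData(X=X, obs=obs, var=var, layers=layers)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    stage: str,
    outdir: str | Path,
    config_snapshot: dict,
    inputs: dict[str, str | Path],
) -> Path:
    """Record what a stage ran with: config values and input file hashes."""
    from . import __version__

    manifest = {
        "stage": stage,
        "version": __version__,
        "config": config_snapshot,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
    }
    path = Path(outdir) / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    tmp.replace(path)
    return path
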
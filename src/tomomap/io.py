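"""Readers and writers for the pipeline's plain-text formats.

Cell counts travel as the 10x triplet dialect (Matrix Market
``matrix.mtx`` with genes as rows and cells as columns, plus
``barcodes.tsv`` and ``features.tsv``); section references, truth
tables, labels, QC reports and result matrices as TSV; gene sets as
newline-delimited ID files; configs as YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from anndata import AnnData
from scipy import io as spio
from scipy import sparse


def write_10x_triplet(adata: AnnData, outdir) -> Path:
    """Write cells x genes counts as a 10x-style uncompressed triplet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    mat = X.T.tocoo()  # genes x cells, 10x orientation
    if np.allclose(mat.data, np.rint(mat.data)):
        mat = mat.astype(np.int64)
    spio.mmwrite(outdir / "matrix.mtx", mat)
    (outdir / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in adata.obs_names))
    feats = pd.DataFrame({
        "gene_id": adata.var_names,
        "gene_symbol": adata.var_names,
        "feature_type": "Gene Expression",
    })
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    return outdir


def read_10x_triplet(indir) -> AnnData:
    """Read an uncompressed 10x triplet directory into AnnData."""
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").tocsr().T.tocsr()  # cells x genes
    barcodes = (indir / "barcodes.tsv").read_text().split()
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    gene_ids = features[0].astype(str).tolist()
    adata = AnnData(X=mat,
                    obs=pd.DataFrame(index=barcodes),
                    var=pd.DataFrame(index=gene_ids))
    return adata


def write_section_reference(ref: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ref.to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_section_reference(path) -> pd.DataFrame:
    """Gene x section counts; columns coerced to integer section IDs."""
    ref = pd.read_csv(path, sep="\t", index_col=0)
    ref.columns = [int(c) for c in ref.columns]
    return ref


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_labels(path) -> pd.Series:
    """Cluster labels from a two-column TSV (cell_id, cluster)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels file needs columns cell_id and cluster")
    return pd.Series(df.iloc[:, 1].astype(str).to_numpy(),
                     index=df.iloc[:, 0].astype(str), name="cluster")


def write_labels(labels: pd.Series, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"cell_id": labels.index, "cluster": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False)
    return path


def read_gene_set(path) -> set[str]:
    """Newline-delimited gene IDs (blank lines ignored)."""
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}


def write_gene_set(genes, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))
    return path


def write_config_yaml(config, path) -> Path:
    """Echo a simulation config (dataclass) as YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = asdict(config)
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def read_config_yaml(path, config_cls):
    data = yaml.safe_load(Path(path).read_text())
    for k, v in list(data.items()):
        if isinstance(v, list):
            data[k] = tuple(v)
    return config_cls(**data)
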
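"""Readers and writers for the formats the tool touches.

Matrices come in as dense TSV/CSV (features as rows, observation header) or
as a MatrixMarket triplet (matrix.mtx + features.tsv + barcodes.tsv,
CellRanger style, orientation auto-detected from the companion files).
Taxonomies go out as JSON (canonical, lossless) and Newick (derived;
branch length = parent height - child height).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .matrix import ExpressionMatrix
from .taxonomy import Taxonomy, TaxonomyNode

__all__ = [
    "read_matrix", "write_matrix", "read_group_labels", "read_phenotypes",
    "write_taxonomy", "load_taxonomy", "taxonomy_to_newick",
    "default_config_dict", "load_config",
]


# ----------------------------------------------------------------------
# matrices
# ----------------------------------------------------------------------

def _read_ids(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None)
    return [str(x) for x in df.iloc[:, 0]]


def read_matrix(path, fmt: str | None = None,
                group_labels: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read an expression matrix; format from the extension unless given.

    fmt: "tsv", "csv" or "mtx_triplet" (path points at the .mtx file, with
    features.tsv/genes.tsv and barcodes.tsv companions next to it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    if fmt is None:
        ext = path.suffix.lower()
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
               ".mtx": "mtx_triplet"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer matrix format from {path.name!r}")
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"{path}: parse error: {exc}") from exc
        if df.shape[1] == 0:
            raise ValueError(f"{path}: no observation columns")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric values: {exc}") from exc
        return ExpressionMatrix(values, [str(i) for i in df.index],
                                [str(c) for c in df.columns], group_labels)
    if fmt == "mtx_triplet":
        feats_path = None
        for cand in ("features.tsv", "genes.tsv"):
            if (path.parent / cand).exists():
                feats_path = path.parent / cand
                break
        bc_path = path.parent / "barcodes.tsv"
        if feats_path is None or not bc_path.exists():
            raise ValueError(f"{path}: missing features.tsv/genes.tsv or barcodes.tsv")
        feats = _read_ids(feats_path)
        barcodes = _read_ids(bc_path)
        m = scipy.io.mmread(path)
        values = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=float)
        if values.shape == (len(feats), len(barcodes)):
            pass
        elif values.shape == (len(barcodes), len(feats)):
            import logging
            logging.getLogger("k2tax").info(
                "%s stored observations x features; transposing", path.name)
            values = values.T
        else:
            raise ValueError(
                f"{path}: shape {values.shape} matches neither "
                f"({len(feats)}, {len(barcodes)}) nor its transpose")
        return ExpressionMatrix(values, feats, barcodes, group_labels)
    raise ValueError(f"unknown matrix format {fmt!r}")


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.to_frame().to_csv(path, sep=sep)


def read_group_labels(path) -> dict[str, str]:
    """Two-column TSV (no header): observation_id <tab> group."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_phenotypes(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Observations x variables TSV with a '#type' declaration row.

    The row indexed '#type' declares continuous/categorical per variable
    and is removed from the returned frame.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "#type" not in df.index:
        raise ValueError(f"{path}: missing '#type' declaration row")
    types = {c: str(df.loc["#type", c]).strip().lower() for c in df.columns}
    bad = {c: t for c, t in types.items() if t not in ("continuous", "categorical")}
    if bad:
        raise ValueError(f"{path}: invalid types {bad}")
    data = df.drop(index="#type")
    for c, t in types.items():
        if t == "continuous":
            data[c] = pd.to_numeric(data[c], errors="raise")
    return data, types


# ----------------------------------------------------------------------
# taxonomies
# ----------------------------------------------------------------------

_NEWICK_BAD = re.compile(r"[\s(),:;\[\]']")


def _safe(name: str) -> str:
    return _NEWICK_BAD.sub("_", name)


def taxonomy_to_newick(taxonomy: Taxonomy) -> str:
    """Newick with branch lengths parent height - child height (>= 0).

    Multi-item terminal leaves become a polytomy of their member items with
    tips at height 0.
    """

    def render(node: TaxonomyNode, parent_h: float | None) -> str:
        h = node.height
        bl = "" if h is None or parent_h is None else f":{max(parent_h - h, 0.0):.10g}"
        if h is not None and parent_h is not None and parent_h - h < -1e-12:
            raise ValueError("negative branch length (height monotonicity violated)")
        if node.is_leaf:
            if len(node.member_items) == 1:
                return f"{_safe(node.member_items[0])}{bl}"
            tip_bl = "" if h is None else f":{h:.10g}"
            tips = ",".join(f"{_safe(m)}{tip_bl}" for m in node.member_items)
            return f"({tips}){_safe(node.node_id)}{bl}"
        inner = ",".join(render(c, h) for c in node.children)
        return f"({inner}){_safe(node.node_id)}{bl}"

    root = taxonomy.root
    body = render(root, None)
    suffix = ":0" if root.height is not None else ""
    if root.is_leaf and len(root.member_items) == 1:
        return f"({body}){suffix};"
    return f"{body}{suffix};"


def write_taxonomy(taxonomy: Taxonomy, outdir, provenance: dict | None = None) -> None:
    """Write taxonomy.json (canonical) and taxonomy.nwk (derived) into outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "taxonomy.json", "w") as fh:
        json.dump(taxonomy.to_dict(), fh, indent=1)
        fh.write("\n")
    with open(outdir / "taxonomy.nwk", "w") as fh:
        fh.write(taxonomy_to_newick(taxonomy) + "\n")
    if provenance is not None:
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1)
            fh.write("\n")


def load_taxonomy(path) -> Taxonomy:
    with open(path) as fh:
        return Taxonomy.from_dict(json.load(fh))


def provenance_block(config: dict) -> dict:
    import importlib.metadata
    import sklearn
    import scipy

    try:
        version = importlib.metadata.version("k2tax")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    return {"k2tax": version, "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "scikit-learn": sklearn.__version__,
            "config": config}


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def default_config_dict() -> dict:
    from .taxonomy import RunConfig
    d = RunConfig().to_dict()
    d["min_items"] = None   # resolved by mode at run time
    return d


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    allowed = set(default_config_dict())
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg
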
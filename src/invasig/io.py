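"""Readers and writers for the pipeline's plain-text formats.

Counts travel as genes x samples TSV (first column gene ids, header of
sample ids) or Matrix Market triplets with sidecar row/column id files;
gene sets as GMT; signatures as two-column TSV.  All writers produce
files their paired readers parse losslessly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from invasig.signatures import GeneSignature

__all__ = [
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
    "config_hash",
    "write_manifest",
]


def write_counts(counts: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write a genes x samples count table as TSV or MTX triplet.

    MTX output creates ``<stem>.mtx`` plus ``<stem>.rows.tsv`` and
    ``<stem>.cols.tsv`` id sidecars.
    """
    path = Path(path)
    if fmt == "tsv":
        counts.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "mtx":
        stem = path.with_suffix("")
        spio.mmwrite(str(stem), sparse.coo_matrix(counts.to_numpy()))
        pd.Series(counts.index).to_csv(f"{stem}.rows.tsv", sep="\t", index=False, header=False)
        pd.Series(counts.columns).to_csv(f"{stem}.cols.tsv", sep="\t", index=False, header=False)
    else:
        raise ValueError("format must be 'tsv' or 'mtx'")


def read_counts(path, fmt: str = "tsv", integer: bool = True) -> pd.DataFrame:
    """Read a count table, enforcing id uniqueness and shape consistency."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        if df.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = df.to_numpy()
    elif fmt == "mtx":
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        mat = spio.mmread(f"{stem}.mtx")
        rows = pd.read_csv(f"{stem}.rows.tsv", sep="\t", header=None)[0].tolist()
        cols = pd.read_csv(f"{stem}.cols.tsv", sep="\t", header=None)[0].tolist()
        arr = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if arr.shape != (len(rows), len(cols)):
            raise ValueError("MTX dimensions do not match id files")
        if len(set(rows)) != len(rows):
            raise ValueError("duplicate gene ids")
        df = pd.DataFrame(arr, index=rows, columns=cols)
        values = arr
    else:
        raise ValueError("format must be 'tsv' or 'mtx'")
    if integer:
        if not np.allclose(values, np.rint(values)):
            raise ValueError("raw counts must be integers")
        df = df.astype(np.int64)
    return df


def read_gmt(path) -> dict:
    """Parse a GMT file into {set name: member list} (members deduplicated)."""
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {ln}: expected name, description and >= 1 member")
        name, _desc, *members = fields
        members = [m for m in members if m]
        uniq = list(dict.fromkeys(members))
        if len(uniq) < len(members):
            warnings.warn(f"GMT set {name!r}: {len(members) - len(uniq)} duplicate members dropped")
        sets[name] = uniq
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *members]) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_signature(sig: GeneSignature, path) -> None:
    """Two-column TSV: gene_id, ICI-regulation direction."""
    df = pd.DataFrame(sorted(sig.members.items()), columns=["gene_id", "direction"])
    df.to_csv(path, sep="\t", index=False)


def read_signature(path, name: str | None = None) -> GeneSignature:
    df = pd.read_csv(path, sep="\t")
    return GeneSignature(name=name or Path(path).stem,
                         members=dict(zip(df["gene_id"], df["direction"])))


def config_hash(config: dict) -> str:
    """Stable hash of a (nested, JSON-serializable) configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, outputs: dict) -> dict:
    """Provenance manifest: config hash, seed, software version, artifacts."""
    from invasig import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
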
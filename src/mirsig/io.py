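"""Plain-text interchange formats.

* expression TSV: ``#``-prefixed metadata header lines, then a header row
  (``feature_id`` + sample ids) and one row per feature; empty cell = missing;
  floats at 9 significant digits
* group map TSV: two columns (sample_id, group)
* edge list TSV: three columns (mirna, gene, source)
* GMT: set name, description, member genes, tab-separated
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GROUPS
from .enrichment import GeneSetCollection

FLOAT_FMT = "%.9g"


def _write_meta(fh, meta: Mapping[str, object] | None) -> None:
    for k, v in (meta or {}).items():
        fh.write(f"# {k}: {v}\n")


def read_meta(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_expression_tsv(ds: ExpressionDataset, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        fh.write("feature_id\t" + "\t".join(ds.sample_ids) + "\n")
        mat = ds.matrix()
        for i, fid in enumerate(ds.feature_ids):
            cells = ["" if not np.isfinite(v) else FLOAT_FMT % v for v in mat[i]]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


def write_group_map(ds: ExpressionDataset, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        fh.write("sample_id\tgroup\n")
        for s in ds.sample_ids:
            fh.write(f"{s}\t{ds.groups[s]}\n")


def read_group_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return pd.Series(df["group"].values, index=df["sample_id"].values)


def read_expression_tsv(path: str | Path, group_map_path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate feature ids {dupes[:5]}")
    groups = read_group_map(group_map_path)
    missing = [s for s in df.columns if s not in groups.index]
    if missing:
        raise ValueError(f"{group_map_path}: samples without group label: {missing}")
    return ExpressionDataset(values=df.astype(float), groups=groups.loc[df.columns],
                             dataset_id=dataset_id or path.stem)


def write_edge_list(edges, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write (mirna, gene, sources) triples, one row per (edge, source)."""
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        fh.write("mirna\tgene\tsource\n")
        for mirna, gene, sources in edges:
            for s in sorted(sources) if not isinstance(sources, str) else [sources]:
                fh.write(f"{mirna}\t{gene}\t{s}\n")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    want = ["mirna", "gene", "source"]
    if list(df.columns) != want:
        raise ValueError(f"{path}: expected columns {want}, got {list(df.columns)}")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: malformed rows at lines {list(bad + 2)}")
    return df


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            fh.write("\t".join([name, "na", *sorted(collection.sets[name])]) + "\n")


def read_id_list(path: str | Path) -> set[str]:
    """One id per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]
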
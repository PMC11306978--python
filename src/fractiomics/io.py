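"""Readers and writers for the formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 is the only
1-based closed surface and the conversion happens at the boundary. Readers
validate rather than silently repair: malformed lines are collected into an
error report (strict mode aborts on the first one) and duplicate identifiers
are rejected.

TSV dialect: tab-separated, UTF-8, ``#``-prefixed comment lines allowed,
no quoting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "DuplicatePair",
    "TeRecord",
    "Gff3Error",
    "read_gff3",
    "write_gff3",
    "read_matrix_tsv",
    "read_anchors",
    "read_trees_tsv",
    "write_trees_tsv",
    "write_report",
]


@dataclass
class GeneRecord:
    """A gene with coordinates (0-based half-open) and retention metadata."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    subgenome: str = "unassigned"  # {LF, MF, unassigned}
    status: str = "singleton"  # {duplicate, singleton, lost}
    ortholog_id: str | None = None
    orthogroup_id: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end (0-based half-open)")


@dataclass
class DuplicatePair:
    """Two syntenic copies of one ancestral gene, one per subgenome."""

    pair_id: str
    lf_gene_id: str
    mf_gene_id: str
    ks: float
    ka: float
    window_id: str | None = None

    def __post_init__(self) -> None:
        if self.lf_gene_id == self.mf_gene_id:
            raise ValueError(f"{self.pair_id}: pair members must differ")
        if self.ks < 0 or self.ka < 0:
            raise ValueError(f"{self.pair_id}: substitution rates must be nonnegative")

    @property
    def omega(self) -> float:
        return self.ka / self.ks if self.ks > 0 else np.nan


@dataclass
class TeRecord:
    """A transposable-element copy with optional divergence to consensus."""

    te_id: str
    chrom: str
    start: int
    end: int
    family: str = "unknown"
    divergence: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.te_id}: start must be < end")
        if self.divergence is not None and not (0 <= self.divergence < 0.75):
            raise ValueError(f"{self.te_id}: divergence must lie in [0, 0.75)")


class Gff3Error(ValueError):
    """Raised in strict mode on the first malformed GFF3 line."""


def _parse_attributes(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(
    path: str | Path,
    feature_filter: str | set[str] | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Read a GFF3 file into a 0-based half-open feature table.

    Returns ``(features, errors)``: a DataFrame with columns chrom, source,
    feature, start, end, score, strand, frame, attributes (dict) plus an
    ``id`` column from the ID attribute; and the list of malformed-line
    messages. In strict mode the first malformed line raises :class:`Gff3Error`.
    ``feature_filter`` restricts to the given feature type(s).
    """
    path = Path(path)
    if isinstance(feature_filter, str):
        feature_filter = {feature_filter}
    rows, errors = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                msg = f"line {lineno}: expected 9 tab-separated fields, got {len(parts)}"
                if strict:
                    raise Gff3Error(msg)
                errors.append(msg)
                continue
            chrom, source, feature, start_s, end_s, score, strand, frame, attrs = parts
            if feature_filter and feature not in feature_filter:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                msg = f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                if strict:
                    raise Gff3Error(msg)
                errors.append(msg)
                continue
            if end1 < start1 or start1 < 1:
                msg = f"line {lineno}: invalid 1-based interval [{start1}, {end1}]"
                if strict:
                    raise Gff3Error(msg)
                errors.append(msg)
                continue
            attr = _parse_attributes(attrs)
            rows.append(
                {
                    "chrom": chrom,
                    "source": source,
                    "feature": feature,
                    "start": start1 - 1,  # to 0-based half-open
                    "end": end1,
                    "score": score,
                    "strand": strand,
                    "frame": frame,
                    "attributes": attr,
                    "id": attr.get("ID", ""),
                }
            )
    cols = ["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attributes", "id"]
    return pd.DataFrame(rows, columns=cols), errors


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write a 0-based half-open feature table back to 1-based closed GFF3."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples():
            attrs = row.attributes
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) if attrs else "."
            fh.write(
                f"{row.chrom}\t{row.source}\t{row.feature}\t{row.start + 1}\t{row.end}\t"
                f"{row.score}\t{row.strand}\t{row.frame}\t{attr_s}\n"
            )


def read_matrix_tsv(
    path: str | Path,
    required_columns: list[str] | None = None,
    index_col: str | int = 0,
    numeric: bool = True,
) -> pd.DataFrame:
    """Read a TSV table with schema validation.

    Rejects duplicate row identifiers, validates ``required_columns`` and (for
    ``numeric=True``) coerces all data columns to float, raising on values
    that do not parse rather than silently inserting NA.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col, dtype=str)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {missing}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"{path}: duplicated row identifiers, e.g. {dups}")
    if numeric:
        try:
            df = df.astype(float)
        except ValueError as e:
            raise ValueError(f"{path}: non-numeric value in a numeric matrix: {e}") from e
    return df


def condition_map(columns) -> dict[str, int]:
    """Parse ``condition_replicate`` headers into {condition: n_replicates}."""
    out: dict[str, int] = {}
    for c in columns:
        cond = c.rsplit("_", 1)[0]
        out[cond] = out.get(cond, 0) + 1
    return out


def read_anchors(path: str | Path) -> pd.DataFrame:
    """Read a collinearity anchor table (ref_gene, ref_chrom, ref_index, copies)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ref_gene": str})
    required = ["ref_gene", "ref_chrom", "ref_index", "copy_a_gene", "copy_b_gene"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: anchor table missing column(s): {missing}")
    df["ref_index"] = df["ref_index"].astype(int)
    if df["ref_gene"].duplicated().any():
        raise ValueError(f"{path}: duplicated reference gene ids")
    return df


def read_trees_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (pair_id, newick) into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["pair_id", "newick"]:
        raise ValueError(f"{path}: expected columns pair_id, newick")
    if df["pair_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated pair ids")
    return dict(zip(df["pair_id"], df["newick"]))


def write_trees_tsv(trees: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pair_id\tnewick\n")
        for pid in sorted(trees):
            fh.write(f"{pid}\t{trees[pid]}\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonify(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    return obj


def write_report(results: dict, outdir: str | Path) -> tuple[Path, Path]:
    """Write a machine-readable JSON summary and a human-readable text table.

    ``results`` is a nested dict of per-stage summaries. Sections that a
    partial run did not produce should be present with value ``None``; the
    text report marks them as missing explicitly. Output is deterministic
    (sorted keys, fixed float formatting), so reruns on identical inputs are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    txt_path = outdir / "report.txt"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(results), fh, indent=2, sort_keys=True)
        fh.write("\n")

    def fmt(v):
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    lines = ["fractiomics report", "=" * 18, ""]
    for section in sorted(results):
        lines.append(f"[{section}]")
        value = results[section]
        if value is None:
            lines.append("  MISSING: this stage did not run")
        elif isinstance(value, dict):
            for k in sorted(value):
                v = value[k]
                if isinstance(v, dict):
                    lines.append(f"  {k}:")
                    for k2 in sorted(v):
                        lines.append(f"    {k2}: {fmt(v[k2])}")
                else:
                    lines.append(f"  {k}: {fmt(v)}")
        else:
            lines.append(f"  {fmt(value)}")
        lines.append("")
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
    return json_path, txt_path
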
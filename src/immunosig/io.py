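"""TSV dialects, GEO series-matrix reading, and provenance headers.

All files are UTF-8, tab-separated, with '#'-prefixed comment lines
permitted at the top; identifiers must be non-empty and unique.  Every
file written by the pipeline starts with a provenance comment block
(package version, seed, config hash) sufficient to re-run its stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError


def provenance_header(stage: str, seed=None, config: dict | None = None) -> str:
    from . import __version__

    lines = [f"# immunosig {__version__}", f"# stage: {stage}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha256: {digest}")
    return "\n".join(lines) + "\n"


def _data_lines(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line.split("\t")))
    if not out:
        raise ParseError(f"{path}: no data lines")
    return out


def read_expression(path) -> pd.DataFrame:
    """Read a probes x samples expression TSV (first column: probe id)."""
    lines = _data_lines(path)
    header_no, header = lines[0]
    sample_ids = header[1:]
    if not sample_ids or any(not s for s in sample_ids):
        raise ParseError(f"{path}:{header_no}: empty sample identifier in header")
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}:{header_no}: duplicate sample identifiers")
    probe_ids, rows = [], []
    seen = set()
    for lineno, fields in lines[1:]:
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        pid = fields[0]
        if not pid:
            raise ParseError(f"{path}:{lineno}: empty probe identifier")
        if pid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate probe identifier {pid!r}")
        seen.add(pid)
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        probe_ids.append(pid)
    return pd.DataFrame(np.asarray(rows), index=probe_ids, columns=sample_ids)


def write_expression(expr: pd.DataFrame, path, header: str = "") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("probe_id\t" + "\t".join(map(str, expr.columns)) + "\n")
        for pid, row in zip(expr.index, expr.to_numpy()):
            fh.write(str(pid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (sample_id, label, dfs_months, event)."""
    df = _read_table(path, ["sample_id", "label", "dfs_months", "event"])
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample identifiers in metadata")
    df["dfs_months"] = df["dfs_months"].astype(float)
    df["event"] = df["event"].astype(int)
    if not df["event"].isin((0, 1)).all():
        raise ParseError(f"{path}: event flags must be 0 or 1")
    return df


def write_metadata(meta: pd.DataFrame, path, header: str = "") -> None:
    _write_table(meta, path, header)


def read_annotation(path) -> pd.DataFrame:
    """Read probe annotation (probe_id, gene_symbol; empty symbol allowed)."""
    df = _read_table(path, ["probe_id", "gene_symbol"])
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    if df["probe_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate probe identifiers in annotation")
    return df


def write_annotation(annotation: pd.DataFrame, path, header: str = "") -> None:
    _write_table(annotation, path, header)


def read_genesets(path, fmt: str = "tsv") -> dict[str, dict]:
    """Read gene sets as term_id -> {"name", "genes": set}.

    fmt='tsv': columns (term_id, term_name, gene_symbol), one pair per
    row.  fmt='gaf': GAF-lite with columns (db, object_id, symbol,
    qualifier, go_id); only symbol and go_id are consumed.
    """
    sets: dict[str, dict] = {}
    for lineno, fields in _data_lines(path)[1 if fmt == "tsv" else 0:]:
        if fmt == "tsv":
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            term, name, gene = fields
        elif fmt == "gaf":
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 GAF fields")
            gene, term, name = fields[2], fields[4], ""
        else:
            raise ValidationError("fmt must be 'tsv' or 'gaf'")
        if not term or not gene:
            raise ParseError(f"{path}:{lineno}: empty term or gene symbol")
        entry = sets.setdefault(term, {"name": name, "genes": set()})
        if name:
            entry["name"] = name
        entry["genes"].add(gene)
    return sets


def write_genesets(sets: dict[str, dict], path, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("term_id\tterm_name\tgene_symbol\n")
        for term_id in sorted(sets):
            entry = sets[term_id]
            for gene in sorted(entry["genes"]):
                fh.write(f"{term_id}\t{entry.get('name', '')}\t{gene}\n")


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format qPCR Ct table (sample_id, group, gene, ct)."""
    df = _read_table(path, ["sample_id", "group", "gene", "ct"])
    df["ct"] = df["ct"].astype(float)
    return df


def read_series_matrix(path) -> pd.DataFrame:
    """Extract the expression block of a GEO series-matrix text file.

    Header lines are prefixed '!'; the matrix lies between the
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
    sentinels, with quoted identifiers in the first column.
    """
    inside = False
    header: list[str] | None = None
    probe_ids, rows = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.lower().startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.lower().startswith("!series_matrix_table_end"):
                inside = False
                break
            if not inside or not line:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: ragged series-matrix row")
            probe_ids.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric cell") from None
    if header is None:
        raise ParseError(f"{path}: no series-matrix table block found")
    return pd.DataFrame(np.asarray(rows), index=probe_ids, columns=header[1:])


def read_table(path) -> pd.DataFrame:
    """Read a generic headered TSV (comment lines allowed), all columns str."""
    lines = _data_lines(path)
    _, header = lines[0]
    rows = []
    for lineno, fields in lines[1:]:
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        rows.append(fields)
    return pd.DataFrame(rows, columns=header)


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    lines = _data_lines(path)
    header_no, header = lines[0]
    if header != columns:
        raise ParseError(
            f"{path}:{header_no}: expected header {columns}, got {header}"
        )
    rows = []
    for lineno, fields in lines[1:]:
        if len(fields) != len(columns):
            raise ParseError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(fields)}"
            )
        rows.append(fields)
    return pd.DataFrame(rows, columns=columns)


def _write_table(df: pd.DataFrame, path, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
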
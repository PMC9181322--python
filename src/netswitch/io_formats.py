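"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: GEO series-matrix (the ``!``-prefixed metadata dialect
with a ``!series_matrix_table_begin`` ... ``!series_matrix_table_end``
block), plain expression TSV plus a two-column sample->group TSV, GMT gene
sets, and 3/4-column TF->target edge tables.  All readers reject malformed
input rather than silently repairing it; every writer produces output its
paired reader accepts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples intensity table with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  Linear
        scale unless ``is_log2`` is set; the flag exists to prevent
        double-logging.
    sample_group
        Series mapping sample id -> group label; must cover every sample.
    is_log2
        Whether ``values`` is already on the log2 scale.
    """

    values: pd.DataFrame
    sample_group: pd.Series
    is_log2: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.sample_group, pd.Series):
            self.sample_group = pd.Series(dict(self.sample_group))
        dup_g = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_g):
            raise FormatError(f"duplicate gene ids: {sorted(map(str, dup_g))}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_s):
            raise FormatError(f"duplicate sample ids: {sorted(map(str, dup_s))}")
        missing = [s for s in self.values.columns if s not in self.sample_group.index]
        if missing:
            raise FormatError(f"samples without a group label: {missing}")
        self.sample_group = self.sample_group.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.sample_group.index[self.sample_group == group])

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy (identity if already log2)."""
        if self.is_log2:
            return self
        vals = self.values.to_numpy()
        if (vals <= 0).any():
            raise ValueError("cannot log2-transform a matrix with non-positive entries; "
                             "run bsce_preprocess or floor them first")
        return ExpressionMatrix(np.log2(self.values), self.sample_group, is_log2=True)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_group,
                                is_log2=self.is_log2)


@dataclass
class GeneSetCollection:
    """Named gene lists with optional descriptions (GMT-writable)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if any((not isinstance(g, str)) or g == "" for g in genes):
                raise FormatError(f"gene set {name!r} contains empty/non-string genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path, group_path=None) -> None:
    """Write the values table (first column = gene id) and, optionally, the
    two-column sample->group table."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    if group_path is not None:
        write_group_tsv(matrix.sample_group, group_path)


def write_group_tsv(sample_group: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for sample, group in sample_group.items():
            fh.write(f"{sample}\t{group}\n")


def read_group_tsv(path) -> pd.Series:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rows.append(parts)
    if not rows:
        raise FormatError(f"{path}: empty group file")
    ser = pd.Series({s: g for s, g in rows})
    if len(ser) != len(rows):
        dups = pd.Series([r[0] for r in rows])
        raise FormatError(f"duplicate samples in group file: "
                          f"{sorted(dups[dups.duplicated()].unique())}")
    return ser


def read_expression_tsv(path, group_path, is_log2: bool = False) -> ExpressionMatrix:
    """Read a rectangular TSV (first column gene id, header = sample ids)
    plus its sample->group file.  Duplicate gene ids are an error naming the
    duplicates; a sample absent from the group file is an error."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate gene ids in {path}: {sorted(map(str, dup))}")
    groups = read_group_tsv(group_path)
    missing = [s for s in df.columns if s not in groups.index]
    if missing:
        raise FormatError(f"samples in matrix absent from group file: {missing}")
    return ExpressionMatrix(df, groups.loc[list(df.columns)], is_log2=is_log2)


def collapse_probes(matrix: ExpressionMatrix,
                    probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to genes, keeping for each gene the
    probe with the highest mean intensity.  Probes without a mapping are
    dropped.  Gene identifiers are otherwise treated as opaque symbols."""
    mapped = [p for p in matrix.genes if p in probe_to_gene]
    sub = matrix.values.loc[mapped]
    means = sub.mean(axis=1)
    best: dict[str, str] = {}
    for probe in mapped:
        gene = probe_to_gene[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    out = sub.loc[[best[g] for g in genes]]
    out.index = genes
    return ExpressionMatrix(out, matrix.sample_group, is_log2=matrix.is_log2)


# ---------------------------------------------------------------------------
# GEO series matrix
# ---------------------------------------------------------------------------

_BEGIN = "!series_matrix_table_begin"
_END = "!series_matrix_table_end"


def _unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def read_series_matrix(path, group_key: str | None = None,
                       default_group: str = "unassigned") -> ExpressionMatrix:
    """Parse a GEO series-matrix file.

    The expression table is read between the ``!series_matrix_table_begin``
    and ``!series_matrix_table_end`` markers; quoted fields are unquoted.
    When ``group_key`` is given (e.g. ``"activity"``), the
    ``!Sample_characteristics`` metadata lines are scanned for
    ``key: value`` entries and used as the sample group labels; samples
    without a matching entry get ``default_group``.
    """
    meta_characteristics: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith(_BEGIN):
                saw_begin, in_table = True, True
                continue
            if line.startswith(_END):
                saw_end, in_table = True, False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!Sample_characteristics"):
                meta_characteristics.append([_unquote(t) for t in line.split("\t")[1:]])
    if not saw_begin or not saw_end:
        raise FormatError(f"{path}: missing series-matrix table markers")
    if not table_lines:
        raise FormatError(f"{path}: empty series-matrix table")

    header = [_unquote(t) for t in table_lines[0].split("\t")]
    sample_ids = header[1:]
    genes, rows = [], []
    for lineno, line in enumerate(table_lines[1:], 2):
        parts = [_unquote(t) for t in line.split("\t")]
        if len(parts) != len(header):
            raise FormatError(f"{path}: ragged table row {lineno} "
                              f"({len(parts)} fields, expected {len(header)})")
        genes.append(parts[0])
        rows.append([float(x) if x not in ("", "null", "NA") else np.nan
                     for x in parts[1:]])
    values = pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)

    group = pd.Series(default_group, index=sample_ids, dtype=object)
    if group_key is not None:
        prefix = f"{group_key}:"
        for entries in meta_characteristics:
            for sample, entry in zip(sample_ids, entries):
                if entry.startswith(prefix):
                    group[sample] = entry[len(prefix):].strip()
    return ExpressionMatrix(values, group, is_log2=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse GMT: ``name TAB description TAB gene...``, empty lines skipped."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(parts)} fields, "
                                  "need at least 3 (name, description, genes...)")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in parts[2:] if g]
            sets[name] = genes
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            d = collection.descriptions.get(name, "")
            fh.write("\t".join([name, d, *genes]) + "\n")


# ---------------------------------------------------------------------------
# TF -> target edges
# ---------------------------------------------------------------------------

def read_tf_edges(path) -> pd.DataFrame:
    """Read a regulator->target edge table.

    Three columns are interpreted as (TF, target, regulatory_potential);
    four as (TF, target, signal, regulatory_potential).  A header row is
    detected by a non-numeric third field.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return pd.DataFrame(columns=["tf", "target", "signal", "regulatory_potential"])
    first = lines[0].split("\t")
    start = 0
    try:
        float(first[2])
    except (ValueError, IndexError):
        start = 1
    records = []
    for lineno, line in enumerate(lines[start:], start + 1):
        parts = line.split("\t")
        if len(parts) == 3:
            tf, target, rp = parts
            signal = np.nan
        elif len(parts) >= 4:
            tf, target = parts[0], parts[1]
            signal, rp = parts[2], parts[3]
        else:
            raise FormatError(f"{path}:{lineno}: edge row needs >= 3 fields")
        try:
            records.append((tf, target,
                            float(signal) if signal == signal else np.nan,
                            float(rp)))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric score: {exc}") from exc
    return pd.DataFrame(records, columns=["tf", "target", "signal",
                                          "regulatory_potential"])


def write_tf_edges(edges: pd.DataFrame, path) -> None:
    cols = ["tf", "target"]
    if "signal" in edges.columns and edges["signal"].notna().any():
        cols.append("signal")
    cols.append("regulatory_potential")
    edges[cols].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# JSON helpers for configs / ground truth
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
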
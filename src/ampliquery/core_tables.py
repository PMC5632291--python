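"""Core data model and I/O for amplicon survey artifacts.

Containers for sample-by-feature count tables, categorical sample
metadata, dereplicated sequences, and taxonomic lineages, together with
readers/writers for the plain-text formats the field deposits:
tab-delimited count matrices, BIOM classic JSON 1.0, EMP-style mapping
files, FASTA, and tab-delimited taxonomy files.

Conventions
-----------
* Counts are strictly non-negative integers; real-valued input is
  rejected rather than rounded, because downstream rarefaction operates
  on integer read multisets.
* Missing metadata: empty cells and the literal strings ``NA``/``na``
  are stored as :data:`MISSING` (``None``) and excluded from category
  enumeration.
* File order of samples and features is preserved on read and write.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "ParseError",
    "SequenceRecord",
    "TaxonomyLineage",
    "FeatureTable",
    "SampleMetadata",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "summarize_metadata",
    "filter_features_by_total",
]

#: Sentinel for a missing metadata value.
MISSING = None

_SEQ_ALPHABET = frozenset("ACGTN")

#: Conventional rank names, domain downward, used when a lineage string
#: carries no explicit rank prefixes.
DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


class ParseError(ValueError):
    """A file did not parse in the expected dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """A (possibly dereplicated) nucleotide sequence with an abundance.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    seq : str
        Uppercase sequence over the alphabet ``{A, C, G, T, N}``.
    count : int
        Total number of reads this record represents (>= 0; default 1).
    """

    id: str
    seq: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        if self.seq != self.seq.upper() or not set(self.seq) <= _SEQ_ALPHABET:
            raise ValueError(
                f"sequence {self.id!r}: characters outside uppercase ACGTN"
            )
        if not isinstance(self.count, (int, np.integer)) or self.count < 0:
            raise ValueError(f"sequence {self.id!r}: count must be an integer >= 0")


@dataclass(frozen=True)
class TaxonomyLineage:
    """An ordered taxonomic lineage from domain downward.

    ``ranks`` is a tuple of ``(rank_name, taxon_name)`` pairs with no
    gaps before the last assigned rank; ``source_db`` labels the
    reference taxonomy the classification came from (e.g. ``"silva"``,
    ``"greengenes"``, ``"rdp"``).
    """

    ranks: tuple[tuple[str, str], ...]
    source_db: str = ""

    def __post_init__(self) -> None:
        for rank_name, taxon in self.ranks:
            if not taxon:
                raise ValueError("lineage has an empty taxon before its last rank")

    @classmethod
    def from_string(cls, lineage: str, source_db: str = "") -> "TaxonomyLineage":
        """Parse a ``;``-separated lineage string.

        Greengenes-style rank prefixes (``k__``, ``p__``, ...) are kept
        as part of the taxon name only if non-empty after the prefix;
        empty trailing levels are dropped.
        """
        names = []
        for part in lineage.split(";"):
            part = part.strip()
            # strip confidence annotations like "(100)"
            part = re.sub(r"\(\d+(\.\d+)?\)$", "", part).strip()
            if re.fullmatch(r"[a-z]__", part) or part == "":
                break
            names.append(part)
        ranks = tuple(
            (DEFAULT_RANKS[i] if i < len(DEFAULT_RANKS) else f"rank{i + 1}", name)
            for i, name in enumerate(names)
        )
        return cls(ranks=ranks, source_db=source_db)

    def to_string(self) -> str:
        return ";".join(name for _, name in self.ranks)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.ranks)

    def contains(self, taxon: str) -> bool:
        """Case-insensitive membership of ``taxon`` at any rank.

        Greengenes-style prefixes are ignored, so ``"chloroplast"``
        matches ``"c__Chloroplast"``.
        """
        needle = taxon.lower()
        for name in self.taxa:
            bare = re.sub(r"^[a-z]__", "", name).lower()
            if bare == needle:
                return True
        return False

    def __len__(self) -> int:
        return len(self.ranks)


class FeatureTable:
    """A samples x features matrix of non-negative integer counts.

    For sOTU (exact sequence variant) tables the feature id *is* the
    trimmed sequence. Sample and feature order is preserved from the
    source file; internal indexing is 0-based.

    Parameters
    ----------
    sample_ids, feature_ids : sequence of str
        Unique, ordered identifiers.
    counts : array-like, shape (n_samples, n_features)
        Integer counts.
    feature_taxonomy : mapping feature_id -> TaxonomyLineage, optional
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        feature_ids: Sequence[str],
        counts,
        feature_taxonomy: Mapping[str, TaxonomyLineage] | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.feature_ids = list(feature_ids)
        arr = np.asarray(counts)
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(counts, dtype=float)
            if not np.all(flt == np.floor(flt)):
                raise ValueError("counts must be integers; real values are rejected")
            arr = flt.astype(np.int64)
        self.counts = arr.astype(np.int64).reshape(
            len(self.sample_ids), len(self.feature_ids)
        )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be >= 0")
        self.feature_taxonomy = dict(feature_taxonomy) if feature_taxonomy else None
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._feature_index = {f: j for j, f in enumerate(self.feature_ids)}

    # -- introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._feature_index[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def feature_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def feature_vector(self, feature_id: str) -> np.ndarray:
        """Counts of one feature across all samples, in sample order."""
        return self.counts[:, self.feature_index(feature_id)]

    def to_dataframe(self):
        """Samples x features :class:`pandas.DataFrame` view."""
        import pandas as pd

        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.feature_ids
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            self.feature_ids,
            self.counts[idx, :],
            self.feature_taxonomy,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return (
            f"<FeatureTable {self.n_samples} samples x {self.n_features} features, "
            f"total {int(self.counts.sum())} reads>"
        )


class SampleMetadata:
    """Per-sample categorical metadata keyed by sample identifier.

    ``fields`` maps a field name to a per-sample mapping whose values
    are strings or :data:`MISSING`. Every field holds an entry for every
    sample.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        fields: Mapping[str, Mapping[str, str | None]] | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in metadata")
        self.fields: dict[str, dict[str, str | None]] = {}
        for name, values in (fields or {}).items():
            if name in self.fields:
                raise ValueError(f"duplicate field name {name!r}")
            self.fields[name] = {s: values.get(s, MISSING) for s in self.sample_ids}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def field_names(self) -> list[str]:
        return list(self.fields)

    def value(self, field: str, sample_id: str) -> str | None:
        return self._field(field)[sample_id]

    def values(self, field: str, sample_ids: Sequence[str] | None = None) -> list:
        """Field values in the given (default: native) sample order."""
        col = self._field(field)
        ids = self.sample_ids if sample_ids is None else sample_ids
        return [col[s] for s in ids]

    def distinct_values(self, field: str) -> list[str]:
        """Distinct non-missing values, in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.values(field):
            if v is not MISSING:
                seen.setdefault(v, None)
        return list(seen)

    def _field(self, field: str) -> dict[str, str | None]:
        try:
            return self.fields[field]
        except KeyError:
            available = ", ".join(self.fields) or "(none)"
            raise KeyError(
                f"unknown metadata field {field!r}; available: {available}"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.sample_ids == other.sample_ids and self.fields == other.fields

    def __repr__(self) -> str:
        return f"<SampleMetadata {self.n_samples} samples, {len(self.fields)} fields>"


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

_TAXONOMY_COLUMNS = {"taxonomy", "consensus lineage", "consensuslineage"}


def _parse_count(token: str, where: str) -> int:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"{where}: {token!r} is not a number") from None
    if value != int(value):
        raise ParseError(f"{where}: count {token!r} is not an integer")
    if value < 0:
        raise ParseError(f"{where}: count {token!r} is negative")
    return int(value)


def _read_tsv_table(path: Path) -> FeatureTable:
    lines = path.read_text().splitlines()
    rows = [line.split("\t") for line in lines if line and not line.startswith("# ")]
    if not rows:
        raise ParseError(f"{path}: empty table")
    header = rows[0]
    if not header or header[0] not in {"#OTU ID", "#OTU_ID", "feature_id", "OTU ID"}:
        raise ParseError(
            f"{path}: line 1: expected a '#OTU ID' header, got {header[0]!r}"
        )
    has_taxonomy = bool(header) and header[-1].strip().lower() in _TAXONOMY_COLUMNS
    sample_ids = header[1 : -1 if has_taxonomy else None]
    feature_ids: list[str] = []
    data: list[list[int]] = []
    taxonomy: dict[str, TaxonomyLineage] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        expected = 1 + len(sample_ids) + (1 if has_taxonomy else 0)
        if len(row) != expected:
            raise ParseError(
                f"{path}: line {lineno}: expected {expected} columns, got {len(row)}"
            )
        feature_ids.append(row[0])
        end = 1 + len(sample_ids)
        data.append(
            [
                _parse_count(tok, f"{path}: line {lineno}")
                for tok in row[1:end]
            ]
        )
        if has_taxonomy:
            taxonomy[row[0]] = TaxonomyLineage.from_string(row[end])
    counts = np.array(data, dtype=np.int64).reshape(len(feature_ids), len(sample_ids))
    return FeatureTable(sample_ids, feature_ids, counts.T, taxonomy or None)


def _read_biom_classic(path: Path) -> FeatureTable:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from None
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise ParseError(f"{path}: BIOM document missing key {key!r}")
    n_feat, n_samp = doc["shape"]
    feature_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if len(feature_ids) != n_feat or len(sample_ids) != n_samp:
        raise ParseError(f"{path}: 'shape' disagrees with rows/columns lists")
    mat = np.zeros((n_feat, n_samp), dtype=np.int64)
    if doc["matrix_type"] == "dense":
        for i, row in enumerate(doc["data"]):
            for j, v in enumerate(row):
                mat[i, j] = _parse_count(str(v), f"{path}: data[{i}][{j}]")
    elif doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            i, j, v = entry
            mat[i, j] = _parse_count(str(v), f"{path}: data entry {entry}")
    else:
        raise ParseError(f"{path}: unsupported matrix_type {doc['matrix_type']!r}")
    taxonomy: dict[str, TaxonomyLineage] = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax:
            lineage = ";".join(tax) if isinstance(tax, list) else str(tax)
            taxonomy[r["id"]] = TaxonomyLineage.from_string(lineage)
    return FeatureTable(sample_ids, feature_ids, mat.T, taxonomy or None)


def read_feature_table(path, format: str | None = None) -> FeatureTable:
    """Read a feature table from ``path``.

    Parameters
    ----------
    path : path-like
    format : {"biom-classic-json", "tsv", None}
        ``None`` sniffs the format: files starting with ``{`` are
        parsed as BIOM classic JSON 1.0, anything else as the
        tab-delimited dense matrix dialect with a ``#OTU ID`` header.

    Returns
    -------
    FeatureTable
        With file order of samples and features preserved. The table in
        the file is features x samples (BIOM orientation); it is
        transposed to samples x features in memory.
    """
    path = Path(path)
    if format is None:
        with open(path) as fh:
            first = fh.read(1)
        format = "biom-classic-json" if first == "{" else "tsv"
    if format == "biom-classic-json":
        return _read_biom_classic(path)
    if format == "tsv":
        return _read_tsv_table(path)
    raise ValueError(f"unknown feature table format {format!r}")


def write_feature_table(
    table: FeatureTable,
    path,
    format: str = "tsv",
    matrix_type: str = "sparse",
    generated_by: str = "ampliquery",
) -> None:
    """Write ``table`` as TSV or BIOM classic JSON 1.0 (features x samples)."""
    path = Path(path)
    mat = table.counts.T  # features x samples, BIOM orientation
    if format == "tsv":
        lines = ["\t".join(["#OTU ID", *table.sample_ids])]
        for i, fid in enumerate(table.feature_ids):
            lines.append("\t".join([fid, *map(str, mat[i].tolist())]))
        path.write_text("\n".join(lines) + "\n")
        return
    if format != "biom-classic-json":
        raise ValueError(f"unknown feature table format {format!r}")
    rows = []
    for fid in table.feature_ids:
        meta = None
        if table.feature_taxonomy and fid in table.feature_taxonomy:
            meta = {"taxonomy": list(table.feature_taxonomy[fid].taxa)}
        rows.append({"id": fid, "metadata": meta})
    if matrix_type == "dense":
        data = mat.tolist()
    elif matrix_type == "sparse":
        nz = np.argwhere(mat > 0)
        data = [[int(i), int(j), int(mat[i, j])] for i, j in nz]
    else:
        raise ValueError(f"unknown matrix_type {matrix_type!r}")
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": generated_by,
        "date": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "matrix_type": matrix_type,
        "matrix_element_type": "int",
        "shape": [table.n_features, table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    path.write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# Sample metadata I/O
# ---------------------------------------------------------------------------

_SAMPLE_ID_HEADERS = {"#sampleid", "#sample id", "sample_name", "sample-id", "sampleid"}
_MISSING_TOKENS = {"", "NA", "na"}


def read_sample_metadata(path) -> SampleMetadata:
    """Read an EMP mapping-file style metadata TSV.

    The first column holds the sample identifier (header ``#SampleID``
    or ``sample_name`` accepted). Empty cells and the literal strings
    ``NA``/``na`` become :data:`MISSING`; every other value is kept
    verbatim as a string.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty metadata file")
    header = lines[0].split("\t")
    if header[0].strip().lower() not in _SAMPLE_ID_HEADERS:
        raise ParseError(
            f"{path}: line 1: first column must be the sample id "
            f"(#SampleID or sample_name), got {header[0]!r}"
        )
    field_names = header[1:]
    if len(set(field_names)) != len(field_names):
        raise ParseError(f"{path}: duplicate field names in header")
    sample_ids: list[str] = []
    columns: dict[str, dict[str, str | None]] = {f: {} for f in field_names}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        row = line.split("\t")
        if len(row) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: expected {len(header)} columns, "
                f"got {len(row)}"
            )
        sid = row[0]
        if sid in sample_ids:
            raise ParseError(f"{path}: line {lineno}: duplicate sample id {sid!r}")
        sample_ids.append(sid)
        for name, cell in zip(field_names, row[1:]):
            columns[name][sid] = MISSING if cell.strip() in _MISSING_TOKENS else cell
    return SampleMetadata(sample_ids, columns)


def write_sample_metadata(md: SampleMetadata, path) -> None:
    """Write metadata as a ``#SampleID`` TSV; MISSING becomes an empty cell."""
    path = Path(path)
    lines = ["\t".join(["#SampleID", *md.field_names])]
    for sid in md.sample_ids:
        cells = [
            "" if md.fields[f][sid] is MISSING else md.fields[f][sid]
            for f in md.field_names
        ]
        lines.append("\t".join([sid, *cells]))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sequence and taxonomy I/O
# ---------------------------------------------------------------------------

_SIZE_RE = re.compile(r";size=(\d+);?$")


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects.

    USEARCH/VSEARCH-style ``;size=N`` abundance annotations on the
    header are parsed into ``count``; headers without one get count 1.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    records = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            m = _SIZE_RE.search(name)
            count = 1
            if m:
                count = int(m.group(1))
                name = name[: m.start()]
            records.append(SequenceRecord(id=name, seq=seq.upper(), count=count))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = 80,
                size_annotations: bool = False) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id + (f";size={rec.count}" if size_annotations else "")
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def read_taxonomy(path, source_db: str = "") -> dict[str, TaxonomyLineage]:
    """Read a two-column ``feature_id<TAB>lineage`` taxonomy file."""
    path = Path(path)
    out: dict[str, TaxonomyLineage] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected id<TAB>lineage")
        out[parts[0]] = TaxonomyLineage.from_string(parts[1], source_db=source_db)
    return out


# ---------------------------------------------------------------------------
# Audits and filters
# ---------------------------------------------------------------------------


def summarize_metadata(md: SampleMetadata, field: str) -> dict[str, int]:
    """Count samples per distinct non-missing value of ``field``.

    The counts sum to the number of samples carrying a value for the
    field; missing entries are excluded.
    """
    counts: dict[str, int] = {}
    for v in md.values(field):
        if v is not MISSING:
            counts[v] = counts.get(v, 0) + 1
    return counts


def filter_features_by_total(table: FeatureTable, min_reads: int) -> FeatureTable:
    """Drop features whose total count over all samples is below ``min_reads``.

    This is the Deblur-style minimal total-abundance filter (e.g.
    ``min_reads=25`` removes sOTUs with <25 reads summed over every
    sample). Samples and retained counts are unchanged.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.feature_totals() >= min_reads
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    taxonomy = None
    if table.feature_taxonomy:
        taxonomy = {f: t for f, t in table.feature_taxonomy.items() if f in set(kept_ids)}
    return FeatureTable(
        table.sample_ids, kept_ids, table.counts[:, keep], taxonomy or None
    )
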
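"""Reading, validation and identifier harmonisation for differential-protein tables.

Cross-study proteomic comparisons hinge on matching records between tables
that identify proteins inconsistently: one table may carry an isoform-level
UniProt accession (``P12345-2``), another only a gene symbol in mixed case.
This module normalises both identifiers into a :class:`ProteinKey` and
implements the dual-identifier matching rule used throughout the pipeline:
two records refer to the same protein if *either* their accessions or their
gene symbols agree. Matching is equality-based only — no synonym expansion
or web ID-mapping — so that every downstream count is reproducible from the
input files alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ProteinKey",
    "DiffRecord",
    "DiffTable",
    "ReferenceSet",
    "LoadReport",
    "TableSchemaError",
    "RowValidationError",
    "normalize_key",
    "keys_match",
    "read_diff_table",
    "read_reference_set",
    "write_diff_table",
    "diff_table_from_frame",
    "KeyIndex",
]

_ISOFORM_RE = re.compile(r"-\d+$")


class TableSchemaError(ValueError):
    """A required column is missing from an input table."""


class RowValidationError(ValueError):
    """A row failed validation; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class ProteinKey:
    """Normalised (UniProt accession, gene symbol) pair used for matching.

    At least one field is non-empty. Accessions are stripped of the
    ``-<digits>`` isoform suffix; gene symbols are upper-cased so that
    symbol matching is case-insensitive.
    """

    uniprot: str = ""
    gene: str = ""

    def __post_init__(self):
        if not self.uniprot and not self.gene:
            raise RowValidationError("ProteinKey needs at least one identifier")


@dataclass(frozen=True)
class DiffRecord:
    """One differential-protein row: key, effect size/direction, FDR call."""

    key: ProteinKey
    direction: str  # "up" | "down"
    log2fc: float | None = None
    significant: bool = True

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise RowValidationError(f"direction must be up/down, got {self.direction!r}")
        if self.log2fc is not None and self.log2fc != 0:
            implied = "up" if self.log2fc > 0 else "down"
            if implied != self.direction:
                raise RowValidationError(
                    f"direction {self.direction} contradicts log2fc {self.log2fc}"
                )


@dataclass
class LoadReport:
    rows_read: int = 0
    rows_dropped: int = 0
    duplicates_collapsed: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class DiffTable:
    """A validated, deduplicated differential-protein table."""

    records: list[DiffRecord]
    label: str = ""
    provenance: str = ""
    report: LoadReport = field(default_factory=LoadReport)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> list[ProteinKey]:
        return [r.key for r in self.records]


@dataclass
class ReferenceSet:
    """A named curated protein list (e.g. tau interactors, causative genes)."""

    name: str
    keys: set[ProteinKey]
    universe_hint: int | None = None

    def __post_init__(self):
        if not self.keys:
            raise ValueError(f"empty reference set {self.name!r}")

    def __len__(self) -> int:
        return len(self.keys)


def normalize_key(raw_uniprot: str | None, raw_gene: str | None, row: int | None = None) -> ProteinKey:
    """Normalise a raw identifier pair into a :class:`ProteinKey`.

    The isoform suffix (``-2`` in ``P12345-2``) is removed from the accession;
    the gene symbol is whitespace-trimmed and upper-cased. Blank inputs become
    empty fields; both blank is a row-level validation error.
    """
    up = "" if raw_uniprot is None or (isinstance(raw_uniprot, float) and pd.isna(raw_uniprot)) else str(raw_uniprot).strip()
    gn = "" if raw_gene is None or (isinstance(raw_gene, float) and pd.isna(raw_gene)) else str(raw_gene).strip()
    up = _ISOFORM_RE.sub("", up)
    gn = gn.upper()
    if not up and not gn:
        raise RowValidationError("both identifiers blank", row=row)
    return ProteinKey(uniprot=up, gene=gn)


def keys_match(a: ProteinKey, b: ProteinKey) -> bool:
    """Dual-identifier match: accession equality OR gene-symbol equality.

    Empty fields never match anything, including other empty fields.
    """
    if a.uniprot and b.uniprot and a.uniprot == b.uniprot:
        return True
    if a.gene and b.gene and a.gene == b.gene:
        return True
    return False


class KeyIndex:
    """Index of keys for fast dual-identifier lookup.

    Lookup resolution follows the fixed order: accession match first, then
    gene-symbol match (matching is never chained through intermediates).
    """

    def __init__(self, keys):
        self._by_uniprot: dict[str, ProteinKey] = {}
        self._by_gene: dict[str, ProteinKey] = {}
        for k in keys:
            if k.uniprot and k.uniprot not in self._by_uniprot:
                self._by_uniprot[k.uniprot] = k
            if k.gene and k.gene not in self._by_gene:
                self._by_gene[k.gene] = k

    def find(self, key: ProteinKey) -> ProteinKey | None:
        """Return the first indexed key matching ``key``, accession priority."""
        if key.uniprot and key.uniprot in self._by_uniprot:
            return self._by_uniprot[key.uniprot]
        if key.gene and key.gene in self._by_gene:
            return self._by_gene[key.gene]
        return None

    def __contains__(self, key: ProteinKey) -> bool:
        return self.find(key) is not None


# ---------------------------------------------------------------------------
# file IO


def _read_frame(path, sheet: str | None = None) -> pd.DataFrame:
    p = str(path)
    if p.endswith((".xlsx", ".xlsm")):
        return pd.read_excel(p, sheet_name=sheet if sheet is not None else 0)
    sep = "," if p.endswith(".csv") else "\t"
    return pd.read_csv(p, sep=sep)

def _require_columns(df: pd.DataFrame, cols, path) -> None:
    for c in cols:
        if c is not None and c not in df.columns:
            raise TableSchemaError(f"{path}: missing column {c!r}")


def _sig_sort_value(rec: DiffRecord, sig_values: dict[int, float], idx: int) -> tuple:
    # smaller significance value wins; ties broken by larger |log2fc|, then first seen
    sig = sig_values.get(idx, 0.0)
    fc = abs(rec.log2fc) if rec.log2fc is not None else 0.0
    return (sig, -fc, idx)


def diff_table_from_frame(
    df: pd.DataFrame,
    column_map: dict[str, str],
    label: str = "",
    provenance: str = "",
) -> DiffTable:
    """Build a validated :class:`DiffTable` from a DataFrame.

    ``column_map`` maps the roles ``uniprot``, ``gene``, and at least one of
    ``log2fc`` / ``direction`` (optionally ``significance``) to column names.
    Duplicate keys are collapsed keeping the most significant record (smallest
    significance value, ties by largest ``|log2fc|``, then first occurrence);
    rows lacking both identifiers are dropped and reported.
    """
    up_col = column_map.get("uniprot")
    gene_col = column_map.get("gene")
    fc_col = column_map.get("log2fc")
    dir_col = column_map.get("direction")
    sig_col = column_map.get("significance")
    if up_col is None and gene_col is None:
        raise TableSchemaError("column_map must name a uniprot and/or gene column")
    if fc_col is None and dir_col is None:
        raise TableSchemaError("column_map must name a log2fc and/or direction column")
    _require_columns(df, [up_col, gene_col, fc_col, dir_col, sig_col], provenance or label)

    report = LoadReport(rows_read=len(df))
    records: list[DiffRecord] = []
    sig_values: dict[int, float] = {}
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            key = normalize_key(
                row[up_col] if up_col else "",
                row[gene_col] if gene_col else "",
                row=i,
            )
        except RowValidationError as e:
            report.rows_dropped += 1
            report.messages.append(str(e))
            continue
        log2fc = None
        if fc_col is not None and pd.notna(row[fc_col]):
            try:
                log2fc = float(row[fc_col])
            except (TypeError, ValueError):
                raise RowValidationError(f"unparseable log2fc {row[fc_col]!r}", row=i)
        if dir_col is not None and pd.notna(row[dir_col]):
            d = str(row[dir_col]).strip().lower()
            direction = {"up": "up", "increased": "up", "down": "down", "decreased": "down"}.get(d)
            if direction is None:
                raise RowValidationError(f"unrecognised direction {row[dir_col]!r}", row=i)
        elif log2fc is not None:
            direction = "up" if log2fc >= 0 else "down"
        else:
            report.rows_dropped += 1
            report.messages.append(f"row {i}: no direction information")
            continue
        records.append(DiffRecord(key=key, direction=direction, log2fc=log2fc))
        if sig_col is not None and pd.notna(row[sig_col]):
            sig_values[len(records) - 1] = float(row[sig_col])

    # collapse duplicate keys, keeping the strongest-evidence record
    best: dict[ProteinKey, tuple] = {}
    for idx, rec in enumerate(records):
        rank = _sig_sort_value(rec, sig_values, idx)
        if rec.key not in best or rank < best[rec.key][0]:
            if rec.key in best:
                report.duplicates_collapsed += 1
            best[rec.key] = (rank, rec)
        else:
            report.duplicates_collapsed += 1
    deduped = [rec for _, rec in sorted(best.values(), key=lambda t: t[0][2])]
    if report.duplicates_collapsed:
        report.messages.append(f"{report.duplicates_collapsed} duplicate(s) collapsed")
    return DiffTable(records=deduped, label=label, provenance=provenance, report=report)


def read_diff_table(
    path,
    column_map: dict[str, str],
    label: str = "",
    sheet: str | None = None,
) -> DiffTable:
    """Read a differential table from TSV/CSV/XLSX and validate it.

    XLSX sheet selection is explicit by name; it is never positional beyond
    the single-sheet default.
    """
    df = _read_frame(path, sheet=sheet)
    return diff_table_from_frame(df, column_map, label=label, provenance=f"{path}" + (f"#{sheet}" if sheet else ""))


def read_reference_set(
    path,
    column_map: dict[str, str],
    name: str,
    sheet: str | None = None,
    universe_hint: int | None = None,
) -> ReferenceSet:
    """Read a curated protein list into a deduplicated :class:`ReferenceSet`."""
    df = _read_frame(path, sheet=sheet)
    up_col = column_map.get("uniprot")
    gene_col = column_map.get("gene")
    if up_col is None and gene_col is None:
        raise TableSchemaError("column_map must name a uniprot and/or gene column")
    _require_columns(df, [up_col, gene_col], path)
    keys: set[ProteinKey] = set()
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            keys.add(normalize_key(row[up_col] if up_col else "", row[gene_col] if gene_col else "", row=i))
        except RowValidationError:
            continue
    if not keys:
        raise ValueError(f"empty reference set from {path}")
    return ReferenceSet(name=name, keys=keys, universe_hint=universe_hint)


def write_diff_table(table: DiffTable, path) -> None:
    """Write a table in the canonical TSV layout (uniprot, gene, log2fc, direction, significant)."""
    df = pd.DataFrame(
        {
            "uniprot": [r.key.uniprot for r in table.records],
            "gene": [r.key.gene for r in table.records],
            "log2fc": [r.log2fc if r.log2fc is not None else "" for r in table.records],
            "direction": [r.direction for r in table.records],
            "significant": [r.significant for r in table.records],
        }
    )
    p = str(path)
    if p.endswith(".xlsx"):
        df.to_excel(p, index=False)
    else:
        df.to_csv(p, sep="\t", index=False)
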
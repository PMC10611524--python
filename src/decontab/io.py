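"""Reading and writing count tables, exclusion lists and sidecar files.

Two count-table dialects are supported:

* ``tsv`` -- UTF-8, tab-delimited, header row
  ``taxon_id<TAB>[taxonomy<TAB>]<sample1>...<sampleN>``.  Lines starting with
  ``#`` are comments; a leading ``# Constructed from biom file`` line (a
  common exporter artifact) is tolerated.
* ``biom-json`` -- the BIOM 1.0 JSON schema (dense or sparse), the plain-text
  interchange dialect produced by classic QIIME.  HDF5 BIOM is out of scope.

Exclusion lists are one name per line (``#`` comments allowed) or two-column
TSV ``name<TAB>note``; cohort labels are two-column TSV ``sample_id<TAB>cohort``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import ExclusionList, TableValidationError, TaxaCountTable
from .taxonomy import TaxonomyLineage

_TAXONOMY_COLUMN_NAMES = {"taxonomy", "lineage", "taxonomy_string"}

DIALECTS = ("tsv", "biom-json")


def read_count_table(
    path: str | Path,
    dialect: str = "tsv",
    marker: str = "16S",
    cohorts: dict[str, str] | None = None,
) -> TaxaCountTable:
    """Read and validate a taxon-by-sample count table.

    Raises :class:`TableValidationError` naming the offenders on duplicate
    ids and giving cell coordinates on negative/non-numeric counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    if dialect == "tsv":
        return _read_tsv(path, marker=marker, cohorts=cohorts)
    if dialect == "biom-json":
        return _read_biom_json(path, marker=marker, cohorts=cohorts)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _read_tsv(path: Path, marker: str, cohorts) -> TaxaCountTable:
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                # classic QIIME writes '#OTU ID\t...' as the real header
                stripped = line.lstrip("#").strip()
                if header is None and "\t" in stripped and not stripped.lower().startswith(
                    "constructed from biom"
                ):
                    header = stripped.split("\t")
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None or not rows:
        raise TableValidationError(f"no tabular data in {path}")
    if len(header) < 2:
        raise TableValidationError(
            f"{path}: need a taxon-id column plus at least one sample column"
        )
    has_taxonomy = len(header) > 1 and header[1].strip().lower() in _TAXONOMY_COLUMN_NAMES
    sample_ids = header[2:] if has_taxonomy else header[1:]
    taxon_ids: list[str] = []
    lineages: dict[str, TaxonomyLineage] = {}
    data: list[list[str]] = []
    for row in rows:
        expected = len(sample_ids) + (2 if has_taxonomy else 1)
        if len(row) != expected:
            raise TableValidationError(
                f"{path}: row for {row[0]!r} has {len(row)} fields, expected {expected}"
            )
        taxon_id = row[0].strip()
        taxon_ids.append(taxon_id)
        if has_taxonomy:
            lineages[taxon_id] = TaxonomyLineage.from_string(row[1])
            data.append(row[2:])
        else:
            data.append(row[1:])
    counts = _parse_count_matrix(data, taxon_ids, sample_ids, path)
    return TaxaCountTable(counts=counts, lineages=lineages, cohorts=cohorts, marker=marker)


def _parse_count_matrix(
    data: list[list[str]], taxon_ids: list[str], sample_ids: list[str], path: Path
) -> pd.DataFrame:
    values = np.empty((len(taxon_ids), len(sample_ids)), dtype=float)
    for i, row in enumerate(data):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise TableValidationError(
                    f"{path}: non-numeric count {cell!r} at "
                    f"(taxon={taxon_ids[i]!r}, sample={sample_ids[j]!r})"
                ) from None
    # duplicate ids are caught by the container, but report with file context
    for axis_name, ids in (("taxon", taxon_ids), ("sample", sample_ids)):
        seen: set[str] = set()
        dupes = [x for x in ids if x in seen or seen.add(x)]
        if dupes:
            raise TableValidationError(f"{path}: duplicate {axis_name} ids: {dupes}")
    return pd.DataFrame(values, index=taxon_ids, columns=sample_ids)


def _read_biom_json(path: Path, marker: str, cohorts) -> TaxaCountTable:
    with open(path, encoding="utf-8") as handle:
        doc = json.load(handle)
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise TableValidationError(f"{path}: not BIOM 1.0 JSON (missing {key!r})")
    n_rows, n_cols = doc["shape"]
    taxon_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    values = np.zeros((n_rows, n_cols), dtype=float)
    if doc["matrix_type"] == "dense":
        values[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            values[int(i), int(j)] = v
    else:
        raise TableValidationError(
            f"{path}: unsupported matrix_type {doc['matrix_type']!r}"
        )
    lineages: dict[str, TaxonomyLineage] = {}
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax is not None:
            text = ";".join(tax) if isinstance(tax, list) else str(tax)
            lineages[row["id"]] = TaxonomyLineage.from_string(text)
    counts = pd.DataFrame(values, index=taxon_ids, columns=sample_ids)
    return TaxaCountTable(counts=counts, lineages=lineages, cohorts=cohorts, marker=marker)


def write_count_table(
    table: TaxaCountTable, path: str | Path, dialect: str = "tsv"
) -> None:
    """Serialize a table so that :func:`read_count_table` reproduces it.

    An empty table (no taxa or no samples) is an error: silently writing a
    header-only file would round-trip to nothing.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise TableValidationError("refusing to write an empty table")
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as handle:
            header = ["taxon_id", "taxonomy", *table.sample_ids]
            handle.write("\t".join(header) + "\n")
            for taxon_id in table.taxon_ids:
                lineage = table.lineages[taxon_id]
                raw = lineage.raw or str(lineage)
                row = [taxon_id, raw] + [
                    str(int(v)) for v in table.counts.loc[taxon_id]
                ]
                handle.write("\t".join(row) + "\n")
    elif dialect == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "decontab",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [
                {
                    "id": t,
                    "metadata": {"taxonomy": table.lineages[t].raw or str(table.lineages[t])},
                }
                for t in table.taxon_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.to_numpy().tolist(),
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(doc, handle)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_exclusion_list(
    path: str | Path,
    rank: str = "genus",
    source: str = "published-curated",
    label: str | None = None,
) -> ExclusionList:
    """Read an exclusion list (one name per line, or ``name<TAB>note`` TSV).

    Names are deduplicated case-insensitively.  An empty file is an error:
    an empty exclusion list must be an explicit choice, never an accident.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"exclusion list not found: {path}")
    names: dict[str, str] = {}  # lowercase -> first-seen spelling
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name = line.split("\t")[0].strip()
            if name.lower() in {"name", "genus", "taxon"}:  # optional header
                continue
            if name and name.lower() not in names:
                names[name.lower()] = name
    if not names:
        raise TableValidationError(
            f"{path}: exclusion list is empty; pass no list instead of an empty file"
        )
    return ExclusionList.from_names(
        names.values(), rank=rank, source=source, label=label or path.name
    )


def read_cohort_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>cohort`` -> mapping."""
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TableValidationError(f"{path}: expected 2 columns, got {line!r}")
            if fields[0].lower() == "sample_id":
                continue
            labels[fields[0]] = fields[1]
    return labels


def read_taxon_list(path: str | Path) -> list[str]:
    """One taxon id per line (used for indicator sets and overlap inputs)."""
    path = Path(path)
    out: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out
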
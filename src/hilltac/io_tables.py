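"""Readers and writers for OTU count tables.

The unit of a study is a :class:`CommunityTable`: an integer matrix of read
counts with taxa (OTUs) as rows and samples as columns.  Two on-disk layouts
are supported:

* mothur ``.shared`` files — one row per sample, with the mandatory
  ``label``, ``Group`` and ``numOtus`` columns followed by one column per OTU;
* plain TSV — a rectangular matrix with one header row and one label column,
  in either orientation.

I/O is deliberately permissive where analysis is strict: a sample with zero
reads is preserved on read (and on a write/read round trip) but rejected by
the analysis operations that would divide by its total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "TableFormatError",
    "read_shared",
    "write_shared",
    "read_tsv",
    "write_tsv",
    "pool_samples",
]

_SHARED_META_COLUMNS = ("label", "Group", "numOtus")


class TableFormatError(ValueError):
    """An input file violates the declared tabular layout."""


@dataclass(frozen=True)
class CommunityTable:
    """Integer OTU count matrix, taxa x samples.

    Parameters
    ----------
    taxon_ids
        Unique row labels (OTU names).
    sample_ids
        Unique column labels (sample / group names).
    counts
        Non-negative integer matrix of shape ``(len(taxon_ids),
        len(sample_ids))``.
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if counts.size == 0 or counts.sum() == 0:
            raise ValueError("table must contain at least one positive count")
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def pooled(self) -> np.ndarray:
        """Per-taxon counts pooled over all samples."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a taxa x samples :class:`pandas.DataFrame`."""
        return pd.DataFrame(
            np.asarray(self.counts),
            index=list(self.taxon_ids),
            columns=list(self.sample_ids),
        )


def _coerce_count_cells(raw: pd.DataFrame, *, row_offset: int = 2) -> np.ndarray:
    """Coerce a DataFrame of strings to an integer matrix.

    Raises ``ValueError`` naming 1-based file coordinates (header counts as
    row 1) for non-numeric, non-integral or negative cells.
    """
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric count {raw.iat[i, j]!r} at row {i + row_offset}, "
            f"column {raw.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing count at row {i + row_offset}, column {raw.columns[j]!r}"
        )
    values = numeric.to_numpy(dtype=float)
    frac = values != np.round(values)
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count {values[i, j]} at row {i + row_offset}, "
            f"column {raw.columns[j]!r}"
        )
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative count {values[i, j]:.0f} at row {i + row_offset}, "
            f"column {raw.columns[j]!r}"
        )
    return values.astype(np.int64)


def _read_rows(path) -> list[list[str]]:
    with open(path, "r", encoding="utf-8") as handle:
        rows = [line.rstrip("\n").split("\t") for line in handle if line.strip()]
    return rows


def read_shared(path) -> CommunityTable:
    """Read a mothur ``.shared`` OTU table.

    Samples come from the ``Group`` column; taxa from the OTU column headers.
    When the file holds several ``label`` (clustering-threshold) blocks only
    the first is kept and a warning lists the labels skipped.
    """
    rows = _read_rows(path)
    if not rows:
        raise TableFormatError(f"{path}: empty file")
    header = rows[0]
    for pos, expected in enumerate(_SHARED_META_COLUMNS):
        if pos >= len(header) or header[pos] != expected:
            found = header[pos] if pos < len(header) else "<missing>"
            raise TableFormatError(
                f"{path}: expected column {expected!r} at position {pos + 1}, "
                f"found {found!r}"
            )
    otu_ids = header[3:]
    if not otu_ids:
        raise TableFormatError(f"{path}: no OTU columns after {_SHARED_META_COLUMNS}")
    if len(rows) < 2:
        raise TableFormatError(f"{path}: header but no sample rows")

    width = len(header)
    for k, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise TableFormatError(
                f"{path}: row {k} has {len(row)} fields, expected {width}"
            )

    body = pd.DataFrame(rows[1:], columns=header)
    labels = body["label"].tolist()
    first_label = labels[0]
    skipped = sorted({lab for lab in labels if lab != first_label})
    if skipped:
        logger.warning(
            "%s: keeping first label block %r, skipping label(s) %s",
            path,
            first_label,
            ", ".join(repr(s) for s in skipped),
        )
        body = body[body["label"] == first_label]

    declared = body["numOtus"].unique().tolist()
    for value in declared:
        try:
            n_declared = int(value)
        except ValueError:
            raise TableFormatError(
                f"{path}: numOtus value {value!r} is not an integer"
            ) from None
        if n_declared != len(otu_ids):
            raise TableFormatError(
                f"{path}: numOtus declares {n_declared} OTUs but "
                f"{len(otu_ids)} OTU columns are present"
            )

    counts_by_sample = _coerce_count_cells(body[otu_ids])
    return CommunityTable(
        taxon_ids=tuple(otu_ids),
        sample_ids=tuple(body["Group"].tolist()),
        counts=counts_by_sample.T,
    )


def write_shared(table: CommunityTable, path, label: str = "0.97") -> None:
    """Write a table in mothur ``.shared`` layout (one row per sample)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(_SHARED_META_COLUMNS + table.taxon_ids) + "\n")
        for j, sample in enumerate(table.sample_ids):
            cells = [label, sample, str(table.n_taxa)]
            cells.extend(str(int(c)) for c in table.counts[:, j])
            handle.write("\t".join(cells) + "\n")


def read_tsv(path, orientation: str = "taxa_by_samples") -> CommunityTable:
    """Read a plain TSV count matrix.

    The file must be rectangular, with one header row of column labels and a
    leading label column.  ``orientation`` states what the file's rows are;
    the returned table is always taxa x samples.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows = _read_rows(path)
    if not rows:
        raise TableFormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise TableFormatError(f"{path}: need at least one label and one data column")
    width = len(header)
    for k, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise TableFormatError(
                f"{path}: ragged row {k} has {len(row)} fields, expected {width}"
            )
    if len(rows) < 2:
        raise TableFormatError(f"{path}: header but no data rows")
    col_ids = header[1:]
    row_ids = [row[0] for row in rows[1:]]
    raw = pd.DataFrame([row[1:] for row in rows[1:]], columns=col_ids)
    counts = _coerce_count_cells(raw)
    if orientation == "samples_by_taxa":
        return CommunityTable(tuple(col_ids), tuple(row_ids), counts.T)
    return CommunityTable(tuple(row_ids), tuple(col_ids), counts)


def write_tsv(
    table: CommunityTable, path, orientation: str = "taxa_by_samples"
) -> None:
    """Write the table as plain TSV in the requested orientation."""
    df = table.to_dataframe()
    if orientation == "samples_by_taxa":
        df = df.T
        corner = "sample_id"
    elif orientation == "taxa_by_samples":
        corner = "taxon_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", index_label=corner)


def pool_samples(table: CommunityTable, sample_subset=None) -> np.ndarray:
    """Sum counts across a subset of samples into one abundance vector.

    Taxa whose pooled count is zero are retained with count 0, so the result
    is positionally aligned with ``table.taxon_ids``.  ``sample_subset=None``
    pools every sample.
    """
    if sample_subset is None:
        sample_subset = list(table.sample_ids)
    if len(sample_subset) == 0:
        raise ValueError("sample_subset must be non-empty")
    index = {s: j for j, s in enumerate(table.sample_ids)}
    try:
        cols = [index[s] for s in sample_subset]
    except KeyError as exc:
        raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
    return table.counts[:, cols].sum(axis=1)
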
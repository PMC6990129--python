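"""OTU table, taxonomy, metadata and tree I/O plus table-level filters.

The central container is :class:`CountTable`, an integer OTU-by-sample
matrix in the classic tab-separated QIIME layout (OTUs as rows, samples
as columns, optional trailing ``taxonomy`` column with a
semicolon-delimited lineage). Filters implement the standard
pre-processing applied to amplicon OTU tables before diversity
analysis: dropping OTUs below a total-read threshold, removing
organellar (mitochondrial/chloroplast) OTUs, and rarefying every sample
to a common depth by subsampling reads without replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered rank names of a 7-level lineage.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class CountTable:
    """Integer OTU x sample abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        OTUs as rows (index = OTU ids), samples as columns. Values must
        be non-negative integers (or integral floats).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise ValueError("counts must be integral")
            values = values.astype(np.int64)
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        self._df = pd.DataFrame(
            values.astype(np.int64) if values.size else values,
            index=data.index.astype(str),
            columns=data.columns.astype(str),
        )

    @property
    def df(self) -> pd.DataFrame:
        """Underlying DataFrame (OTUs x samples, int64)."""
        return self._df

    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def sample_totals(self) -> pd.Series:
        return self._df.sum(axis=0)

    def otu_totals(self) -> pd.Series:
        return self._df.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (columns sum to 1; zero-total columns NaN)."""
        totals = self._df.sum(axis=0)
        return self._df / totals.replace(0, np.nan)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self._df.loc[:, list(sample_ids)])

    def select_otus(self, otu_ids) -> "CountTable":
        return CountTable(self._df.loc[list(otu_ids)])

    def drop_empty_otus(self) -> "CountTable":
        return CountTable(self._df.loc[self._df.sum(axis=1) > 0])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"CountTable({self.shape[0]} OTUs x {self.shape[1]} samples)"


@dataclass
class FilterConfig:
    """Table-level filter settings.

    ``min_otu_total_reads`` drops OTUs whose total across all samples is
    strictly below the threshold; ``organelle_keywords`` are
    case-insensitive substrings matched against the joined lineage.
    """

    min_otu_total_reads: int = 20
    organelle_keywords: frozenset[str] = field(
        default_factory=lambda: frozenset({"mitochondria", "chloroplast"})
    )

    def __post_init__(self):
        if self.min_otu_total_reads < 0:
            raise ValueError("min_otu_total_reads must be >= 0")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a semicolon-delimited lineage into at most 7 rank labels."""
    parts = tuple(p.strip() for p in str(text).split(";") if p.strip())
    return parts[: len(RANKS)]


def read_count_table(path) -> tuple[CountTable, pd.Series | None]:
    """Read a classic tab-separated OTU table.

    First column holds OTU ids (header may be ``#OTU ID``); remaining
    columns are samples; an optional last column named ``taxonomy``
    (case-insensitive) carries semicolon-delimited lineages. Leading
    comment lines starting with ``#`` (other than the header) are
    skipped.

    Returns
    -------
    (CountTable, taxonomy)
        ``taxonomy`` is a Series mapping OTU id to a tuple of rank
        labels, or None when the file has no taxonomy column.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = [ln for ln in lines if ln.strip()]
    # classic format: optional "# Constructed from ..." comment, then a
    # header line that may itself start with "#OTU ID"
    header_idx = 0
    for i, ln in enumerate(rows):
        if ln.startswith("#") and not ln.startswith("#OTU"):
            header_idx = i + 1
        else:
            break
    header = rows[header_idx].split("\t")
    body = [ln.split("\t") for ln in rows[header_idx + 1 :]]
    sample_cols = header[1:]
    has_tax = bool(sample_cols) and sample_cols[-1].strip().lower() == "taxonomy"
    if has_tax:
        sample_cols = sample_cols[:-1]
    otu_ids, data, lineages = [], [], {}
    for r, fields in enumerate(body):
        otu = fields[0]
        cells = fields[1 : 1 + len(sample_cols)]
        if len(cells) != len(sample_cols):
            raise ValueError(f"row {otu!r}: expected {len(sample_cols)} counts, got {len(cells)}")
        row = []
        for c, (sample, cell) in enumerate(zip(sample_cols, cells)):
            try:
                v = int(cell)
            except ValueError:
                # rarefaction-averaged tables are sometimes written with
                # float cells; only exact integers are accepted here
                raise ValueError(
                    f"non-integer count {cell!r} at OTU {otu!r}, sample {sample!r} "
                    f"(row {r + 2}, column {c + 2})"
                ) from None
            row.append(v)
        otu_ids.append(otu)
        data.append(row)
        if has_tax:
            lineages[otu] = parse_lineage(fields[1 + len(sample_cols)])
    table = CountTable(pd.DataFrame(data, index=otu_ids, columns=sample_cols, dtype=np.int64))
    tax = pd.Series(lineages, name="taxonomy") if has_tax else None
    return table, tax


def write_count_table(table: CountTable, path, taxonomy: pd.Series | None = None) -> None:
    """Write a CountTable in classic tab-separated layout (round-trips with
    :func:`read_count_table`)."""
    path = Path(path)
    with path.open("w") as fh:
        cols = list(table.sample_ids)
        header = ["#OTU ID"] + cols + (["taxonomy"] if taxonomy is not None else [])
        fh.write("\t".join(header) + "\n")
        for otu in table.otu_ids:
            row = [otu] + [str(int(v)) for v in table.df.loc[otu]]
            if taxonomy is not None:
                lineage = taxonomy.get(otu, ())
                row.append(";".join(lineage))
            fh.write("\t".join(row) + "\n")


def read_metadata(path) -> pd.DataFrame:
    """Read a tab-separated sample mapping file keyed on sample id.

    The first column is the sample id (header may be ``#SampleID``).
    Expected factor columns are ``site``, ``habitat``, ``year`` and
    ``replicate`` but any extra columns are preserved.
    """
    md = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    md.columns = [c.lstrip("#") for c in md.columns]
    md = md.set_index(md.columns[0])
    md.index = md.index.astype(str)
    for col in ("year", "replicate"):
        if col in md.columns:
            md[col] = md[col].astype(int)
    return md


def write_metadata(metadata: pd.DataFrame, path) -> None:
    md = metadata.copy()
    md.index.name = "#SampleID"
    md.to_csv(path, sep="\t")


HABITATS = ("rhizosphere", "bulk", "bare")


def validate_metadata(metadata: pd.DataFrame) -> None:
    """Check the closed habitat vocabulary and unique sample ids."""
    if metadata.index.duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    if "habitat" in metadata.columns:
        bad = set(metadata["habitat"]) - set(HABITATS)
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}; expected one of {HABITATS}")


def filter_low_count_otus(table: CountTable, config: FilterConfig | None = None) -> CountTable:
    """Drop OTUs whose total count across all samples is strictly below
    ``config.min_otu_total_reads``. Samples are never removed."""
    config = config or FilterConfig()
    keep = table.otu_totals() >= config.min_otu_total_reads
    return CountTable(table.df.loc[keep])


def remove_organelle_otus(
    table: CountTable, taxonomy: pd.Series | None, config: FilterConfig | None = None
) -> CountTable:
    """Drop OTUs whose lineage contains an organelle keyword
    (case-insensitive substring on the joined lineage). OTUs without a
    taxonomy entry are treated as non-organellar and kept."""
    config = config or FilterConfig()
    if taxonomy is None or not config.organelle_keywords:
        return CountTable(table.df)
    keywords = [k.lower() for k in config.organelle_keywords]
    keep = []
    for otu in table.otu_ids:
        lineage = taxonomy.get(otu, ())
        joined = ";".join(lineage).lower()
        keep.append(not any(k in joined for k in keywords))
    return CountTable(table.df.loc[keep])


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Rarefy every sample to ``depth`` reads by subsampling without
    replacement (multivariate hypergeometric draw).

    Samples with fewer than ``depth`` total reads are dropped with a
    logged warning. ``depth=None`` uses the minimum sample total. OTUs
    that end up with zero reads in every retained sample are kept (rows
    are preserved) so tables stay alignable.
    """
    if depth is None:
        depth = int(table.sample_totals().min())
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be > 0, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept, dropped = [], []
    out = {}
    for sample in table.sample_ids:
        total = int(totals[sample])
        if total < depth:
            dropped.append(sample)
            continue
        col = table.df[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, depth)
        kept.append(sample)
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) with total < %d: %s", len(dropped), depth, dropped
        )
    if not kept:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    return CountTable(pd.DataFrame(out, index=table.otu_ids, columns=kept))
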
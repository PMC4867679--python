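"""Data model and readers/writers for HR-SIP inputs.

The universal input is an OTU x sample table of non-negative integer counts
(:class:`CountMatrix`) plus per-sample annotations (:class:`SampleMeta`)
describing treatment, sampling day, gradient membership and fraction buoyant
density. Taxonomy and a rooted phylogeny (scikit-bio ``TreeNode``) are
optional side inputs.

Formats: tab-separated tables (primary) and the BIOM 1.0 JSON dialect
(optional) for counts; newick for trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountMatrix",
    "SampleMeta",
    "TaxonomyTable",
    "FormatError",
    "read_count_table",
    "write_count_table",
    "read_sample_meta",
    "write_sample_meta",
    "read_taxonomy",
    "read_tree",
    "relative_abundance",
    "aggregate_by_rank",
]

TREATMENTS = ("control", "13C-xylose", "13C-cellulose")
RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

META_COLUMNS = (
    "treatment",
    "day",
    "gradient_id",
    "density",
    "is_fractionated",
)


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dupes}")


@dataclass
class CountMatrix:
    """Non-negative integer OTU x sample count table.

    ``data`` is a pandas DataFrame with OTU ids as the index and sample ids
    as the columns. Construction validates the invariants: unique ids, no
    negative entries, and integral counts (whole-valued floats are coerced).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "OTU")
        _check_unique(df.columns, "sample")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count table contains non-numeric cells")
        if np.isnan(values.astype(float)).any():
            raise FormatError("count table contains missing values")
        if (values < 0).any():
            raise FormatError("count table contains negative values")
        if not np.allclose(values, np.round(values.astype(float))):
            raise FormatError("count table contains non-integer values")
        self.data = df.astype(np.int64)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "otu_id"
        self.data.columns = self.data.columns.astype(str)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing}")
        return CountMatrix(self.data.loc[:, list(sample_ids)].copy())

    def select_otus(self, otu_ids: Sequence[str]) -> "CountMatrix":
        missing = [o for o in otu_ids if o not in self.data.index]
        if missing:
            raise KeyError(f"OTUs not in count matrix: {missing}")
        return CountMatrix(self.data.loc[list(otu_ids)].copy())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.data.equals(other.data)


@dataclass
class SampleMeta:
    """Per-sample annotations defining gradients and comparisons.

    Required columns: treatment, day, gradient_id, density, is_fractionated.
    Density must be present for fractionated samples (and > 1.0 g/mL) and
    absent (NaN) for non-fractionated ones.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required column(s): {missing}")
        df = df.copy()
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        df["day"] = df["day"].astype(int)
        df["is_fractionated"] = df["is_fractionated"].astype(bool)
        df["density"] = pd.to_numeric(df["density"], errors="coerce")
        bad_treat = set(df["treatment"]) - set(TREATMENTS)
        if bad_treat:
            raise FormatError(f"unknown treatment label(s): {sorted(bad_treat)}")
        frac = df["is_fractionated"]
        if df.loc[frac, "density"].isna().any():
            bad = df.index[frac & df["density"].isna()].tolist()
            raise FormatError(f"fractionated samples missing density: {bad}")
        if df.loc[~frac, "density"].notna().any():
            bad = df.index[~frac & df["density"].notna()].tolist()
            raise FormatError(f"non-fractionated samples carry a density: {bad}")
        if (df.loc[frac, "density"] <= 1.0).any():
            raise FormatError("fraction density must exceed 1.0 g/mL")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def fractionated(self) -> pd.DataFrame:
        return self.data[self.data["is_fractionated"]]

    def non_fractionated(self) -> pd.DataFrame:
        return self.data[~self.data["is_fractionated"]]

    def gradient_samples(self, gradient_id: str) -> pd.DataFrame:
        sub = self.fractionated()
        return sub[sub["gradient_id"] == gradient_id]

    def check_against(self, m: CountMatrix) -> None:
        """Every sample referenced by metadata must exist in the matrix."""
        missing = [s for s in self.sample_ids if s not in m.data.columns]
        if missing:
            raise FormatError(f"metadata samples absent from counts: {missing}")


@dataclass
class TaxonomyTable:
    """OTU -> ordered rank labels (phylum ... genus).

    Missing labels are stored as the explicit marker ``"unclassified"``.
    """

    data: pd.DataFrame
    ranks: tuple[str, ...] = field(default=RANKS)

    def __post_init__(self) -> None:
        df = self.data.copy()
        _check_unique(df.index, "OTU")
        df.index = df.index.astype(str)
        df.index.name = "otu_id"
        for rank in self.ranks:
            if rank not in df.columns:
                df[rank] = UNCLASSIFIED
        df = df[list(self.ranks)].astype(str)
        df = df.replace({"": UNCLASSIFIED, "nan": UNCLASSIFIED, "NA": UNCLASSIFIED})
        self.data = df

    def labels(self, rank: str) -> pd.Series:
        if rank not in self.ranks:
            raise KeyError(f"unknown rank {rank!r}; known ranks: {list(self.ranks)}")
        return self.data[rank]


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read an OTU x sample count table.

    TSV dialect: tab-separated, UTF-8, header row of sample ids, first header
    cell ``otu_id``. BIOM dialect: BIOM 1.0 JSON (dense or sparse).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        except Exception as exc:  # malformed table
            raise FormatError(f"cannot parse count table {path}: {exc}") from exc
        non_numeric = df.select_dtypes(exclude="number").columns.tolist()
        if non_numeric:
            raise FormatError(f"non-numeric column(s) in count table: {non_numeric}")
        return CountMatrix(df)
    if format == "biom":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(m: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        m.data.to_csv(path, sep="\t")
    elif format == "biom":
        _write_biom_json(m, path)
    else:
        raise ValueError(f"unknown count-table format {format!r}")


def _read_biom_json(path: Path) -> CountMatrix:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        otu_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mat = np.zeros(shape)
        if doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        elif doc["matrix_type"] == "dense":
            mat = np.asarray(doc["data"], dtype=float)
        else:
            raise FormatError(f"unknown BIOM matrix_type {doc['matrix_type']!r}")
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed BIOM file {path}: {exc}") from exc
    return CountMatrix(pd.DataFrame(mat, index=otu_ids, columns=sample_ids))


def _write_biom_json(m: CountMatrix, path: Path) -> None:
    values = m.data.to_numpy()
    ii, jj = np.nonzero(values)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "hrsip",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(values.shape),
        "rows": [{"id": o, "metadata": None} for o in m.otu_ids],
        "columns": [{"id": s, "metadata": None} for s in m.sample_ids],
        "data": [[int(i), int(j), int(values[i, j])] for i, j in zip(ii, jj)],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_sample_meta(path: str | Path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    return TaxonomyTable(df)


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick phylogeny and validate tips/branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tree tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    return tree


# ---------------------------------------------------------------------------
# transformations


def relative_abundance(m: CountMatrix) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1.

    Raises on a zero-sum sample (proportions undefined), naming it.
    """
    totals = m.data.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    return m.data / totals


def aggregate_by_rank(m: CountMatrix, tax: TaxonomyTable, rank: str) -> CountMatrix:
    """Sum counts over OTUs sharing a rank label.

    OTUs without taxonomy (or with a missing label) are pooled into the
    explicit ``unclassified`` bucket, so per-sample totals are conserved.
    """
    labels = tax.labels(rank)  # KeyError for unknown rank
    assigned = labels.reindex(m.data.index).fillna(UNCLASSIFIED)
    grouped = m.data.groupby(assigned.to_numpy()).sum()
    grouped.index.name = rank
    return CountMatrix(grouped)
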
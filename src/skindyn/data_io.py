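"""Readers and writers for the tabular and tree formats the pipeline touches.

All tabular formats are plain TSV (UTF-8, ``#``-prefixed comment lines
ignored).  Sample and taxon order is preserved exactly as read; nothing is
sorted silently.  Writers emit a leading comment line with the tool version
so output provenance survives a round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountTable",
    "SampleMetadata",
    "TaxonomyTable",
    "DistanceMatrix",
    "FormatError",
    "SITES",
    "SEASONS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_matrix",
    "write_matrix",
]

logger = logging.getLogger(__name__)

#: The five skin sites sampled per individual per season.
SITES = ("forehead", "left_forearm", "right_forearm", "left_palm", "right_palm")

#: Season name -> integer index 1-4 (sampling order within the year).
SEASONS = {"winter": 1, "spring": 2, "summer": 3, "autumn": 4}

METADATA_COLUMNS = (
    "sample_id",
    "individual",
    "household",
    "site",
    "season",
    "occupancy",
    "age_group",
    "gender",
    "batch",
)


class FormatError(ValueError):
    """A file violated the format contract (duplicate ids, bad cells, ...)."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class CountTable:
    """Integer taxon x sample read-count matrix with aligned label lists."""

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_taxa, n_samples), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts must be non-negative")
        _check_unique(self.taxa, "taxon")
        _check_unique(self.samples, "sample")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)

    def select_taxa(self, keep: list[str]) -> "CountTable":
        idx = [self.taxa.index(t) for t in keep]
        return CountTable(list(keep), list(self.samples), self.counts[idx, :])

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in keep]
        return CountTable(list(self.taxa), list(keep), self.counts[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample design variables, one row per sample id."""

    frame: pd.DataFrame  # indexed by sample_id, columns METADATA_COLUMNS[1:]

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS[1:] if c not in self.frame.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise FormatError(f"duplicate sample id in metadata: {dup!r}")
        occ = self.frame["occupancy"]
        if (occ < 1).any():
            bad = self.frame.index[occ < 1][0]
            raise FormatError(f"occupancy < 1 for sample {bad!r}")
        bad_season = ~self.frame["season"].isin([1, 2, 3, 4])
        if bad_season.any():
            raise FormatError(
                f"season index outside 1-4 for sample "
                f"{self.frame.index[bad_season][0]!r}"
            )

    def for_samples(self, samples: list[str]) -> pd.DataFrame:
        missing = [s for s in samples if s not in self.frame.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {missing[:5]}")
        return self.frame.loc[samples]

    @property
    def households(self) -> dict[str, str]:
        """individual id -> household id."""
        sub = self.frame[["individual", "household"]].drop_duplicates()
        return dict(zip(sub["individual"], sub["household"]))

    @property
    def occupancies(self) -> dict[str, int]:
        """household id -> occupancy (number of residents)."""
        sub = self.frame[["household", "occupancy"]].drop_duplicates("household")
        return dict(zip(sub["household"], sub["occupancy"].astype(int)))


@dataclass
class TaxonomyTable:
    """taxon id -> ranked lineage; only the genus rank is used downstream."""

    frame: pd.DataFrame  # indexed by taxon id; columns kingdom..genus

    RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise FormatError(f"duplicate taxon id in taxonomy: {dup!r}")
        if "genus" not in self.frame.columns:
            raise FormatError("taxonomy table must have a 'genus' column")

    def genus_of(self, taxa: list[str]) -> list[str]:
        out = []
        for t in taxa:
            if t not in self.frame.index:
                raise FormatError(f"taxon {t!r} missing from taxonomy")
            g = self.frame.at[t, "genus"]
            out.append("unclassified" if pd.isna(g) or g == "" else str(g))
        return out


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal, labelled by sample."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise FormatError("distance matrix shape does not match ids")
        _check_unique(self.ids, "sample")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric")
        if self.data.size and np.abs(np.diag(self.data)).max() > 1e-12:
            raise FormatError("distance matrix diagonal is not zero")
        if self.data.size and self.data.min() < -1e-12:
            raise FormatError("distances must be non-negative")
        np.fill_diagonal(self.data, 0.0)
        self.data = np.clip(self.data, 0.0, None)
        self._index = {s: i for i, s in enumerate(self.ids)}

    def between(self, a: str, b: str) -> float:
        return float(self.data[self._index[a], self._index[b]])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, header=0)


_HEADER = "# skindyn 0.1.0\n"


def read_count_table(path) -> CountTable:
    """Parse a taxa x samples TSV of integer read counts.

    The header is parsed directly (not via pandas) so duplicated sample ids
    are detected rather than silently renamed.
    """
    with open(path, encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh
                if line.strip() and not line.startswith("#")]
    if not rows:
        raise FormatError("no taxa: count table is empty")
    samples = rows[0][1:]
    if not samples:
        raise FormatError("no samples: count table has no sample columns")
    if len(rows) == 1:
        raise FormatError("no taxa: count table has no data rows")
    taxa = [r[0] for r in rows[1:]]
    width = len(rows[0])
    for r in rows[1:]:
        if len(r) != width:
            raise FormatError(f"ragged row for taxon {r[0]!r}")
    try:
        counts = np.array([[float(c) for c in r[1:]] for r in rows[1:]])
    except ValueError as e:
        raise FormatError(f"non-numeric cell in count table: {e}") from e
    if np.isnan(counts).any():
        raise FormatError("missing cell in count table")
    if not np.all(counts == np.floor(counts)):
        raise FormatError("non-integer cell in count table")
    if counts.min() < 0:
        raise FormatError("negative cell in count table")
    return CountTable(taxa, samples, counts.astype(np.int64))


def write_count_table(table: CountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write("taxon_id\t" + "\t".join(table.samples) + "\n")
        for i, t in enumerate(table.taxa):
            fh.write(t + "\t" + "\t".join(str(int(c)) for c in table.counts[i]) + "\n")


def read_metadata(path) -> SampleMetadata:
    """Parse the 9-column sample metadata TSV; season tokens map to index 1-4."""
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    season = []
    for tok in df["season"]:
        t = str(tok).strip().lower()
        if t in SEASONS:
            season.append(SEASONS[t])
        elif t in {"1", "2", "3", "4"}:
            season.append(int(t))
        else:
            raise FormatError(
                f"unknown season token {tok!r}; expected one of {sorted(SEASONS)}"
            )
    site = []
    for tok in df["site"]:
        t = str(tok).strip().lower()
        if t not in SITES:
            raise FormatError(f"unknown site token {tok!r}; allowed sites: {SITES}")
        site.append(t)
    out = df.copy()
    out["season"] = season
    out["site"] = site
    out["occupancy"] = out["occupancy"].astype(int)
    out = out.set_index("sample_id")
    return SampleMetadata(out[list(METADATA_COLUMNS[1:])])


def write_metadata(meta: SampleMetadata, path) -> None:
    inv_season = {v: k for k, v in SEASONS.items()}
    df = meta.frame.reset_index(names="sample_id").copy()
    df["season"] = [inv_season[s] for s in df["season"]]
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    if df.columns[0] != "taxon_id":
        raise FormatError("taxonomy table must start with a 'taxon_id' column")
    return TaxonomyTable(df.set_index("taxon_id"))


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        tax.frame.reset_index(names="taxon_id").to_csv(fh, sep="\t", index=False)


def read_tree(path) -> TreeNode:
    """Parse a rooted newick tree; missing branch lengths become 0 (warned)."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError(f"negative branch length at {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        logger.warning("%d branch lengths missing; set to 0.0", n_missing)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_matrix(path) -> DistanceMatrix:
    df = _read_tsv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    cols = [str(c) for c in df.columns[1:]]
    if cols != ids:
        raise FormatError("distance matrix row and column labels differ")
    return DistanceMatrix(ids, data)


def write_matrix(dm: DistanceMatrix, path) -> None:
    """Write a square labelled TSV that reads back within 1e-12."""
    with open(path, "w") as fh:
        fh.write(_HEADER)
        fh.write("sample_id\t" + "\t".join(dm.ids) + "\n")
        for i, s in enumerate(dm.ids):
            fh.write(s + "\t" + "\t".join(repr(float(x)) for x in dm.data[i]) + "\n")
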
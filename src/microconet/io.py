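"""Tabular and tree input/output plus count-level preprocessing.

The on-disk formats are deliberately plain: tab-separated UTF-8 tables with a
header row ('#'-prefixed comment lines are skipped) and newick trees. The
in-memory containers are thin, validated wrappers around pandas objects.

Counts pass through three preprocessing steps before any analysis:

1. rare-OTU removal — taxa seen in fewer than ``min_samples`` samples or with
   fewer than ``min_total`` reads across the whole cohort are treated as
   likely artifacts and dropped;
2. rarefaction — every sample is subsampled *without replacement* to a common
   depth (default 6,000 reads) so that richness estimates are comparable;
   samples below the depth are dropped and reported;
3. closure — conversion to relative abundances (rows summing to one).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "UNCLASSIFIED",
    "CountTable",
    "TaxonomyMap",
    "RarefyResult",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "read_metadata",
    "validate_metadata",
    "filter_rare_otus",
    "rarefy",
    "to_relative_abundance",
    "aggregate_by_rank",
    "read_tree",
    "write_tree",
]

#: explicit marker pooled over taxa lacking an assignment at a rank
UNCLASSIFIED = "unclassified"

GROUPS = ("CTRL", "ERA")
TIMEPOINTS = ("T0", "T1")

#: metadata columns that are not numeric clinical/metabolite variables
METADATA_COLUMNS = ("group", "timepoint", "subject_id")


class FormatError(ValueError):
    """A file violated the expected tabular format."""


@dataclass
class CountTable:
    """Integer abundance matrix, samples x taxa.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by taxon id, nonnegative integer
        counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept float input only when every cell is integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
                raise FormatError(
                    "non-integer count at sample "
                    f"{df.index[bad[0]]!r}, taxon {df.columns[bad[1]]!r}"
                )
            df = df.astype(np.int64)
        if arr.size and (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                "negative count at sample "
                f"{df.index[bad[0]]!r}, taxon {df.columns[bad[1]]!r}"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class TaxonomyMap:
    """taxon id -> ordered lineage (at minimum genus and species).

    Missing assignments are stored as the explicit :data:`UNCLASSIFIED`
    marker, never as empty strings or NaN.
    """

    data: pd.DataFrame  # index: taxon_id; columns: ranks

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise FormatError("duplicate taxon ids in taxonomy map")
        for rank in ("genus", "species"):
            if rank not in df.columns:
                raise FormatError(f"taxonomy map lacks required rank {rank!r}")
        df = df.fillna(UNCLASSIFIED)
        for rank in df.columns:
            empties = df.index[df[rank].astype(str).str.len() == 0]
            if len(empties):
                raise FormatError(
                    f"empty {rank} label for taxon {empties[0]!r}; use "
                    f"{UNCLASSIFIED!r} explicitly"
                )
        object.__setattr__(self, "data", df.astype(str))

    @property
    def ranks(self) -> list[str]:
        return list(self.data.columns)

    def lineage(self, taxon_id: str) -> dict[str, str]:
        return self.data.loc[taxon_id].to_dict()


@dataclass
class RarefyResult:
    """Rarefied table plus the samples that fell below the depth."""

    table: CountTable
    dropped: list[str] = field(default_factory=list)
    depth: int = 0
    seed: int | None = None


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=None)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise FormatError(str(exc)) from exc


def read_count_table(path, orientation: str = "samples") -> CountTable:
    """Read a TSV count table.

    Parameters
    ----------
    path : str or file-like
        Tab-separated file; first column holds ids, header row present.
    orientation : {"samples", "taxa"}
        Whether rows of the file are samples (default) or taxa. The result is
        always samples x taxa.
    """
    if orientation not in ("samples", "taxa"):
        raise ValueError(f"orientation must be 'samples' or 'taxa', got {orientation!r}")
    df = _read_tsv(path)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise FormatError(
                f"non-numeric count in column {col!r}, row {bad!r}"
            )
    if orientation == "taxa":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df)


def write_count_table(table: CountTable, path, orientation: str = "samples") -> None:
    df = table.data if orientation == "samples" else table.data.T
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a TSV taxonomy map: first column taxon id, then rank columns."""
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    return TaxonomyMap(df)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a per-sample metadata table (see validate_metadata)."""
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    return validate_metadata(df)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the group/timepoint/subject pairing invariants of the design.

    Expected columns: ``group`` in {CTRL, ERA}, ``timepoint`` in {T0, T1}
    (controls are T0 only), ``subject_id`` shared across an ERA subject's two
    samples, and any number of numeric clinical/metabolite columns.
    """
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"metadata lacks required column {col!r}")
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    bad_group = set(meta["group"]) - set(GROUPS)
    if bad_group:
        raise FormatError(f"unknown group labels: {sorted(bad_group)}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise FormatError(f"unknown timepoint labels: {sorted(bad_tp)}")
    ctrl_t1 = meta[(meta["group"] == "CTRL") & (meta["timepoint"] != "T0")]
    if len(ctrl_t1):
        raise FormatError(
            f"control samples must be T0 only: {list(ctrl_t1.index[:3])}"
        )
    era = meta[meta["group"] == "ERA"]
    dup = era.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise FormatError(
            "an ERA subject appears more than once per timepoint: "
            f"{list(era.index[dup][:3])}"
        )
    for col in meta.columns:
        if col in METADATA_COLUMNS:
            continue
        if not pd.api.types.is_numeric_dtype(meta[col]):
            raise FormatError(f"variable column {col!r} is not numeric")
    return meta


def variable_columns(meta: pd.DataFrame) -> list[str]:
    """Names of the numeric clinical/metabolite columns of a metadata table."""
    return [c for c in meta.columns if c not in METADATA_COLUMNS]


def strata(meta: pd.DataFrame) -> dict[str, pd.Index]:
    """Sample ids per stratum: CTRL, ERA-T0, ERA-T1 (empty strata omitted)."""
    out: dict[str, pd.Index] = {}
    ctrl = meta.index[meta["group"] == "CTRL"]
    if len(ctrl):
        out["CTRL"] = ctrl
    for tp in TIMEPOINTS:
        idx = meta.index[(meta["group"] == "ERA") & (meta["timepoint"] == tp)]
        if len(idx):
            out[f"ERA-{tp}"] = idx
    return out


# ---------------------------------------------------------------------------
# count-level preprocessing


def filter_rare_otus(
    table: CountTable, min_samples: int = 2, min_total: int = 10
) -> CountTable:
    """Drop likely-artifact taxa.

    A taxon is removed when it is present (count > 0) in fewer than
    ``min_samples`` samples OR its total count across all samples is below
    ``min_total``. The sample set is unchanged.
    """
    df = table.data
    prevalence = (df > 0).sum(axis=0)
    totals = df.sum(axis=0)
    keep = (prevalence >= min_samples) & (totals >= min_total)
    return CountTable(df.loc[:, keep])


def rarefy(table: CountTable, depth: int = 6000, seed: int | None = None) -> RarefyResult:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and listed in the
    result. Subsampling is a multivariate hypergeometric draw, i.e. a uniform
    subsample of the reads without replacement, reproducible given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    df = table.data
    totals = df.sum(axis=1)
    kept = totals.index[totals >= depth]
    dropped = [s for s in df.index if s not in set(kept)]
    if not len(kept):
        raise ValueError(f"no samples reach rarefaction depth {depth}")
    rows = np.empty((len(kept), df.shape[1]), dtype=np.int64)
    for i, s in enumerate(kept):
        rows[i] = rng.multivariate_hypergeometric(df.loc[s].to_numpy(), depth)
    out = pd.DataFrame(rows, index=kept, columns=df.columns)
    return RarefyResult(CountTable(out), dropped=dropped, depth=depth, seed=seed)


def to_relative_abundance(table: CountTable) -> pd.DataFrame:
    """Close the composition: divide each sample's counts by its total."""
    df = table.data
    totals = df.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    return df.div(totals, axis=0)


def aggregate_by_rank(table: CountTable, taxonomy: TaxonomyMap, rank: str) -> CountTable:
    """Sum counts over taxa sharing a rank label (genus or species).

    Taxa unassigned at the rank are pooled under :data:`UNCLASSIFIED`. The
    grand total is conserved exactly.
    """
    if rank not in taxonomy.ranks:
        raise ValueError(f"rank {rank!r} not in taxonomy ({taxonomy.ranks})")
    missing = [t for t in table.taxon_ids if t not in taxonomy.data.index]
    if missing:
        raise KeyError(f"taxa missing from taxonomy map: {missing[:5]}")
    labels = taxonomy.data.loc[table.taxon_ids, rank]
    agg = table.data.T.groupby(labels.to_numpy()).sum().T
    agg.columns = agg.columns.astype(str)
    return CountTable(agg)


# ---------------------------------------------------------------------------
# trees


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(path, format="newick")
    except Exception as exc:
        raise FormatError(f"malformed newick: {exc}") from exc
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise FormatError(
                f"branch length of node {node.name!r} is not finite and >= 0"
            )
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError("tree leaf labels are not unique")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def tree_from_newick(newick: str) -> TreeNode:
    """Parse a newick string (convenience wrapper around read_tree)."""
    return read_tree(_io.StringIO(newick))


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
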
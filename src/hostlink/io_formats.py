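"""Readers, writers and cross-validation for the package's on-disk artifacts.

All tabular artifacts are plain TSV (tab-separated, UTF-8, ``.`` decimal);
trees are Newick; results and ground truth are JSON.  The in-memory
conventions used throughout the package are:

* **count table** — :class:`pandas.DataFrame`, rows = samples, columns =
  taxa (ASVs), non-negative integers;
* **sample metadata** — :class:`pandas.DataFrame` indexed by sample id with
  at least the columns ``environment`` (``worm``/``apple``), ``apple_id``,
  ``timepoint`` and optionally ``batch``, ``pH``, ``worm_presence`` and
  weather covariates.  Missing values are empty cells on disk, ``NaN`` in
  memory — never sentinel numbers;
* **phylogeny** — a rooted :class:`skbio.TreeNode` with branch lengths;
* **metabolite table** — :class:`MetaboliteTable` below.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import FormatError

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("environment", "apple_id", "timepoint")


@dataclass
class MetaboliteTable:
    """Sample x metabolite abundance matrix with a named internal standard.

    The internal-standard column must be present and strictly positive in
    every sample; it anchors the ratio normalization downstream.
    """

    values: pd.DataFrame
    internal_standard_id: str

    def __post_init__(self) -> None:
        if self.internal_standard_id not in self.values.columns:
            raise FormatError(
                f"internal standard {self.internal_standard_id!r} missing from table"
            )
        std = self.values[self.internal_standard_id]
        bad = std.index[~(std > 0)].tolist()
        if bad:
            raise FormatError(
                f"internal standard {self.internal_standard_id!r} not strictly "
                f"positive in samples: {bad}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups}")


def validate_count_table(table: pd.DataFrame) -> None:
    """Raise :class:`FormatError` naming the offending cell on any violation."""
    _check_unique(table.index, "sample ids")
    _check_unique(table.columns, "taxon ids")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count table contains non-numeric cells")
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise FormatError(
            f"negative count at sample {table.index[i]!r}, taxon {table.columns[j]!r}"
        )
    frac = np.argwhere(values != np.floor(values))
    if frac.size:
        i, j = frac[0]
        raise FormatError(
            f"non-integer count at sample {table.index[i]!r}, taxon {table.columns[j]!r}"
        )


def read_count_table(path) -> pd.DataFrame:
    """Read a sample x taxon TSV (first column sample ids, header taxon ids)."""
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # ragged rows, empty file, ...
        raise FormatError(f"cannot parse count table {path}: {exc}") from exc
    table.index = table.index.astype(str)
    table.index.name = None
    table.columns = table.columns.astype(str)
    validate_count_table(table)
    return table.astype(np.int64)


def write_count_table(table: pd.DataFrame, path) -> None:
    validate_count_table(table)
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_metabolite_table(path, internal_standard_id: str) -> MetaboliteTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return MetaboliteTable(values=values, internal_standard_id=internal_standard_id)


def write_metabolite_table(table: MetaboliteTable, path) -> None:
    table.values.to_csv(path, sep="\t", index_label="sample_id")


def read_newick(source) -> skbio.TreeNode:
    """Parse a Newick tree; unrooted input (trifurcating root) is midpoint-rooted."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        source = io.StringIO(source)
    try:
        tree = skbio.TreeNode.read(source, format="newick")
    except Exception as exc:
        raise FormatError(f"unparseable Newick input: {exc}") from exc
    leaves = [tip.name for tip in tree.tips()]
    _check_unique(leaves, "leaf labels")
    if len(tree.children) > 2:
        logger.info("input tree is unrooted (%d root children); midpoint rooting",
                    len(tree.children))
        tree = tree.root_at_midpoint()
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`; empty iff the dataset is consistent."""

    findings: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.findings.append(message)

    @property
    def ok(self) -> bool:
        return not self.findings

    def __iter__(self):
        return iter(self.findings)

    def __len__(self) -> int:
        return len(self.findings)


def validate_dataset(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    tree: skbio.TreeNode | None = None,
    metabolites: MetaboliteTable | None = None,
) -> ValidationReport:
    """Cross-check referential integrity between all dataset pieces.

    Pure function: inputs are never mutated; every violation becomes one
    finding in the returned report.
    """
    report = ValidationReport()

    meta_ids = set(metadata.index)
    for sample in counts.index:
        if sample not in meta_ids:
            report.add(f"sample {sample!r} missing from metadata")

    if tree is not None:
        leaf_names = {tip.name for tip in tree.tips()}
        for taxon in counts.columns:
            if taxon not in leaf_names:
                report.add(f"taxon {taxon!r} missing from tree")

    apples = set(metadata.index[metadata["environment"] == "apple"])
    worms = metadata[metadata["environment"] == "worm"]
    for sample, apple_id in worms["apple_id"].items():
        if pd.isna(apple_id) or apple_id not in apples:
            report.add(
                f"worm sample {sample!r} references unknown apple_id {apple_id!r}"
            )

    if "timepoint" in metadata.columns:
        bad_tp = metadata.index[metadata["timepoint"].fillna(1) < 1].tolist()
        for sample in bad_tp:
            report.add(f"sample {sample!r} has timepoint < 1")

    if metabolites is not None:
        have = set(metabolites.values.index)
        for sample in sorted(apples & set(counts.index)):
            if sample not in have:
                report.add(f"apple sample {sample!r} missing from metabolite table")

    return report
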
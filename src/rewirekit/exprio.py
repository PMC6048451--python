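"""Expression-matrix I/O, probeset collapsing, and gene-panel extraction.

The on-disk format is plain UTF-8 TSV: first column header ``gene_id``,
remaining columns one per sample, no quoting.  Values are log-scale
intensities; scientific notation is accepted on read.  Missing values are
rejected at read time (downstream statistics assume complete matrices).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "collapse_probesets",
    "extract_panel",
    "load_mapk_panel",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with row/column identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene ids: {sorted(dupes)[:10]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample ids: {sorted(dupes)[:10]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            cells = [
                f"({self.gene_ids[i]}, {self.sample_ids[j]})" for i, j in bad[:10]
            ]
            raise ValueError(f"non-finite values at cells: {', '.join(cells)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(float))

    def select_samples(self, which) -> "ExpressionMatrix":
        """Subset samples by boolean mask or integer index array."""
        which = np.asarray(which)
        if which.dtype == bool:
            which = np.flatnonzero(which)
        ids = [self.sample_ids[i] for i in which]
        return ExpressionMatrix(list(self.gene_ids), ids, self.values[:, which])

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column ``gene_id``)."""
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype={0: str}, float_precision="round_trip"
    )
    frame.index = frame.index.astype(str)
    if frame.isna().any().any():
        stacked = frame.stack(future_stack=True)
        bad = stacked[stacked.isna()].index.tolist()[:10]
        raise ValueError(f"missing values in {path} at cells: {bad}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:  # non-numeric cell
        raise ValueError(f"non-numeric values in {path}: {exc}") from exc
    return ExpressionMatrix(list(frame.index), [str(c) for c in frame.columns], values)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix to TSV with full round-trip precision."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    # default float formatting is the shortest exact repr -> lossless round trip
    frame.to_csv(path, sep="\t")


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a sample annotation TSV (first column ``sample_id``)."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    first = frame.columns[0]
    if first != "sample_id":
        raise ValueError(f"annotation file must start with 'sample_id', got {first!r}")
    frame = frame.set_index("sample_id")
    return frame


def match_annotation(
    matrix: ExpressionMatrix, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Align annotation rows to matrix samples; report unmatched annotation ids."""
    unmatched = [s for s in annotation.index if s not in set(matrix.sample_ids)]
    if unmatched:
        logger.warning("%d annotated samples not in matrix: %s", len(unmatched), unmatched[:5])
    aligned = annotation.reindex([s for s in matrix.sample_ids if s in annotation.index])
    return aligned, unmatched


@dataclass
class CollapseReport:
    """Bookkeeping from probeset-to-gene collapsing."""

    chosen: dict[str, str] = field(default_factory=dict)  # gene -> probeset kept
    dropped_probesets: list[str] = field(default_factory=list)  # unmapped probes
    ties: list[str] = field(default_factory=list)  # genes whose mean tie was broken


def collapse_probesets(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> tuple[ExpressionMatrix, CollapseReport]:
    """Collapse a probeset-keyed matrix to genes.

    For each gene with several mapped probesets, the probeset with the
    maximum across-sample mean intensity is retained.  Exact mean ties are
    broken toward the lexicographically smallest probeset id (logged).
    Probesets absent from the map are dropped and reported.
    """
    report = CollapseReport()
    by_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            report.dropped_probesets.append(probe)
            continue
        by_gene.setdefault(str(gene), []).append(i)
    if not by_gene:
        raise ValueError("no probesets in the matrix are covered by the probe map")

    means = matrix.values.mean(axis=1)
    genes: list[str] = []
    rows: list[int] = []
    for gene in sorted(by_gene):
        idx = by_gene[gene]
        gene_means = means[idx]
        best = gene_means.max()
        winners = [i for i in idx if means[i] == best]
        if len(winners) > 1:
            winners.sort(key=lambda i: matrix.gene_ids[i])
            report.ties.append(gene)
            logger.info(
                "gene %s: mean tie among %d probesets, kept %s",
                gene, len(winners), matrix.gene_ids[winners[0]],
            )
        keep = winners[0]
        report.chosen[gene] = matrix.gene_ids[keep]
        genes.append(gene)
        rows.append(keep)
    collapsed = ExpressionMatrix(genes, list(matrix.sample_ids), matrix.values[rows])
    return collapsed, report


def extract_panel(
    matrix: ExpressionMatrix, panel: Sequence[str]
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a matrix to a gene panel, preserving panel order.

    Returns the restricted matrix and the list of panel genes absent from
    the matrix (never silently dropped).  Duplicate panel entries are
    deduplicated with a warning.
    """
    seen: set[str] = set()
    unique_panel: list[str] = []
    for g in panel:
        g = str(g)
        if g in seen:
            warnings.warn(f"duplicate panel gene {g!r} deduplicated", stacklevel=2)
            continue
        seen.add(g)
        unique_panel.append(g)

    present = set(matrix.gene_ids)
    mapped = [g for g in unique_panel if g in present]
    unmapped = [g for g in unique_panel if g not in present]
    if not mapped:
        raise ValueError("no panel genes found in the matrix")
    return matrix.select_genes(mapped), unmapped


def load_mapk_panel() -> list[str]:
    """Load the packaged 224-gene MAPK panel fixture."""
    text = resources.files("rewirekit.data").joinpath("mapk_panel_224.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]
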
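"""Loading and stratification of expression data.

Expression arrives as a genes × samples matrix (GCT 1.2 or plain TSV, values
already normalized, e.g. TPM) together with a sample-attribute table mapping
every sample to a tissue label and a donor age group.  Stratification slices
the matrix into one sample-aligned block per age group — the unit on which
pairwise correlation is computed — pooling samples across the selected
tissues within each age group.

Strata with fewer than three samples are constructed but flagged
``undersized``: a correlation p-value is meaningless below three points, so
the network builder emits no edges from them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, GeneLookupError
from .model import AgeGroup

__all__ = [
    "ALL_TISSUES",
    "ExpressionDataset",
    "ExpressionStratum",
    "SampleAnnotation",
    "load_expression",
    "stratify",
    "write_annotations",
    "write_gct",
]

logger = logging.getLogger(__name__)

#: Sentinel: do not filter by tissue (pool every tissue in the dataset).
ALL_TISSUES = None

_ANNOTATION_COLUMNS = ("sample_id", "tissue", "age_group")


@dataclass(frozen=True)
class SampleAnnotation:
    """Tissue and age-group attributes of one expression sample."""

    sample_id: str
    tissue: str
    age_group: AgeGroup


@dataclass(frozen=True)
class ExpressionDataset:
    """Annotated genes × samples expression matrix.

    ``values[i, k]`` is the normalized expression of ``genes[i]`` in
    ``samples[k]``; column order is the alignment contract every
    downstream vector slice relies on.
    """

    genes: tuple[str, ...]
    samples: tuple[SampleAnnotation, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene IDs in expression dataset")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self.genes.index(gene)]
        except ValueError:
            raise GeneLookupError(f"gene {gene!r} not in dataset") from None


@dataclass(frozen=True)
class ExpressionStratum:
    """Sample-aligned expression vectors for one age group.

    ``vectors[g][k]`` and ``vectors[h][k]`` always refer to the same sample
    (``sample_ids[k]``), which is what makes pairwise correlation valid.
    """

    age_group: AgeGroup
    tissues: frozenset[str]
    vectors: Mapping[str, np.ndarray]
    sample_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def undersized(self) -> bool:
        """True when n < 3; such strata never contribute edges."""
        return self.n < 3


def _read_annotations(path: Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"annotation file {path} is empty") from exc
    missing = [c for c in _ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"annotation file missing column(s): {', '.join(missing)}"
        )
    dupes = table["sample_id"][table["sample_id"].duplicated()]
    if len(dupes):
        raise FormatError(f"duplicate sample_id in annotations: {dupes.iloc[0]!r}")
    return table


def _read_matrix(path: Path) -> pd.DataFrame:
    """Read a GCT 1.2 or plain TSV expression matrix, genes as index."""
    with open(path, "r", encoding="utf-8", newline=None) as handle:
        first = handle.readline().rstrip("\r\n")
    if first.startswith("#1.2"):
        with open(path, "r", encoding="utf-8", newline=None) as handle:
            handle.readline()
            dims = handle.readline().rstrip("\r\n").split("\t")
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"malformed GCT dimensions line in {path}") from exc
            body = pd.read_csv(handle, sep="\t", index_col=0)
        if "Description" in body.columns:
            body = body.drop(columns=["Description"])
        if body.shape != (n_genes, n_samples):
            raise FormatError(
                f"GCT dimensions line declares {n_genes}x{n_samples} but body "
                f"is {body.shape[0]}x{body.shape[1]} in {path}"
            )
        return body
    return pd.read_csv(path, sep="\t", index_col=0)


def load_expression(
    expression_path: str | Path, annotations_path: str | Path
) -> ExpressionDataset:
    """Load an expression matrix together with its sample attributes.

    Every expression column must have an annotation row; samples whose
    age-group label is not one of the six canonical decade bins are dropped
    with a logged count (they carry no time-point information).
    """
    expression_path = Path(expression_path)
    annotations_path = Path(annotations_path)
    matrix = _read_matrix(expression_path)
    annotations = _read_annotations(annotations_path)

    by_sample = annotations.set_index("sample_id")
    missing = [c for c in matrix.columns if c not in by_sample.index]
    if missing:
        raise FormatError(
            f"no annotation row for expression column(s): {missing}"
        )

    samples: list[SampleAnnotation] = []
    keep_columns: list[str] = []
    dropped = 0
    for column in matrix.columns:
        row = by_sample.loc[column]
        if not AgeGroup.is_canonical(row["age_group"]):
            dropped += 1
            continue
        samples.append(
            SampleAnnotation(
                sample_id=column,
                tissue=row["tissue"],
                age_group=AgeGroup.from_label(row["age_group"]),
            )
        )
        keep_columns.append(column)
    if dropped:
        logger.warning(
            "dropped %d sample(s) without a canonical age-group label", dropped
        )

    values = matrix[keep_columns].to_numpy(dtype=float)
    return ExpressionDataset(
        genes=tuple(str(g) for g in matrix.index),
        samples=tuple(samples),
        values=values,
    )


def stratify(
    ds: ExpressionDataset,
    genes: Sequence[str],
    tissues: set[str] | frozenset[str] | Sequence[str] | None = ALL_TISSUES,
) -> list[ExpressionStratum]:
    """Slice a dataset into per-age-group strata for the requested genes.

    Samples from all selected tissues are pooled within each age group.
    Returns one stratum per age group with at least one surviving sample,
    in ascending temporal order; an empty tissue intersection yields an
    empty list with a warning rather than an error.
    """
    absent = [g for g in genes if g not in ds.genes]
    if absent:
        raise GeneLookupError(f"gene(s) not in dataset: {absent}")
    tissue_set = None if tissues is ALL_TISSUES else {str(t) for t in tissues}

    gene_rows = {g: ds.genes.index(g) for g in genes}
    column_ids: dict[str, list[int]] = {}
    for k, sample in enumerate(ds.samples):
        if tissue_set is not None and sample.tissue not in tissue_set:
            continue
        column_ids.setdefault(sample.age_group.label, []).append(k)

    if not column_ids:
        logger.warning("no sample survives the tissue filter; empty stratification")
        return []

    strata: list[ExpressionStratum] = []
    for label in sorted(column_ids, key=lambda lab: AgeGroup(lab).index):
        columns = column_ids[label]
        vectors = {
            g: ds.values[row, columns].copy() for g, row in gene_rows.items()
        }
        strata.append(
            ExpressionStratum(
                age_group=AgeGroup(label),
                tissues=frozenset(ds.samples[k].tissue for k in columns),
                vectors=vectors,
                sample_ids=tuple(ds.samples[k].sample_id for k in columns),
            )
        )
    return strata


def write_gct(ds: ExpressionDataset, path: str | Path) -> Path:
    """Write a dataset as a GCT 1.2 file (LF endings, 6-decimal values)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("#1.2\n")
        handle.write(f"{ds.n_genes}\t{ds.n_samples}\n")
        header = ["Name", "Description"] + [s.sample_id for s in ds.samples]
        handle.write("\t".join(header) + "\n")
        for i, gene in enumerate(ds.genes):
            row = [gene, gene] + [f"{v:.6f}" for v in ds.values[i]]
            handle.write("\t".join(row) + "\n")
    return path


def write_annotations(ds: ExpressionDataset, path: str | Path) -> Path:
    """Write the sample-attribute table matching :func:`write_gct` output."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for s in ds.samples:
            handle.write(f"{s.sample_id}\t{s.tissue}\t{s.age_group.label}\n")
    return path
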
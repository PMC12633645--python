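"""Gene-identifier harmonization.

User-facing gene lists arrive as a mix of symbols, aliases and versioned or
unversioned Ensembl/GENCODE identifiers.  Everything downstream (pair
generation, expression lookup, exports) operates on canonical versioned IDs,
so the first pipeline step maps every query alias onto one row of a
reference gene table.

Matching rules, in priority order:

1. exact canonical ID ("ENSG00000182944.19"),
2. version-tolerant canonical ID ("ENSG00000182944" matches any version),
3. case-insensitive official symbol,
4. case-insensitive entry in the optional pipe-separated alias column.

An alias hitting more than one row at its matching level is an error —
silent disambiguation would corrupt the pair set.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import AmbiguousAliasError, FormatError, ResolutionError

__all__ = [
    "GeneRecord",
    "ReferenceGeneTable",
    "bundled_reference_path",
    "load_reference_table",
    "resolve_genes",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("symbol", "canonical_id")
_OPTIONAL_COLUMNS = ("gene_type", "description", "aliases")


@dataclass(frozen=True)
class GeneRecord:
    """Resolved identity of one input gene."""

    query_alias: str
    canonical_id: str
    symbol: str
    gene_type: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.canonical_id:
            raise ResolutionError("GeneRecord requires a nonempty canonical_id")
        if not self.symbol:
            raise ResolutionError("GeneRecord requires a nonempty symbol")


def _strip_version(identifier: str) -> str:
    return identifier.split(".", 1)[0]


class ReferenceGeneTable:
    """In-memory reference gene table with alias lookup indices."""

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(
                f"reference table missing required column(s): {', '.join(missing)}"
            )
        if len(frame) == 0:
            raise FormatError("reference table is empty")
        frame = frame.copy()
        for col in _OPTIONAL_COLUMNS:
            if col not in frame.columns:
                frame[col] = ""
        frame = frame.fillna("")
        dupes = frame["canonical_id"][frame["canonical_id"].duplicated()]
        if len(dupes):
            raise FormatError(
                f"duplicate canonical_id in reference table: {dupes.iloc[0]!r}"
            )
        if (frame["symbol"].str.len() == 0).any():
            raise FormatError("reference table contains an empty symbol")
        self._frame = frame.reset_index(drop=True)

        # lookup indices: key -> list of row positions
        self._by_id: dict[str, list[int]] = {}
        self._by_unversioned: dict[str, list[int]] = {}
        self._by_symbol: dict[str, list[int]] = {}
        self._by_alias: dict[str, list[int]] = {}
        for row_idx, row in self._frame.iterrows():
            self._by_id.setdefault(row["canonical_id"], []).append(row_idx)
            self._by_unversioned.setdefault(
                _strip_version(row["canonical_id"]), []
            ).append(row_idx)
            self._by_symbol.setdefault(row["symbol"].lower(), []).append(row_idx)
            for alias in str(row["aliases"]).split("|"):
                alias = alias.strip().lower()
                if alias:
                    self._by_alias.setdefault(alias, []).append(row_idx)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def lookup(self, alias: str) -> GeneRecord | None:
        """Resolve one alias; ``None`` if no rule matches.

        Raises :class:`AmbiguousAliasError` when the first matching rule
        hits more than one row.
        """
        query = alias.strip()
        for index in (
            self._by_id.get(query),
            self._by_unversioned.get(query),
            self._by_symbol.get(query.lower()),
            self._by_alias.get(query.lower()),
        ):
            if index is None:
                continue
            if len(index) > 1:
                ids = [self._frame.at[i, "canonical_id"] for i in index]
                raise AmbiguousAliasError(
                    f"alias {alias!r} matches multiple canonical IDs: {ids}"
                )
            row = self._frame.iloc[index[0]]
            return GeneRecord(
                query_alias=alias,
                canonical_id=row["canonical_id"],
                symbol=row["symbol"],
                gene_type=row["gene_type"],
                description=row["description"],
            )
        return None


def load_reference_table(path: str | Path) -> ReferenceGeneTable:
    """Load a reference gene table from a header-bearing TSV file.

    Required columns: ``symbol``, ``canonical_id``; recognized optional
    columns: ``gene_type``, ``description``, ``aliases`` (pipe-separated).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"reference table {path} is empty") from exc
    return ReferenceGeneTable(frame)


def bundled_reference_path() -> Path:
    """Path of the small reference-table fixture shipped with the package.

    Covers the eight aging/Alzheimer case-study genes plus a few common
    aliases; intended for examples and tests, not as a full annotation.
    """
    return Path(
        importlib.resources.files("tgcn").joinpath("data/reference_genes.tsv")
    )


def resolve_genes(
    aliases: Sequence[str],
    ref: ReferenceGeneTable,
    strict: bool = True,
) -> list[GeneRecord]:
    """Map user aliases to canonical gene records.

    One record per distinct resolvable alias, in first-occurrence input
    order; aliases that resolve to the same canonical ID collapse to one
    record.  Unresolved aliases raise :class:`ResolutionError` in strict
    mode (default) and warn in lenient mode; a fully unresolvable input
    always raises.
    """
    trimmed = [a.strip() for a in aliases if a and a.strip()]
    if not trimmed:
        raise ResolutionError("no gene aliases supplied")

    records: list[GeneRecord] = []
    seen_ids: set[str] = set()
    seen_aliases: set[str] = set()
    unresolved: list[str] = []
    for alias in trimmed:
        key = alias.lower()
        if key in seen_aliases:
            continue
        seen_aliases.add(key)
        record = ref.lookup(alias)
        if record is None:
            unresolved.append(alias)
            continue
        if record.canonical_id in seen_ids:
            continue
        seen_ids.add(record.canonical_id)
        records.append(record)

    if not records:
        raise ResolutionError(
            f"none of the supplied aliases resolved: {unresolved}"
        )
    if unresolved:
        message = f"unresolved gene alias(es): {unresolved}"
        if strict:
            raise ResolutionError(message)
        warnings.warn(message, stacklevel=2)
        logger.warning(message)
    return records
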
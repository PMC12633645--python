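"""Temporal-network construction engine.

Given resolved genes and a stratified expression dataset, the builder:

1. enumerates all unordered gene pairs P = {{g_i, g_j} : i < j};
2. for every age group a, tests each pair's Pearson correlation on the
   pooled stratum samples, with a two-sided p-value from the exact
   t-distribution on n - 2 degrees of freedom;
3. retains the edge in snapshot S_a exactly when p < alpha (strict);
4. assembles the snapshots, ascending by age group, into a TemporalNetwork.

Age groups are processed independently — the natural parallel grain — via
joblib; results are assembled in temporal order rather than completion
order, so the output is identical for any worker count.

A full audit trail (one PairResult per pair per stratum, retained or not,
including undefined correlations with a reason code) is returned alongside
the network.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .errors import (
    AlignmentError,
    ConfigurationError,
    EmptyNetworkError,
    GeneLookupError,
)
from .expression import ALL_TISSUES, ExpressionDataset, ExpressionStratum, stratify
from .genes import GeneRecord
from .model import AgeGroup, Edge, Snapshot, TemporalNetwork, make_temporal_network

__all__ = [
    "DEFAULT_ALPHA",
    "Correlation",
    "PairResult",
    "build_snapshot",
    "build_temporal_network",
    "correlate",
    "generate_pairs",
]

#: Default significance threshold for edge retention.
DEFAULT_ALPHA = 0.05

#: Reason codes for undefined correlations.
REASON_UNDERSIZED = "undersized"  # fewer than 3 samples in the stratum
REASON_CONSTANT = "constant"  # at least one vector has zero variance


@dataclass(frozen=True)
class Correlation:
    """Result of one pairwise correlation test.

    ``r`` and ``p`` are ``None`` when the statistic is undefined; ``reason``
    then carries the code (``"undersized"`` or ``"constant"``).
    """

    r: float | None
    p: float | None
    n: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None


@dataclass(frozen=True)
class PairResult:
    """Audit record: one gene pair at one time point."""

    gene_i: str
    gene_j: str
    age_group: AgeGroup
    r: float | None
    p: float | None
    n: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.r is not None


def generate_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs, once each, in lexicographic order.

    Returns n(n-1)/2 pairs; fewer than two genes yields an empty list with
    a warning (a single gene cannot form a network).
    """
    gene_list = list(genes)
    if len(set(gene_list)) != len(gene_list):
        raise ConfigurationError("gene list for pair generation contains duplicates")
    if len(gene_list) < 2:
        warnings.warn(
            f"{len(gene_list)} gene(s) supplied; no pairs can be formed",
            stacklevel=2,
        )
        return []
    return list(itertools.combinations(sorted(gene_list), 2))


def correlate(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> Correlation:
    """Pearson correlation of two sample-aligned expression vectors.

    The p-value is two-sided, from the exact t-distribution with n - 2
    degrees of freedom under H0: rho = 0.  When n < 3 or either vector is
    constant the result is flagged undefined rather than raising.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise AlignmentError(
            f"expression vectors are not aligned: shapes {xv.shape} vs {yv.shape}"
        )
    n = xv.size
    if n < 3:
        return Correlation(None, None, n, REASON_UNDERSIZED)
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        return Correlation(None, None, n, REASON_CONSTANT)
    r, p = stats.pearsonr(xv, yv)
    # guard against float fuzz just outside [-1, 1]
    r = float(min(1.0, max(-1.0, r)))
    return Correlation(r, float(p), n)


def build_snapshot(
    stratum: ExpressionStratum,
    pairs: Sequence[tuple[str, str]],
    alpha: float,
    *,
    bh: bool = False,
    positive_only: bool = False,
) -> tuple[Snapshot, list[PairResult]]:
    """Construct the static network for one age group.

    An edge is retained exactly when its p-value is defined and strictly
    below ``alpha`` (a pair at p == alpha is excluded).  With ``bh`` the
    retention test uses Benjamini-Hochberg-adjusted p-values (adjusted
    within this snapshot only); the audit records keep the raw p.  The
    snapshot node set is the full stratum gene set, so genes with no
    significant partner remain as isolated nodes.
    """
    for pair in pairs:
        for endpoint in pair:
            if endpoint not in stratum.vectors:
                raise GeneLookupError(
                    f"pair endpoint {endpoint!r} missing from stratum "
                    f"{stratum.age_group.label}"
                )

    results: list[PairResult] = []
    for gene_i, gene_j in pairs:
        corr = correlate(stratum.vectors[gene_i], stratum.vectors[gene_j])
        results.append(
            PairResult(
                gene_i=gene_i,
                gene_j=gene_j,
                age_group=stratum.age_group,
                r=corr.r,
                p=corr.p,
                n=corr.n,
                reason=corr.reason,
            )
        )

    if bh:
        defined = [res for res in results if res.defined]
        if defined:
            adjusted = stats.false_discovery_control(
                [res.p for res in defined], method="bh"
            )
            test_p = {(res.gene_i, res.gene_j): adj for res, adj in zip(defined, adjusted)}
        else:
            test_p = {}
    else:
        test_p = {
            (res.gene_i, res.gene_j): res.p for res in results if res.defined
        }

    edges = []
    for res in results:
        if not res.defined:
            continue
        if positive_only and res.r <= 0:
            continue
        if test_p[(res.gene_i, res.gene_j)] < alpha:
            edges.append(Edge(res.gene_i, res.gene_j, p=res.p, r=res.r))

    nodes = tuple(stratum.vectors.keys())
    return Snapshot(stratum.age_group, nodes, edges), results


def _dataset_key(record: GeneRecord, ds: ExpressionDataset) -> str:
    """The dataset row identifier a resolved gene corresponds to.

    Expression matrices may key rows by versioned canonical ID, by the
    unversioned ID, or (in hand-made fixtures) by symbol; any of the three
    matches the record.
    """
    if record.canonical_id in ds.genes:
        return record.canonical_id
    unversioned = record.canonical_id.split(".", 1)[0]
    for gene in ds.genes:
        if gene.split(".", 1)[0] == unversioned:
            return gene
    if record.symbol in ds.genes:
        return record.symbol
    raise GeneLookupError(
        f"gene {record.symbol} ({record.canonical_id}) not found in the "
        "expression dataset under any identifier form"
    )


def build_temporal_network(
    genes: Sequence[GeneRecord] | Sequence[str],
    ds: ExpressionDataset,
    tissues: Sequence[str] | set[str] | None = ALL_TISSUES,
    alpha: float = DEFAULT_ALPHA,
    workers: int | None = None,
    *,
    bh: bool = False,
    positive_only: bool = False,
) -> tuple[TemporalNetwork, list[PairResult]]:
    """End-to-end construction of the temporal co-expression network.

    Parameters
    ----------
    genes:
        Resolved :class:`GeneRecord` objects or raw canonical IDs (>= 2).
    ds:
        Loaded expression dataset.
    tissues:
        Tissue labels to pool, or ``ALL_TISSUES``/``None`` for no filter.
    alpha:
        Significance threshold in (0, 1); edges require p < alpha.
    workers:
        Parallel worker count (one task per age group); ``None`` uses all
        available cores.  The result does not depend on this value.
    bh, positive_only:
        Optional Benjamini-Hochberg retention and positive-correlation-only
        modes; both default off.

    Returns the validated :class:`TemporalNetwork` and the full audit list
    of :class:`PairResult`, ordered by age group then pair.
    """
    ids = [
        _dataset_key(g, ds) if isinstance(g, GeneRecord) else str(g) for g in genes
    ]
    if len(ids) < 2:
        raise ConfigurationError(
            f"temporal-network construction requires >= 2 genes, got {len(ids)}"
        )
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate canonical IDs in gene list")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must lie in (0, 1), got {alpha}")

    strata = stratify(ds, ids, tissues)
    if not strata:
        raise EmptyNetworkError(
            "no age-group stratum survives the tissue filter: check the "
            "tissue labels against the annotation table"
        )
    pairs = generate_pairs(ids)

    n_jobs = -1 if workers is None else int(workers)
    outcomes = Parallel(n_jobs=n_jobs)(
        delayed(build_snapshot)(
            stratum, pairs, alpha, bh=bh, positive_only=positive_only
        )
        for stratum in strata
    )
    # strata arrive in temporal order and joblib preserves input order, so
    # assembly (and therefore output) is independent of worker scheduling
    snapshots = [snap for snap, _ in outcomes]
    audit = [res for _, results in outcomes for res in results]
    tn = make_temporal_network(tuple(ids), snapshots, alpha)
    return tn, audit
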
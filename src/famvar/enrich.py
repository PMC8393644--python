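"""Gene-set over-representation with rank-calibrated scoring.

Three scores are computed for every library term, in the style
popularized by list-enrichment web servers:

1. **Fisher exact p** — the one-sided upper-tail hypergeometric
   probability ``P(X >= k)`` of drawing at least the observed overlap
   ``k`` between a size-``n`` query list and a size-``K`` term from a
   background universe of ``N`` genes.
2. **Expected-rank z-score** — some terms systematically rank well under
   the Fisher test for *any* query (large terms in small universes, for
   instance).  Random query lists are drawn from the library universe,
   all terms are ranked by Fisher p in each draw, and a term's observed
   rank is standardized against its own null rank distribution:
   ``z = (mean_rank - observed_rank) / sd_rank``.  Positive z means the
   term ranks better (lower) than expected.
3. **Combined score** — ``-ln(p) * z``, so genuinely enriched terms
   score large and positive.

Benjamini–Hochberg adjustment of the Fisher p-values is reported
alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import hypergeom, rankdata
from statsmodels.stats.multitest import multipletests

from .io import GeneSetLibrary

logger = logging.getLogger(__name__)

#: Floor applied to null rank standard deviations so a term whose rank
#: never varies across permutations still yields a finite z (degenerate
#: libraries only; any real permutation spread dominates this floor).
_SD_FLOOR = 1e-9


class EnrichmentError(ValueError):
    """Invalid contingency table, calibration, or query."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts behind the one-sided Fisher test.

    k: overlap between query and term; n: query size; K: term size;
    N: background universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise EnrichmentError(
                f"overlap k={self.k} outside [0, min(n={self.n}, K={self.K})]"
            )
        if self.n > self.N or self.K > self.N:
            raise EnrichmentError(
                f"query size n={self.n} and term size K={self.K} must not exceed N={self.N}"
            )
        if min(self.n, self.K, self.N) < 0:
            raise EnrichmentError("negative contingency count")


def fisher_overrepresentation(table: ContingencyTable) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X ~ Hypergeom(N, K, n)``: the overlap obtained by drawing the
    query uniformly at random from the background.
    """
    return float(hypergeom.sf(table.k - 1, table.N, table.K, table.n))


def _fisher_sf_array(ks: np.ndarray, n: int, Ks: np.ndarray, N: int) -> np.ndarray:
    return hypergeom.sf(ks - 1, N, Ks, n)


def combined_score(p: float, z: float) -> float:
    """``-ln(p) * z``; zero whenever p = 1 or z = 0."""
    if not 0.0 < p <= 1.0:
        raise EnrichmentError(f"p-value {p} outside (0, 1]")
    return -np.log(p) * z


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# rank calibration


@dataclass(frozen=True)
class RankCalibration:
    """Per-term null rank statistics estimated from random query lists."""

    library_name: str
    list_size: int
    num_permutations: int
    seed: int
    mean_rank: Mapping[str, float]
    sd_rank: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_rank", dict(self.mean_rank))
        object.__setattr__(self, "sd_rank", dict(self.sd_rank))


def _membership_matrix(library: GeneSetLibrary) -> Tuple[List[str], List[str], np.ndarray]:
    """Term order, universe order, and a boolean term-by-gene matrix."""
    term_names = sorted(library.terms)
    universe = sorted(library.universe)
    index = {g: i for i, g in enumerate(universe)}
    matrix = np.zeros((len(term_names), len(universe)), dtype=bool)
    for t, term in enumerate(term_names):
        for gene in library.terms[term]:
            matrix[t, index[gene]] = True
    return term_names, universe, matrix


def _rank_terms(p: np.ndarray) -> np.ndarray:
    """Ascending ranks of Fisher p per row, average rank on ties."""
    return rankdata(p, method="average", axis=-1)


def calibrate_ranks(
    library: GeneSetLibrary,
    list_size: int,
    num_permutations: int = 1000,
    seed: int = 0,
) -> RankCalibration:
    """Estimate each term's null rank distribution under random queries.

    Draws ``num_permutations`` uniform gene lists of ``list_size`` from
    the library's gene universe (without replacement), scores every term
    by the Fisher test in each draw, ranks terms by ascending p (average
    rank on ties), and records per-term mean and standard deviation of
    rank.  Fully reproducible from ``seed``.
    """
    term_names, universe, matrix = _membership_matrix(library)
    if list_size > len(universe):
        raise EnrichmentError(
            f"list_size {list_size} exceeds the {len(universe)}-gene universe"
        )
    if num_permutations < 2:
        raise EnrichmentError("num_permutations must be >= 2")
    rng = np.random.default_rng(seed)
    term_sizes = matrix.sum(axis=1)
    # query indicator matrix: permutations x universe
    indicators = np.zeros((num_permutations, len(universe)), dtype=bool)
    for i in range(num_permutations):
        indicators[i, rng.choice(len(universe), size=list_size, replace=False)] = True
    ks = indicators.astype(np.float32) @ matrix.T.astype(np.float32)  # perms x terms
    ks = np.rint(ks).astype(np.int64)
    p = _fisher_sf_array(ks, list_size, term_sizes[None, :], library.background_size)
    ranks = _rank_terms(p)
    means = ranks.mean(axis=0)
    sds = np.maximum(ranks.std(axis=0, ddof=1), _SD_FLOOR)
    return RankCalibration(
        library_name=library.name,
        list_size=list_size,
        num_permutations=num_permutations,
        seed=seed,
        mean_rank=dict(zip(term_names, means.tolist())),
        sd_rank=dict(zip(term_names, sds.tolist())),
    )


def z_score(observed_rank: float, cal: RankCalibration, term: str) -> float:
    """Standardized deviation from the expected rank; positive = better than expected."""
    try:
        mean = cal.mean_rank[term]
        sd = cal.sd_rank[term]
    except KeyError:
        raise EnrichmentError(
            f"term {term!r} absent from calibration of {cal.library_name!r}"
        ) from None
    return (mean - observed_rank) / sd


# ---------------------------------------------------------------------------
# full enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """All audit fields for one scored term."""

    term: str
    k: int
    n: int
    K: int
    N: int
    p_fisher: float
    observed_rank: float
    z: float
    combined_score: float
    p_adjusted: float
    overlap_genes: Tuple[str, ...]


def enrich(
    query_genes: Iterable[str],
    library: GeneSetLibrary,
    cal: RankCalibration,
    top_n: Optional[int] = 10,
) -> List[EnrichmentResult]:
    """Score every library term against a query gene list.

    Results are sorted by combined score descending (ties alphabetical
    by term) and truncated to ``top_n`` (``None`` keeps all terms).
    Query genes are uppercased; genes outside the library universe still
    count toward the query size ``n``, mirroring the contingency table
    convention of list-enrichment servers.
    """
    query = frozenset(g.strip().upper() for g in query_genes if g and g.strip())
    if not query:
        raise EnrichmentError("empty query gene list")
    if cal.library_name != library.name:
        raise EnrichmentError(
            f"calibration is for library {cal.library_name!r}, not {library.name!r}"
        )
    n = len(query)
    if n != cal.list_size:
        logger.info(
            "query size %d differs from calibration list size %d; reusing the "
            "nearest configured calibration",
            n,
            cal.list_size,
        )
    term_names = sorted(library.terms)
    ks = np.array([len(query & library.terms[t]) for t in term_names])
    Ks = np.array([len(library.terms[t]) for t in term_names])
    N = library.background_size
    if n > N:
        raise EnrichmentError(f"query size {n} exceeds background universe {N}")
    p = _fisher_sf_array(ks, n, Ks, N)
    observed_ranks = _rank_terms(p)
    p_adj = adjust_bh(p)
    results = []
    for i, term in enumerate(term_names):
        z = z_score(observed_ranks[i], cal, term)
        results.append(
            EnrichmentResult(
                term=term,
                k=int(ks[i]),
                n=n,
                K=int(Ks[i]),
                N=N,
                p_fisher=float(p[i]),
                observed_rank=float(observed_ranks[i]),
                z=float(z),
                combined_score=float(combined_score(float(p[i]), float(z))),
                p_adjusted=float(p_adj[i]),
                overlap_genes=tuple(sorted(query & library.terms[term])),
            )
        )
    results.sort(key=lambda r: (-r.combined_score, r.term))
    if top_n is not None:
        results = results[:top_n]
    return results
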
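"""Exact over-representation statistics with multiple-testing correction.

The core statistic is the one-sided Fisher exact test for over-representation,
i.e. the upper tail of the hypergeometric distribution: drawing ``n`` genes
from a universe of ``N`` in which ``K`` carry an annotation, the probability
of observing at least ``k`` annotated genes is

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)

Binomial coefficients are evaluated in log space (log-gamma) so the tail is
stable for genome-scale universes (N ~ 20,000).  Fold enrichment is the
observed over expected overlap proportion, (k/n)/(K/N).

Corrections offered are Benjamini-Hochberg step-up (FDR) and Bonferroni
(FWER), matching the two procedures the pipeline stages use.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .io_formats import GeneSetLibrary, TFCatalog

logger = logging.getLogger("cordhox")

CorrectionMethod = Literal["bh", "bonferroni"]


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's over-representation result.

    k of n query genes fall in the term's K members within a universe of N;
    ``fold`` is (k/n)/(K/N); ``p_raw`` the hypergeometric upper tail;
    ``p_adj`` the corrected p under ``method``.
    """

    term: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p_raw: float
    p_adj: float
    method: str


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), in log space.

    Parameter bounds: 0 <= K <= N, 0 <= n <= N, 0 <= k <= min(n, K).
    ``k = 0`` returns exactly 1.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    hi = min(n, K)
    if not (0 <= k <= hi):
        raise ValueError(f"require 0 <= k <= min(n, K) = {hi}, got k={k}")
    if k == 0:
        return 1.0
    log_denom = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
        for i in range(k, hi + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def fold_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Observed/expected overlap proportion (k/n)/(K/N); 0 when k = 0."""
    if k == 0:
        return 0.0
    return (k / n) / (K / N)


def _check_probabilities(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr <= 0).any() or (arr > 1).any()):
        bad = arr[(arr <= 0) | (arr > 1)]
        raise ValueError(f"p-values must lie in (0, 1]; offending values: {bad[:5]}")
    return arr


def adjust_bh(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Sorted ascending, q_(i) = p_(i) * m / i, then a running minimum from the
    largest rank down enforces monotonicity; capped at 1.
    """
    arr = _check_probabilities(p)
    m = arr.size
    if m == 0:
        return []
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    # q >= p holds mathematically; guard the last-rank division against 1-ulp dips
    return np.maximum(out, arr).tolist()


def adjust_bonferroni(p: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: q_i = min(1, p_i * m), order preserved."""
    arr = _check_probabilities(p)
    return np.minimum(arr * arr.size, 1.0).tolist()


_ADJUSTERS = {"bh": adjust_bh, "bonferroni": adjust_bonferroni}


def overrepresentation(query: frozenset[str] | set[str], library: GeneSetLibrary,
                       universe: frozenset[str] | set[str],
                       method: CorrectionMethod = "bh") -> list[EnrichmentRow]:
    """Test every library term for over-representation in ``query``.

    Query genes outside the universe are dropped with a logged warning; term
    sets are intersected with the universe, and terms empty after that
    intersection are not tested.  Adjustment is applied across all emitted
    rows; rows are sorted by adjusted p, ties broken by raw p then term name.
    """
    if method not in _ADJUSTERS:
        raise ValueError(f"unknown correction method {method!r}")
    if not library.entries:
        raise ValueError("empty gene-set library")
    universe = frozenset(universe)
    query = frozenset(query)
    outside = query - universe
    if outside:
        logger.warning("dropping %d query gene(s) outside the universe: %s",
                       len(outside), sorted(outside)[:5])
    query &= universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")

    N, n = len(universe), len(query)
    terms: list[tuple[str, int, int]] = []
    for name, members in library.entries.items():
        eff = members & universe
        if eff:
            terms.append((name, len(eff), len(eff & query)))
    p_raw = [hypergeom_tail(N, K, n, k) for _, K, k in terms]
    p_adj = _ADJUSTERS[method](p_raw)
    rows = [
        EnrichmentRow(term=name, k=k, n=n, K=K, N=N,
                      fold=fold_enrichment(N, K, n, k),
                      p_raw=pr, p_adj=pa, method=method)
        for (name, K, k), pr, pa in zip(terms, p_raw, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return rows


def module_enrichment(partners: frozenset[str] | set[str],
                      module_tfs: frozenset[str] | set[str],
                      tf_universe: TFCatalog) -> EnrichmentRow:
    """Over-representation of a co-expression module's TFs among a protein's TF partners.

    The universe is the TF catalog (N = total_count), the annotated class is
    the module's TFs (K), the draw is the query protein's TF partners (n),
    and the overlap is k.  Partners outside the catalog are dropped with a
    warning; a single row is returned (no multiplicity, p_adj = p_raw).
    """
    partners = frozenset(partners)
    module = frozenset(module_tfs) & tf_universe.members
    outside = partners - tf_universe.members
    if outside:
        logger.warning("dropping %d partner(s) outside the TF catalog: %s",
                       len(outside), sorted(outside)[:5])
    partners &= tf_universe.members
    if not partners:
        raise ValueError("no partners remain within the TF catalog")
    N = tf_universe.total_count
    K, n = len(module), len(partners)
    k = len(partners & module)
    p = hypergeom_tail(N, K, n, k)
    return EnrichmentRow(term="module", k=k, n=n, K=K, N=N,
                         fold=fold_enrichment(N, K, n, k),
                         p_raw=p, p_adj=p, method="none")


def rows_to_tsv(rows: Sequence[EnrichmentRow], path) -> None:
    """Write enrichment rows as a TSV with the standard column set."""
    import pandas as pd

    df = pd.DataFrame([{
        "term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
        "fold": r.fold, "p_raw": r.p_raw, "p_adj": r.p_adj,
    } for r in rows])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
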
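"""First-shell interactor extraction and transcription-factor crossing.

Given a cleaned interaction network and a set of query proteins (the
spinal-cord-overexpressed homeobox TFs), collect every directly adjacent
partner (first shell), then restrict to partners that are themselves
transcription factors by crossing with a TF catalog.  A second-shell step
finds, for a TF set, its partners lying inside a gene module of interest.

Edges are undirected; a query appearing as another query's partner is kept.
Distinct-TF counting is by partner symbol, not by (query, partner) row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import Interactome, TFCatalog, normalize_symbols

logger = logging.getLogger("cordhox")


@dataclass(frozen=True)
class PartnerRow:
    query: str
    partner: str
    is_tf: bool


@dataclass(frozen=True)
class PartnerTable:
    """Rows (query, partner, is_tf) plus the distinct partner union."""

    rows: tuple[PartnerRow, ...]

    @property
    def partners(self) -> frozenset[str]:
        return frozenset(r.partner for r in self.rows)

    @property
    def queries(self) -> frozenset[str]:
        return frozenset(r.query for r in self.rows)

    def partners_of(self, query: str) -> frozenset[str]:
        return frozenset(r.partner for r in self.rows if r.query == query)

    def tf_partners_by_query(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for r in self.rows:
            if r.is_tf:
                out.setdefault(r.query, set()).add(r.partner)
        return {q: frozenset(s) for q, s in out.items()}


def first_shell(queries: frozenset[str] | set[str], net: Interactome) -> PartnerTable:
    """All proteins directly adjacent to each query in the network.

    Queries absent from the network get a logged warning and contribute no
    rows.  The ``is_tf`` flag is False here; :func:`cross_with_tfs` sets it.
    """
    queries = normalize_symbols(queries)
    adj = net.adjacency()
    rows: list[PartnerRow] = []
    for q in sorted(queries):
        if q not in adj:
            logger.warning("query %s has no edges in the interactome", q)
            continue
        for p in sorted(adj[q]):
            rows.append(PartnerRow(query=q, partner=p, is_tf=False))
    return PartnerTable(rows=tuple(rows))


def cross_with_tfs(partners: PartnerTable, catalog: TFCatalog) -> PartnerTable:
    """Retain rows whose partner is in the TF catalog; flag them as TFs."""
    if not catalog.members:
        raise ValueError("empty TF catalog")
    rows = tuple(
        PartnerRow(query=r.query, partner=r.partner, is_tf=True)
        for r in partners.rows if r.partner in catalog)
    table = PartnerTable(rows=rows)
    logger.info("TF crossing: %d of %d partner rows retained; %d distinct TFs",
                len(rows), len(partners.rows), len(table.partners))
    return table


def second_shell_tf_links(tfs: frozenset[str] | set[str], net: Interactome,
                          module: frozenset[str] | set[str]) -> list[tuple[str, str]]:
    """Edges from each input TF to its partners lying inside ``module``.

    Returns sorted (tf, module_partner) pairs; empty module gives an empty list.
    """
    tfs = normalize_symbols(tfs)
    module = frozenset(module)
    adj = net.adjacency()
    links = [
        (tf, p)
        for tf in sorted(tfs)
        for p in sorted(adj.get(tf, set()) & module)
    ]
    return links
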
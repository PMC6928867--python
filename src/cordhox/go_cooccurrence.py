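"""GO term co-occurrence over an annotation corpus and antagonism screening.

Two GO terms "co-occur" when at least one protein is annotated to both.
Co-occurrence strength is quantified as percent Jaccard similarity,

    S% = 100 * c_ab / (c_a + c_b - c_ab),

where c_a, c_b are the terms' annotation counts and c_ab the co-annotation
count, together with a probability ratio PR = (c_ab / c_b) / (c_a / N)
comparing the conditional frequency of the queried term among the other
term's proteins to its marginal frequency in the corpus (N proteins).  Terms
co-occurring with a query are ranked by similarity.  These definitions are a
reconstruction of web-service co-occurrence listings whose exact statistic
is unpublished; ranks on public corpora are therefore corpus-dependent.

The antagonism screen takes, for two pathways, one positive-regulation and
one negative-regulation GO term each, examines the four cross-pathway term
pairs, and reports whether every observed overlap joins terms of opposite
polarity ("antagonism-only") — the signature of two mutually repressive
pathways.

Annotations are ingested from GAF 2.x files (via Biopython); "NOT"-qualified
rows are dropped; protein identity is the DB object ID (column 2).  Term
names travel in a sidecar id->name table because GAF itself carries no
names.  Annotation propagation to is_a/part_of ancestors is available when
an OBO ontology is supplied, and is off by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

from Bio.UniProt import GOA

from .io_formats import FormatError


@dataclass(frozen=True)
class GOAnnotationCorpus:
    """term id -> (term name, annotated protein set) over a protein universe.

    ``total_proteins`` (N) is the size of the corpus protein universe — every
    protein annotated to at least one term.
    """

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, prots) in self.terms.items():
            if not prots:
                raise ValueError(f"term {tid} has an empty annotation set")

    @property
    def total_proteins(self) -> int:
        universe: set[str] = set()
        for _, prots in self.terms.values():
            universe |= prots
        return len(universe)

    def proteins(self, term_id: str) -> frozenset[str]:
        if term_id not in self.terms:
            raise KeyError(f"unknown GO term {term_id}")
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


# ---------------------------------------------------------------------------
# GAF ingestion
# ---------------------------------------------------------------------------

def read_gaf(path: str | Path,
             term_names: Mapping[str, str] | str | Path | None = None,
             evidence_codes: Iterable[str] | None = None,
             ontology=None, propagate: bool = False) -> GOAnnotationCorpus:
    """Build an annotation corpus from a GAF 2.x file.

    Rows qualified "NOT" are dropped.  ``evidence_codes``, when given,
    whitelists evidence codes (all kept by default).  ``term_names`` is a
    mapping or a two-column TSV path (term id, name); unnamed terms get an
    empty name.  With ``propagate=True`` and an ``ontology`` (a networkx
    graph as read by :func:`read_obo`), annotations propagate to is_a /
    part_of ancestors.
    """
    path = Path(path)
    names = _load_term_names(term_names)
    evidence = set(evidence_codes) if evidence_codes is not None else None

    annotations: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        try:
            records = list(GOA.gafiterator(fh))
        except Exception as exc:  # malformed column counts, bad version line
            raise FormatError(f"{path}: not a readable GAF file ({exc})") from exc
    for rec in records:
        if "NOT" in rec.get("Qualifier", []):
            continue
        if evidence is not None and rec.get("Evidence") not in evidence:
            continue
        annotations.setdefault(rec["GO_ID"], set()).add(rec["DB_Object_ID"])

    if propagate:
        if ontology is None:
            raise ValueError("propagate=True requires an ontology")
        annotations = _propagate(annotations, ontology)

    terms = {
        tid: (names.get(tid, ""), frozenset(prots))
        for tid, prots in annotations.items()
    }
    return GOAnnotationCorpus(terms=terms)


def _load_term_names(term_names) -> dict[str, str]:
    if term_names is None:
        return {}
    if isinstance(term_names, (str, Path)):
        out: dict[str, str] = {}
        for lineno, line in enumerate(Path(term_names).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{term_names}:{lineno}: expected 'id<TAB>name'")
            out[parts[0].strip()] = parts[1].strip()
        return out
    return dict(term_names)


def read_obo(path: str | Path):
    """Read an OBO ontology into a networkx graph (child -> parent edges)."""
    import obonet

    return obonet.read_obo(str(path))


def _propagate(annotations: dict[str, set[str]], ontology) -> dict[str, set[str]]:
    """Extend each annotation to all is_a/part_of ancestors of its term."""
    import networkx as nx

    keep = {"is_a", "part_of"}
    sub = ontology.edge_subgraph(
        [(u, v, k) for u, v, k in ontology.edges(keys=True) if k in keep]).copy()
    out: dict[str, set[str]] = {t: set(p) for t, p in annotations.items()}
    for term, prots in annotations.items():
        if term in sub:
            for anc in nx.descendants(sub, term):  # edges point child -> parent
                out.setdefault(anc, set()).update(prots)
    return out


def write_gaf(annotations: Mapping[str, Iterable[tuple[str, str]]] | Iterable[tuple[str, str, str]],
              path: str | Path, taxon: str = "taxon:9606") -> Path:
    """Write (protein_id, symbol, term_id) annotations as minimal GAF 2.1."""
    if isinstance(annotations, Mapping):
        rows = [(pid, sym, tid) for tid, pairs in annotations.items() for pid, sym in pairs]
    else:
        rows = list(annotations)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("!gaf-version: 2.1\n")
        for pid, symbol, term in sorted(rows):
            fields = ["UniProtKB", pid, symbol, "", term, "GO_REF:0000000", "IEA",
                      "", "P", "", "", "protein", taxon, "20190101", "cordhox", "", ""]
            fh.write("\t".join(fields) + "\n")
    return path


def write_term_names(names: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for tid in sorted(names):
            fh.write(f"{tid}\t{names[tid]}\n")
    return path


# ---------------------------------------------------------------------------
# Co-occurrence statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CooccurrenceRow:
    """Co-occurrence of ``term_b`` with the queried ``term_a``."""

    term_a: str
    term_b: str
    c_a: int
    c_b: int
    c_ab: int
    similarity: float  # percent Jaccard, (0, 100]
    prob_ratio: float
    rank: int


def percent_jaccard(c_a: int, c_b: int, c_ab: int) -> float:
    return 100.0 * c_ab / (c_a + c_b - c_ab)


def cooccurring_terms(corpus: GOAnnotationCorpus, query: str) -> list[CooccurrenceRow]:
    """All terms sharing >= 1 protein with ``query``, ranked by similarity.

    Sorted by percent Jaccard descending, ties by probability ratio
    descending then term id ascending; ranks run 1..n with no gaps.
    """
    q_prots = corpus.proteins(query)
    c_a = len(q_prots)
    N = corpus.total_proteins
    unranked = []
    for tid, (_, prots) in corpus.terms.items():
        if tid == query:
            continue
        c_ab = len(q_prots & prots)
        if c_ab == 0:
            continue
        c_b = len(prots)
        unranked.append((
            percent_jaccard(c_a, c_b, c_ab),
            (c_ab / c_b) / (c_a / N),
            tid, c_b, c_ab,
        ))
    unranked.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [
        CooccurrenceRow(term_a=query, term_b=tid, c_a=c_a, c_b=c_b, c_ab=c_ab,
                        similarity=sim, prob_ratio=pr, rank=i)
        for i, (sim, pr, tid, c_b, c_ab) in enumerate(unranked, start=1)
    ]


# ---------------------------------------------------------------------------
# Polarity and antagonism
# ---------------------------------------------------------------------------

Polarity = Literal["positive", "negative", "none"]

_POLARITY_RE = re.compile(r"^(positive|negative) regulation of (.+)$", re.IGNORECASE)


@dataclass(frozen=True)
class PolarityTag:
    direction: Polarity
    concept: str


def parse_polarity(term_name: str) -> PolarityTag:
    """Split a GO term name into its regulation polarity and residual concept.

    Matches a leading "positive regulation of " / "negative regulation of "
    case-insensitively; anything else gets direction "none".
    """
    m = _POLARITY_RE.match(term_name.strip())
    if not m:
        return PolarityTag(direction="none", concept=term_name.strip())
    return PolarityTag(direction=m.group(1).lower(), concept=m.group(2).strip())


@dataclass(frozen=True)
class PairReport:
    """One cross-pathway term pair in the antagonism screen."""

    term_a: str
    term_b: str
    polarity_a: Polarity
    polarity_b: Polarity
    observed: bool
    classification: Literal["antagonistic", "agonistic", "no overlap"]
    similarity: float | None
    rank_in_a: int | None     # rank of term_b in term_a's co-occurrence list
    total_in_a: int | None    # length of that list
    rank_in_b: int | None
    total_in_b: int | None


@dataclass(frozen=True)
class AntagonismReport:
    pairs: tuple[PairReport, ...]
    verdict: Literal["antagonism-only", "agonism-only", "mixed", "no-overlap"]


def antagonism_screen(corpus: GOAnnotationCorpus,
                      pathway_a_terms: tuple[str, str],
                      pathway_b_terms: tuple[str, str]) -> AntagonismReport:
    """Screen the four cross-pathway pairs of two (positive, negative) term pairs.

    ``pathway_a_terms`` and ``pathway_b_terms`` each give (positive-regulation
    term id, negative-regulation term id) for one pathway.  Terms absent from
    the corpus are reported as "no overlap" for their pairs, but a pathway
    whose two terms are both absent is an error.  The verdict is
    "antagonism-only" when every observed overlap joins opposite polarities.
    """
    for side, (pos, neg) in (("a", pathway_a_terms), ("b", pathway_b_terms)):
        if pos not in corpus and neg not in corpus:
            raise ValueError(f"both terms of pathway {side} are absent from the corpus")

    ranks_cache: dict[str, dict[str, tuple[int, int]]] = {}

    def ranks_of(query: str) -> dict[str, tuple[int, int]]:
        if query not in ranks_cache:
            rows = cooccurring_terms(corpus, query)
            ranks_cache[query] = {r.term_b: (r.rank, len(rows)) for r in rows}
        return ranks_cache[query]

    polarities_a = {pathway_a_terms[0]: "positive", pathway_a_terms[1]: "negative"}
    polarities_b = {pathway_b_terms[0]: "positive", pathway_b_terms[1]: "negative"}

    pairs: list[PairReport] = []
    for ta, pol_a in polarities_a.items():
        for tb, pol_b in polarities_b.items():
            if ta not in corpus or tb not in corpus:
                pairs.append(PairReport(ta, tb, pol_a, pol_b, False, "no overlap",
                                        None, None, None, None, None))
                continue
            shared = corpus.proteins(ta) & corpus.proteins(tb)
            if not shared:
                pairs.append(PairReport(ta, tb, pol_a, pol_b, False, "no overlap",
                                        None, None, None, None, None))
                continue
            sim = percent_jaccard(len(corpus.proteins(ta)), len(corpus.proteins(tb)),
                                  len(shared))
            rank_a, total_a = ranks_of(ta)[tb]
            rank_b, total_b = ranks_of(tb)[ta]
            cls = "antagonistic" if pol_a != pol_b else "agonistic"
            pairs.append(PairReport(ta, tb, pol_a, pol_b, True, cls, sim,
                                    rank_a, total_a, rank_b, total_b))

    observed = [p for p in pairs if p.observed]
    if not observed:
        verdict = "no-overlap"
    elif all(p.classification == "antagonistic" for p in observed):
        verdict = "antagonism-only"
    elif all(p.classification == "agonistic" for p in observed):
        verdict = "agonism-only"
    else:
        verdict = "mixed"
    return AntagonismReport(pairs=tuple(pairs), verdict=verdict)
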
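"""GO co-occurrence statistics, polarity parsing and the antagonism screen."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cordhox as cx
from cordhox.go_cooccurrence import GOAnnotationCorpus, write_gaf, write_term_names


def corpus_of(**terms) -> GOAnnotationCorpus:
    return GOAnnotationCorpus(terms={
        tid: (name_prots[0], frozenset(name_prots[1]))
        for tid, name_prots in terms.items()})


class TestCooccurringTerms:
    def test_identical_annotation_sets_rank_first_at_100(self):
        c = corpus_of(A=("a", {"p1", "p2"}), B=("b", {"p1", "p2"}),
                      C=("c", {"p1", "p9"}))
        rows = cx.cooccurring_terms(c, "A")
        assert rows[0].term_b == "B" and rows[0].similarity == 100.0
        assert rows[0].rank == 1

    def test_percent_jaccard_arithmetic(self):
        # c_a=5, c_b=4, c_ab=3 -> 100*3/6
        assert cx.percent_jaccard(5, 4, 3) == pytest.approx(50.0)

    def test_probability_ratio_definition(self):
        prots_a = {f"p{i}" for i in range(5)}
        prots_b = {"p0", "p1", "p2", "x1"}
        background = {f"q{i}" for i in range(94)}  # pad universe to N=100
        c = corpus_of(A=("a", prots_a), B=("b", prots_b), BG=("bg", background))
        (row,) = [r for r in cx.cooccurring_terms(c, "A") if r.term_b == "B"]
        assert row.c_ab == 3 and row.c_b == 4
        assert row.prob_ratio == pytest.approx((3 / 4) / (5 / 100))

    def test_unknown_query_rejected(self):
        c = corpus_of(A=("a", {"p1"}))
        with pytest.raises(KeyError):
            cx.cooccurring_terms(c, "NOPE")

    def test_query_itself_excluded_and_zero_overlap_omitted(self):
        c = corpus_of(A=("a", {"p1"}), B=("b", {"p2"}))
        assert cx.cooccurring_terms(c, "A") == []

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 300))
    def test_similarity_symmetric_and_ranks_gapless(self, seed):
        corpus = cx.gen_go_corpus(cx.SimulationConfig(
            seed=seed, go=cx.GOConfig(n_background_terms=30, n_proteins=300)))
        terms = list(corpus.terms)[:6]
        sims = {}
        for q in terms:
            rows = cx.cooccurring_terms(corpus, q)
            assert [r.rank for r in rows] == list(range(1, len(rows) + 1))
            for r in rows:
                sims[(r.term_a, r.term_b)] = r.similarity
        for (a, b), s in sims.items():
            if (b, a) in sims:
                assert sims[(b, a)] == pytest.approx(s)

    def test_removing_top_term_shifts_ranks_down_by_one(self):
        corpus = cx.gen_go_corpus(cx.SimulationConfig(seed=3))
        query = "GO:0060391"
        rows = cx.cooccurring_terms(corpus, query)
        top = rows[0].term_b
        trimmed = GOAnnotationCorpus(terms={
            t: v for t, v in corpus.terms.items() if t != top})
        rows2 = cx.cooccurring_terms(trimmed, query)
        assert [(r.term_b, r.rank - 1) for r in rows[1:]] == \
            [(r.term_b, r.rank) for r in rows2]


class TestParsePolarity:
    @pytest.mark.parametrize("name,direction,concept", [
        ("Positive regulation of SMAD protein signal transduction",
         "positive", "SMAD protein signal transduction"),
        ("Negative regulation of androgen receptor signaling pathway",
         "negative", "androgen receptor signaling pathway"),
        ("NEGATIVE REGULATION OF X", "negative", "X"),
        ("signal transduction", "none", "signal transduction"),
    ])
    def test_polarity_parsing(self, name, direction, concept):
        tag = cx.parse_polarity(name)
        assert tag.direction == direction and tag.concept == concept


class TestAntagonismScreen:
    def test_planted_antagonistic_overlap_recovered(self):
        corpus = cx.gen_go_corpus(cx.SimulationConfig(seed=11))
        report = cx.antagonism_screen(corpus, ("GO:0060391", "GO:0060392"),
                                      ("GO:2000825", "GO:0060766"))
        assert report.verdict == "antagonism-only"
        observed = [p for p in report.pairs if p.observed]
        assert [(p.term_a, p.term_b) for p in observed] == [("GO:0060391", "GO:0060766")]
        assert observed[0].rank_in_a is not None and observed[0].rank_in_a >= 1

    def test_planted_similarity_follows_generator_parameters(self):
        cfg = cx.SimulationConfig(seed=5)
        corpus = cx.gen_go_corpus(cfg)
        report = cx.antagonism_screen(corpus, ("GO:0060391", "GO:0060392"),
                                      ("GO:2000825", "GO:0060766"))
        (pair,) = [p for p in report.pairs if p.observed]
        size, ov = cfg.go.term_size, cfg.go.planted_overlaps[0]
        assert pair.similarity == pytest.approx(100 * ov / (2 * size - ov))

    def test_no_shared_proteins_vacuous_verdict(self):
        c = corpus_of(PA=("Positive regulation of s", {"p1"}),
                      NA=("Negative regulation of s", {"p2"}),
                      PB=("Positive regulation of t", {"p3"}),
                      NB=("Negative regulation of t", {"p4"}))
        report = cx.antagonism_screen(c, ("PA", "NA"), ("PB", "NB"))
        assert report.verdict == "no-overlap"
        assert all(p.classification == "no overlap" for p in report.pairs)

    def test_same_polarity_overlap_breaks_verdict(self):
        c = corpus_of(PA=("pos a", {"p1", "s"}), NA=("neg a", {"p2"}),
                      PB=("pos b", {"p3", "s"}), NB=("neg b", {"p4"}))
        report = cx.antagonism_screen(c, ("PA", "NA"), ("PB", "NB"))
        assert report.verdict == "agonism-only"

    def test_pathway_with_both_terms_absent_rejected(self):
        c = corpus_of(PA=("pos a", {"p1"}), NA=("neg a", {"p2"}))
        with pytest.raises(ValueError, match="pathway b"):
            cx.antagonism_screen(c, ("PA", "NA"), ("XX", "YY"))

    def test_single_missing_term_reported_not_fatal(self):
        c = corpus_of(PA=("pos a", {"p1", "s"}), NA=("neg a", {"p2"}),
                      NB=("neg b", {"p4", "s"}))
        report = cx.antagonism_screen(c, ("PA", "NA"), ("MISSING", "NB"))
        assert report.verdict == "antagonism-only"
        missing = [p for p in report.pairs if p.term_b == "MISSING"]
        assert all(p.classification == "no overlap" for p in missing)


class TestGAFIngestion:
    def test_round_trip_through_gaf(self, tmp_path):
        corpus = cx.gen_go_corpus(cx.SimulationConfig(
            seed=2, go=cx.GOConfig(n_background_terms=10, n_proteins=200)))
        rows = [(pid, pid, tid) for tid, (_, prots) in corpus.terms.items()
                for pid in sorted(prots)]
        gaf = write_gaf(rows, tmp_path / "c.gaf")
        names = write_term_names(
            {t: n for t, (n, _) in corpus.terms.items() if n}, tmp_path / "n.tsv")
        back = cx.read_gaf(gaf, term_names=names)
        assert {t: p for t, (_, p) in back.terms.items()} == \
            {t: p for t, (_, p) in corpus.terms.items()}
        assert back.name("GO:0060391") == corpus.name("GO:0060391")

    def test_not_qualifier_rows_dropped(self, tmp_path):
        gaf = tmp_path / "c.gaf"
        gaf.write_text(
            "!gaf-version: 2.1\n"
            "UniProtKB\tP1\tP1\tNOT\tGO:1\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20190101\tx\t\t\n"
            "UniProtKB\tP2\tP2\t\tGO:1\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20190101\tx\t\t\n")
        corpus = cx.read_gaf(gaf)
        assert corpus.proteins("GO:1") == {"P2"}

    def test_evidence_filter(self, tmp_path):
        gaf = tmp_path / "c.gaf"
        gaf.write_text(
            "!gaf-version: 2.1\n"
            "UniProtKB\tP1\tP1\t\tGO:1\tREF\tEXP\t\tP\t\t\tprotein\ttaxon:9606\t20190101\tx\t\t\n"
            "UniProtKB\tP2\tP2\t\tGO:1\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20190101\tx\t\t\n")
        corpus = cx.read_gaf(gaf, evidence_codes={"EXP"})
        assert corpus.proteins("GO:1") == {"P1"}

    def test_ontology_propagation_extends_to_ancestors(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:1\nname: child\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: parent\n\n")
        gaf = tmp_path / "c.gaf"
        gaf.write_text(
            "!gaf-version: 2.1\n"
            "UniProtKB\tP1\tP1\t\tGO:1\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20190101\tx\t\t\n")
        flat = cx.read_gaf(gaf)
        assert "GO:2" not in flat
        deep = cx.read_gaf(gaf, ontology=cx.read_obo(obo), propagate=True)
        assert deep.proteins("GO:2") == {"P1"}
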
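"""Seeded generators for every input class, with planted structure.

Each generator is a pure function of (config, seed): identical configs give
byte-identical outputs.  Defaults mirror the published study conditions —
10 homeobox genes planted at their GTEx median TPM values in a 29-gene
median matrix; 10-vs-10 two-group sample matrices with the published
spinal-cord/brain-cortex fold ratios; an interactome carrying the curated
HOX-TF pairs among 71 non-TF partners and a 1211-member TF catalog; and a
GO annotation corpus with a planted antagonistic overlap of 5 proteins
between a positive-regulation term of one pathway and a negative-regulation
term of the other.

Donor-to-donor expression noise defaults to 0.25 on the natural-log scale
(about a 25% coefficient of variation), the magnitude consistent with
Bonferroni-adjusted p-values of order 1e-5 at 10 samples per group for fold
ratios in the hundreds, as observed in the two-group comparison the sample
generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datasets
from .go_cooccurrence import GOAnnotationCorpus, write_gaf, write_term_names
from .io_formats import (
    ExpressionColumn, ExpressionMatrix, GeneSetLibrary, Interactome, TFCatalog,
    make_edge, write_expression_tsv, write_gmt, write_interactome, write_tf_catalog,
)


@dataclass(frozen=True)
class PPIConfig:
    """Interactome generator settings.

    ``planted_tf_partners`` are (query, TF partner) edges; ``n_nontf_partners``
    decoy partners are spread round-robin over the queries so the first shell
    matches the published 85-interactor scale (14 TFs + 71 non-TFs).  The TF
    catalog is padded with decoy TFs (never adjacent to a query) up to
    ``catalog_size``; the gliosis-style module contains the named module TFs
    plus catalog decoys up to ``module_size``.
    """

    planted_tf_partners: tuple[tuple[str, str], ...] = datasets.HOX_TF_PARTNERS
    n_nontf_partners: int = 71
    catalog_size: int = datasets.TF_CATALOG_SIZE
    module_size: int = datasets.GLIOSIS_MODULE_TF_COUNT
    n_background_proteins: int = 100
    n_background_edges: int = 150
    second_shell: tuple[tuple[str, str], ...] = (
        ("SOX2", "AR"), ("SMAD1", "GLIS3"), ("SMAD1", "NFIB"))


@dataclass(frozen=True)
class GOConfig:
    """GO corpus generator settings.

    Four polarity-named terms cover two concepts (two pathways); the two
    cross-pathway opposite-polarity pairs share ``planted_overlaps`` proteins
    (default mirrors the published screen: one antagonistic pair with 5
    shared proteins, no other overlap among the four); same-polarity pairs
    share none by construction.
    """

    n_background_terms: int = 200
    n_proteins: int = 2000
    term_size: int = 30
    background_size_range: tuple[int, int] = (5, 40)
    planted_overlaps: tuple[int, int] = (5, 0)  # (posA & negB, negA & posB)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for all generators."""

    seed: int = 0
    n_genes: int = 29                 # planted + distractor rows in the median matrix
    n_regions: int = 4
    n_samples_per_group: int = 10
    #: (symbol, target-region TPM, group fold ratio); defaults are the
    #: published medians and spinal-cord/cortex ratios of the 10 HOX genes.
    planted_genes: tuple[tuple[str, float, float], ...] = tuple(
        (g, datasets.SPINAL_CORD_MEDIAN_TPM[g][0], datasets.SPINAL_VS_CORTEX_RATIOS[g][0])
        for g in datasets.SPINAL_CORD_MEDIAN_TPM)
    noise_sd_log: float = 0.25
    min_target: float = 5.0
    max_other: float = 1.0
    embed_reference_medians: bool = True
    ppi: PPIConfig = field(default_factory=PPIConfig)
    go: GOConfig = field(default_factory=GOConfig)

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_regions < 2 or self.n_samples_per_group <= 0:
            raise ValueError("counts must be positive (and n_regions >= 2)")
        for sym, tpm, fold in self.planted_genes:
            if fold <= 0 or tpm < 0:
                raise ValueError(f"invalid planted gene ({sym}, {tpm}, {fold})")
        symbols = [s for s, _, _ in self.planted_genes]
        if len(symbols) != len(set(symbols)):
            raise ValueError("planted gene symbols collide")


def _rng_named(cfg: SimulationConfig, stream_id: int) -> np.random.Generator:
    # independent, reproducible stream per generator
    return np.random.default_rng([cfg.seed, stream_id])


# ---------------------------------------------------------------------------
# Median matrix (region filter input)
# ---------------------------------------------------------------------------

def gen_median_matrix(cfg: SimulationConfig) -> ExpressionMatrix:
    """Median-TPM matrix: planted region-specific genes among sub-threshold distractors.

    Planted genes sit at their target TPM in the first region and below
    ``max_other`` elsewhere (published medians are used verbatim when
    ``embed_reference_medians`` and the symbol is one of the 10 published
    genes).  Distractors draw a target-region TPM uniformly below
    ``min_target`` and stay below ``max_other`` in other regions, so the
    region filter at default thresholds recovers exactly the planted set.
    """
    rng = _rng_named(cfg, 1)
    if cfg.n_genes < len(cfg.planted_genes):
        raise ValueError("n_genes smaller than the planted gene count")
    labels = ["Spinal Cord"] + [f"Region_{i}" for i in range(2, cfg.n_regions + 1)]
    if cfg.n_regions == 4:
        labels = [c.label for c in datasets.REGION_COLUMNS]

    rows: dict[str, list[float]] = {}
    for sym, tpm, _ in cfg.planted_genes:
        if cfg.embed_reference_medians and sym in datasets.SPINAL_CORD_MEDIAN_TPM \
                and cfg.n_regions == 4:
            rows[sym] = list(datasets.SPINAL_CORD_MEDIAN_TPM[sym])
        else:
            others = rng.uniform(0, 0.9 * cfg.max_other, cfg.n_regions - 1)
            rows[sym] = [tpm, *np.round(others, 2)]
    n_distractors = cfg.n_genes - len(cfg.planted_genes)
    for i in range(1, n_distractors + 1):
        sym = f"HXD{i:02d}"
        if sym in rows:
            raise ValueError(f"planted symbol collision: {sym}")
        target = rng.uniform(0, 0.98 * cfg.min_target)
        others = rng.uniform(0, 0.9 * cfg.max_other, cfg.n_regions - 1)
        rows[sym] = [round(target, 2), *np.round(others, 2)]

    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    columns = list(datasets.REGION_COLUMNS) if cfg.n_regions == 4 else [
        ExpressionColumn(l) for l in labels]
    return ExpressionMatrix(values=df, unit="TPM", columns=columns)


# ---------------------------------------------------------------------------
# Two-group sample matrix (differential expression input)
# ---------------------------------------------------------------------------

def gen_sample_matrix(cfg: SimulationConfig) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Per-sample two-group matrix with planted group-mean fold ratios.

    Group means: planted genes take a baseline in group 2 and baseline*fold
    in group 1; background (null) genes share one mean across groups.
    Samples are lognormal around the group mean with ``noise_sd_log`` on the
    natural-log scale, mean-corrected so the expectation equals the group
    mean exactly (the noiseless limit reproduces the fold ratio exactly).

    Returns the matrix and a column -> group-name mapping.
    """
    if cfg.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = _rng_named(cfg, 2)
    n = cfg.n_samples_per_group
    cols1 = [f"SC_{i+1:02d}" for i in range(n)]
    cols2 = [f"BC_{i+1:02d}" for i in range(n)]
    groups = {**{c: "group1" for c in cols1}, **{c: "group2" for c in cols2}}

    genes: list[str] = []
    means1: list[float] = []
    means2: list[float] = []
    for sym, _, fold in cfg.planted_genes:
        base = 10.0
        genes.append(sym)
        means1.append(base * fold)
        means2.append(base)
    n_null = cfg.n_genes - len(cfg.planted_genes)
    null_means = np.exp(rng.uniform(np.log(5), np.log(100), n_null))
    for i in range(n_null):
        genes.append(f"NUL{i+1:02d}")
        means1.append(float(null_means[i]))
        means2.append(float(null_means[i]))

    s = cfg.noise_sd_log
    shape = (len(genes), n)
    correction = np.exp(-0.5 * s * s)
    noise1 = np.exp(rng.normal(0.0, s, shape)) * correction if s > 0 else np.ones(shape)
    noise2 = np.exp(rng.normal(0.0, s, shape)) * correction if s > 0 else np.ones(shape)
    x1 = np.asarray(means1)[:, None] * noise1
    x2 = np.asarray(means2)[:, None] * noise2

    df = pd.DataFrame(np.hstack([x1, x2]), index=genes, columns=cols1 + cols2)
    columns = [ExpressionColumn(c, group=groups[c]) for c in df.columns]
    return ExpressionMatrix(values=df, unit="AU", columns=columns), groups


# ---------------------------------------------------------------------------
# Interactome + TF catalog + module
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractomeBundle:
    net: Interactome
    catalog: TFCatalog
    module_tfs: frozenset[str]
    queries: frozenset[str]


def gen_interactome(cfg: SimulationConfig) -> InteractomeBundle:
    """Interactome with planted query->TF edges, decoy partners and background.

    The planted (query, TF) pairs and ``n_nontf_partners`` non-TF partners
    form the queries' complete first shell; background edges connect only
    background proteins, so first-shell results are exactly the planted
    structure.  The catalog holds the planted TFs, the named module TFs and
    decoy TFs up to ``catalog_size``; the module holds the named module TFs
    plus catalog decoys up to ``module_size``.
    """
    p = cfg.ppi
    rng = _rng_named(cfg, 3)
    all_queries = sorted({q for q, _ in p.planted_tf_partners}
                         | (set(datasets.hox_query_genes())
                            if cfg.embed_reference_medians else set()))
    planted_tfs = sorted({t for _, t in p.planted_tf_partners})

    edges = [make_edge(q, t, system="two-hybrid") for q, t in p.planted_tf_partners]
    # non-TF decoy partners, spread over all queries so none is isolated
    for i in range(p.n_nontf_partners):
        q = all_queries[i % len(all_queries)]
        edges.append(make_edge(q, f"NTF{i+1:03d}", system="affinity"))
    for a, b in p.second_shell:
        edges.append(make_edge(a, b, system="two-hybrid"))

    # background edges among background proteins only
    bg = [f"BGP{i+1:03d}" for i in range(p.n_background_proteins)]
    capacity = len(bg) * (len(bg) - 1) // 2
    if p.n_background_edges > capacity:
        raise ValueError(
            f"{p.n_background_edges} background edges exceed simple-graph capacity {capacity}")
    seen: set[tuple[str, str]] = set()
    while len(seen) < p.n_background_edges:
        i, j = rng.integers(0, len(bg), 2)
        if i == j:
            continue
        a, b = sorted((bg[i], bg[j]))
        seen.add((a, b))
    edges.extend(make_edge(a, b, system="affinity") for a, b in sorted(seen))

    named_module = sorted(datasets.GLIOSIS_MODULE_NAMED_TFS)
    n_decoy_tfs = p.catalog_size - len(set(planted_tfs) | set(named_module))
    if n_decoy_tfs < 0:
        raise ValueError("catalog_size smaller than the planted TF set")
    decoy_tfs = [f"TFD{i+1:04d}" for i in range(n_decoy_tfs)]
    catalog = TFCatalog(members=frozenset(planted_tfs) | frozenset(named_module)
                        | frozenset(decoy_tfs))
    n_module_decoys = p.module_size - len(named_module)
    if n_module_decoys < 0:
        raise ValueError("module_size smaller than the named module TF set")
    module = frozenset(named_module) | frozenset(decoy_tfs[:n_module_decoys])

    return InteractomeBundle(
        net=Interactome(edges=frozenset(edges)),
        catalog=catalog,
        module_tfs=module,
        queries=frozenset(all_queries),
    )


# ---------------------------------------------------------------------------
# GO annotation corpus
# ---------------------------------------------------------------------------

def gen_go_corpus(cfg: SimulationConfig) -> GOAnnotationCorpus:
    """GO corpus with a planted antagonistic cross-pathway overlap.

    Four polarity-named terms over two pathway concepts; the opposite-
    polarity cross-pathway pairs share exactly ``planted_overlaps`` proteins,
    all other intersections among the four are empty.  Background terms draw
    proteins from the whole universe (and so may co-occur with anything).
    """
    g = cfg.go
    ov1, ov2 = g.planted_overlaps
    if ov1 > g.term_size or ov2 > g.term_size:
        raise ValueError("planted overlap exceeds term size")
    rng = _rng_named(cfg, 4)
    universe = [f"P{i+1:06d}" for i in range(g.n_proteins)]
    needed = 4 * g.term_size  # disjoint allocation upper bound
    if needed > g.n_proteins:
        raise ValueError("protein universe too small for the four polarity terms")
    reserved = list(rng.choice(universe, size=needed, replace=False))

    def take(k: int) -> list[str]:
        out, reserved[:] = reserved[:k], reserved[k:]
        return out

    shared_1 = take(ov1)  # posA & negB
    shared_2 = take(ov2)  # negA & posB
    pos_a = frozenset(shared_1 + take(g.term_size - ov1))
    neg_b = frozenset(shared_1 + take(g.term_size - ov1))
    neg_a = frozenset(shared_2 + take(g.term_size - ov2))
    pos_b = frozenset(shared_2 + take(g.term_size - ov2))

    pos_a_id, neg_a_id = datasets.SMAD_PATHWAY_TERMS
    pos_b_id, neg_b_id = datasets.AR_PATHWAY_TERMS
    terms: dict[str, tuple[str, frozenset[str]]] = {
        pos_a_id: (datasets.GO_TERM_NAMES[pos_a_id], pos_a),
        neg_a_id: (datasets.GO_TERM_NAMES[neg_a_id], neg_a),
        pos_b_id: (datasets.GO_TERM_NAMES[pos_b_id], pos_b),
        neg_b_id: (datasets.GO_TERM_NAMES[neg_b_id], neg_b),
    }
    lo, hi = g.background_size_range
    for i in range(g.n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        prots = frozenset(rng.choice(universe, size=size, replace=False))
        terms[f"GO:{9000000 + i}"] = (f"background process {i}", prots)
    return GOAnnotationCorpus(terms=terms)


# ---------------------------------------------------------------------------
# Signature + annotation libraries (signature-crossing inputs)
# ---------------------------------------------------------------------------

def gen_signature_library(cfg: SimulationConfig, n_specific: int = 50,
                          n_shared: int = 30) -> GeneSetLibrary:
    """Two tissue signatures with the planted genes specific to the first.

    "SC" holds the planted genes plus synthetic SC-specific genes; "Brain"
    holds synthetic brain-specific genes; both share a common block.  The
    companion annotation term "HOMEOBOX" (see :func:`gen_annotation_library`)
    marks the planted genes plus homeobox decoys outside the SC signature.
    """
    planted = [s for s, _, _ in cfg.planted_genes]
    sc_only = [f"SCG{i+1:03d}" for i in range(n_specific)]
    br_only = [f"BRG{i+1:03d}" for i in range(n_specific)]
    shared = [f"SHG{i+1:03d}" for i in range(n_shared)]
    return GeneSetLibrary(entries={
        "SC": frozenset(planted + sc_only + shared),
        "Brain": frozenset(br_only + shared),
    }, source_tag="synthetic signatures")


def gen_annotation_library(cfg: SimulationConfig, n_decoy_terms: int = 20,
                           n_homeobox_decoys: int = 19) -> GeneSetLibrary:
    """Term -> gene annotation library with a homeobox family term.

    "HOMEOBOX" holds the planted genes plus decoy homeobox genes absent from
    the SC signature; decoy terms hold synthetic shared/brain genes so
    over-representation of an SC-specific query singles out "HOMEOBOX".
    """
    rng = _rng_named(cfg, 5)
    planted = [s for s, _, _ in cfg.planted_genes]
    homeobox = planted + [f"HXD{i+1:02d}" for i in range(n_homeobox_decoys)]
    entries = {"HOMEOBOX": frozenset(homeobox)}
    pool = [f"BRG{i+1:03d}" for i in range(50)] + [f"SHG{i+1:03d}" for i in range(30)]
    for t in range(n_decoy_terms):
        size = int(rng.integers(5, 25))
        entries[f"FAM{t+1:03d}"] = frozenset(rng.choice(pool, size=size, replace=False))
    return GeneSetLibrary(entries=entries, source_tag="synthetic annotation library")


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SimulationConfig, outdir: str | Path,
                    kinds: tuple[str, ...] = ("medians", "samples", "ppi", "gaf",
                                              "signatures")) -> dict[str, Path]:
    """Generate the requested input kinds and write them under ``outdir``.

    Returns a name -> path mapping of everything written.  Files carry the
    seed in a header comment where the format allows.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if "medians" in kinds:
        paths["medians"] = write_expression_tsv(gen_median_matrix(cfg),
                                                outdir / "medians.tsv")
    if "samples" in kinds:
        matrix, groups = gen_sample_matrix(cfg)
        paths["samples"] = write_expression_tsv(matrix, outdir / "samples.tsv")
        gpath = outdir / "groups.tsv"
        with gpath.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# seed={cfg.seed}\n")
            for col, grp in groups.items():
                fh.write(f"{col}\t{grp}\n")
        paths["groups"] = gpath
    if "ppi" in kinds:
        bundle = gen_interactome(cfg)
        paths["interactome"] = write_interactome(bundle.net, outdir / "interactome.tsv")
        paths["tf_catalog"] = write_tf_catalog(bundle.catalog, outdir / "tf_catalog.txt")
        (outdir / "module_tfs.txt").write_text(
            "\n".join(sorted(bundle.module_tfs)) + "\n", encoding="utf-8")
        paths["module_tfs"] = outdir / "module_tfs.txt"
        (outdir / "queries.txt").write_text(
            "\n".join(sorted(bundle.queries)) + "\n", encoding="utf-8")
        paths["queries"] = outdir / "queries.txt"
    if "gaf" in kinds:
        corpus = gen_go_corpus(cfg)
        rows = [(pid, pid, tid) for tid, (_, prots) in corpus.terms.items()
                for pid in sorted(prots)]
        paths["gaf"] = write_gaf(rows, outdir / "annotations.gaf")
        paths["term_names"] = write_term_names(
            {tid: name for tid, (name, _) in corpus.terms.items() if name},
            outdir / "term_names.tsv")
    if "signatures" in kinds:
        paths["signatures"] = write_gmt(gen_signature_library(cfg),
                                        outdir / "signatures.gmt")
        paths["annotation_library"] = write_gmt(gen_annotation_library(cfg),
                                                outdir / "families.gmt")
    return paths
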
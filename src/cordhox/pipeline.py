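"""End-to-end orchestration of the cross-database inference workflow.

Stage order: signature crossing -> family over-representation -> candidate
annotation -> region-specific median filter -> two-group differential-
expression confirmation -> first-shell interactome crossing with the TF
catalog -> module enrichment -> GO antagonism screen -> regulatory-network
assembly.  Every stage writes its output under the run directory and is
hashed into a JSON manifest; reruns with an identical config and inputs
reproduce identical hashes.  On failure the outputs of completed stages are
retained, and every stage is independently invocable through its per-stage
CLI command on the same files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from .enrichment import module_enrichment, overrepresentation, rows_to_tsv
from .go_cooccurrence import antagonism_screen, read_gaf
from .interactome import cross_with_tfs, first_shell, second_shell_tf_links
from .io_formats import (
    read_expression_tsv, read_gene_list, read_gmt, read_interactome, read_tf_catalog,
)
from .network_assembly import assemble, export_network
from .region_expression import (
    RegionFilterConfig, de_results_to_frame, region_specific_filter, split_groups, welch_de,
)
from .signatures import annotate_membership, cross_signatures

logger = logging.getLogger("cordhox")


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""


@dataclass
class RunConfig:
    """Paths, thresholds and methods for one pipeline run."""

    signatures_gmt: str
    annotation_gmt: str
    medians_tsv: str
    samples_tsv: str
    groups_tsv: str
    interactome_tsv: str
    tf_catalog: str
    queries: str
    module_tfs: str
    gaf: str
    outdir: str
    term_names: str | None = None
    signature_a: str = "SC"
    signature_b: str = "Brain"
    family_term: str = "HOMEOBOX"
    target_label: str = "Spinal Cord"
    min_target: float = 5.0
    max_other: float = 1.0
    alpha: float = 0.05
    enrichment_method: str = "bh"
    pathway_a_terms: tuple[str, str] = datasets.SMAD_PATHWAY_TERMS
    pathway_b_terms: tuple[str, str] = datasets.AR_PATHWAY_TERMS
    repression_tsv: str | None = None
    predicted_tsv: str | None = None
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        for key in ("pathway_a_terms", "pathway_b_terms"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        RegionFilterConfig(self.target_label, self.min_target, self.max_other)
        required = [self.signatures_gmt, self.annotation_gmt, self.medians_tsv,
                    self.samples_tsv, self.groups_tsv, self.interactome_tsv,
                    self.tf_catalog, self.queries, self.module_tfs, self.gaf]
        missing = [p for p in required if not Path(p).is_file()]
        if missing:
            raise StageError(f"stage 0 (config): missing input file(s): {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_edge_tsv(path: str | Path) -> list[tuple[str, str]]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: edge line needs 2 tab-separated fields: {line!r}")
        out.append((parts[0], parts[1]))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; return the run manifest (also written to disk).

    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "thresholds": {"min_target": cfg.min_target, "max_other": cfg.max_other,
                       "alpha": cfg.alpha},
        "stages": {},
    }

    def stage(name: str, fn):
        logger.info("[%s] starting", name)
        try:
            out_path = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "output": str(out_path), "sha256": _sha256(Path(out_path))}
        logger.info("[%s] wrote %s", name, out_path)

    state: dict = {}

    def signatures_stage():
        lib = read_gmt(cfg.signatures_gmt)
        cross = cross_signatures(lib[cfg.signature_a], lib[cfg.signature_b],
                                 cfg.signature_a, cfg.signature_b)
        state["cross"] = cross
        out = outdir / "signature_cross.json"
        out.write_text(json.dumps({
            "a_specific": sorted(cross.a_specific),
            "b_specific": sorted(cross.b_specific),
            "shared": sorted(cross.shared),
        }, indent=1) + "\n", encoding="utf-8")
        return out

    def enrichment_stage():
        library = read_gmt(cfg.annotation_gmt)
        universe = set().union(*library.entries.values()) | state["cross"].a_specific \
            | state["cross"].b_specific | state["cross"].shared
        rows = overrepresentation(state["cross"].a_specific, library, universe,
                                  method=cfg.enrichment_method)
        state["enrichment"] = rows
        out = outdir / "family_enrichment.tsv"
        rows_to_tsv(rows, out)
        return out

    def candidates_stage():
        library = read_gmt(cfg.annotation_gmt)
        cands = annotate_membership(state["cross"].a_specific, library, cfg.family_term)
        state["candidates"] = cands
        out = outdir / "candidate_genes.txt"
        out.write_text("\n".join(sorted(cands)) + "\n", encoding="utf-8")
        return out

    def region_filter_stage():
        matrix = read_expression_tsv(cfg.medians_tsv)
        passed = region_specific_filter(matrix, RegionFilterConfig(
            cfg.target_label, cfg.min_target, cfg.max_other))
        state["region_genes"] = passed
        out = outdir / "region_specific_genes.txt"
        out.write_text("\n".join(passed) + "\n", encoding="utf-8")
        return out

    def diffexp_stage():
        matrix = read_expression_tsv(cfg.samples_tsv, unit="AU")
        groups = {}
        for line in Path(cfg.groups_tsv).read_text(encoding="utf-8").splitlines():
            if line.strip() and not line.startswith("#"):
                col, grp = line.split("\t")[:2]
                groups[col] = grp
        g1, g2 = split_groups(matrix, groups, "group1", "group2")
        results = welch_de(g1, g2)
        state["de"] = results
        out = outdir / "diffexp.tsv"
        de_results_to_frame(results).to_csv(out, sep="\t", lineterminator="\n")
        return out

    def interactome_stage():
        net = read_interactome(cfg.interactome_tsv)
        queries = read_gene_list(cfg.queries)
        catalog = read_tf_catalog(cfg.tf_catalog)
        shell = first_shell(queries, net)
        tf_table = cross_with_tfs(shell, catalog)
        state.update(net=net, catalog=catalog, shell=shell, tf_table=tf_table)
        out = outdir / "tf_partners.tsv"
        pd.DataFrame([{"query": r.query, "partner": r.partner} for r in tf_table.rows]
                     ).to_csv(out, sep="\t", index=False, lineterminator="\n")
        return out

    def module_stage():
        module = read_gene_list(cfg.module_tfs)
        by_query = state["tf_table"].tf_partners_by_query()
        if not by_query:
            raise StageError("stage 'module_enrichment': no TF partners to test")
        # the query with the strongest module overlap carries the headline statistic
        best_q, best_row = None, None
        for q, partners in sorted(by_query.items()):
            row = module_enrichment(partners, module, state["catalog"])
            if best_row is None or row.p_raw < best_row.p_raw:
                best_q, best_row = q, row
        overlap_tfs = by_query[best_q] & module
        links = second_shell_tf_links(overlap_tfs, state["net"], module)
        state.update(module=module, module_row=best_row, module_query=best_q,
                     second_shell=links)
        out = outdir / "module_enrichment.json"
        out.write_text(json.dumps({
            "query": best_q,
            "k": best_row.k, "n": best_row.n, "K": best_row.K, "N": best_row.N,
            "fold": best_row.fold, "p": best_row.p_raw,
            "second_shell_links": links,
        }, indent=1) + "\n", encoding="utf-8")
        return out

    def go_stage():
        corpus = read_gaf(cfg.gaf, term_names=cfg.term_names)
        report = antagonism_screen(corpus, cfg.pathway_a_terms, cfg.pathway_b_terms)
        state["antagonism"] = report
        out = outdir / "antagonism.json"
        out.write_text(json.dumps({
            "verdict": report.verdict,
            "pairs": [dataclasses.asdict(p) for p in report.pairs],
        }, indent=1) + "\n", encoding="utf-8")
        return out

    def network_stage():
        physical = [(r.query, r.partner) for r in state["tf_table"].rows]
        physical += state["second_shell"]
        repression = (_read_edge_tsv(cfg.repression_tsv) if cfg.repression_tsv
                      else list(datasets.REPRESSION_EDGES))
        predicted = (_read_edge_tsv(cfg.predicted_tsv) if cfg.predicted_tsv
                     else list(datasets.PREDICTED_BINDING_EDGES))
        net = assemble(physical=physical, repression=repression, predicted=predicted,
                       roles=datasets.NODE_ROLES)
        state["network"] = net
        out = outdir / "network.graphml"
        export_network(net, out, format="graphml")
        export_network(net, outdir / "network.sif", format="sif")
        return out

    stages = [
        ("signatures", signatures_stage),
        ("family_enrichment", enrichment_stage),
        ("candidates", candidates_stage),
        ("region_filter", region_filter_stage),
        ("diffexp", diffexp_stage),
        ("tf_crossing", interactome_stage),
        ("module_enrichment", module_stage),
        ("go_antagonism", go_stage),
        ("network", network_stage),
    ]
    for name, fn in stages:
        stage(name, fn)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n", encoding="utf-8")
    return manifest
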
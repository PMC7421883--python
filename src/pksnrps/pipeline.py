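"""End-to-end orchestration: scan -> identify -> dereplicate -> tree ->
extract -> profile -> classify -> summarize, with per-stage outputs and a
provenance record."""
from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__, constants as C
from .bgc import (build_me_profile, extract_bgc, write_bgc_report,
                  write_me_profiles)
from .bundle import ReferenceBundle, load_reference_bundle
from .classify import (classify_daase, level1_classify, level2_classify,
                       NpCladeAssignment)
from .errors import ConfigError, PksNrpsError
from .io import read_fasta, read_gff3, read_taxonomy
from .mining import (Thresholds, collapse_orthologs, identify_hybrids,
                     write_stage_report)
from .phylo import assign_major_clade, build_distance_matrix, upgma, \
    write_newick
from .report import (estimate_chemical_space, summarize, summary_to_text,
                     summary_to_tsv, write_assignments)
from .scan import scan_domains, write_domain_table

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: str
    gff3: str
    outdir: str
    taxonomy: Optional[str] = None
    bundle: Optional[str] = None        # bundle directory; None = packaged
    scan_backend: str = "builtin_pssm"  # or import_table
    domain_table: Optional[str] = None
    distance_backend: str = "edlib"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    verbosity: str = "info"

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise ConfigError(f"protein FASTA not found: {self.fasta}")
        if not Path(self.gff3).exists():
            raise ConfigError(f"GFF3 not found: {self.gff3}")
        if self.taxonomy and not Path(self.taxonomy).exists():
            raise ConfigError(f"taxonomy table not found: {self.taxonomy}")
        if self.scan_backend == "import_table" and not self.domain_table:
            raise ConfigError("import_table backend requires domain_table")


@dataclass
class PipelineResult:
    outdir: Path
    n_proteins: int
    n_dataset1: int
    n_dataset2: int
    n_dataset3: int
    n_bgcs: int
    assignments: list
    summary: object
    tree: object


def run_pipeline(config: RunConfig,
                 bundle: Optional[ReferenceBundle] = None) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    stage = "load"
    try:
        bundle = bundle or load_reference_bundle(config.bundle)
        proteins = read_fasta(config.fasta)
        genes = read_gff3(config.gff3)
        taxonomy = read_taxonomy(config.taxonomy) if config.taxonomy else {}
        proteome = {p.id: p for p in proteins}
        genes_by_contig: dict[str, list] = {}
        for g in genes:
            genes_by_contig.setdefault(g.contig, []).append(g)
        gene_by_protein = {g.protein_id: g for g in genes}

        stage = "scan"
        hits = scan_domains(proteins, models=bundle.domain_models,
                            backend=config.scan_backend,
                            table_path=config.domain_table)
        write_domain_table(hits, outdir / "domain_hits.tsv")
        log.info("scan: %d domain hits on %d proteins", len(hits),
                 len(proteins))

        stage = "identify"
        # resolve each protein's taxon: explicit assembly key first, then
        # the contig carrying its gene (how merged-FASTA inputs link back)
        if taxonomy:
            from dataclasses import replace as _replace
            resolved = []
            for p in proteins:
                taxon = p.taxon or taxonomy.get(p.source_assembly)
                if taxon is None:
                    g = gene_by_protein.get(p.id)
                    if g is not None:
                        taxon = taxonomy.get(g.contig)
                resolved.append(_replace(p, taxon=taxon) if taxon else p)
            proteins = resolved
            proteome = {p.id: p for p in proteins}
        candidates = identify_hybrids(proteins, hits, th)
        n1 = len(candidates)
        n2 = sum(1 for c in candidates if c.dataset_stage == "dataset2")

        stage = "dereplicate"
        dataset3 = collapse_orthologs(candidates, taxonomy, th,
                                      backend=config.distance_backend)
        write_stage_report(candidates + dataset3, outdir / "datasets.tsv")
        log.info("identify: %d dataset1, %d dataset2, %d dataset3",
                 n1, n2, len(dataset3))

        stage = "tree"
        hybrids = [c.protein for c in dataset3]
        records = hybrids + bundle.reference_records()
        dm = build_distance_matrix(records, mode="pairwise",
                                   backend=config.distance_backend)
        tree = upgma(dm)
        write_newick(tree, outdir / "tree.nwk")
        placements = assign_major_clade(
            tree, bundle.reference_clades(), bundle.reference_np_clades(),
            outgroups=bundle.outgroup_ids())

        stage = "extract"
        bgcs = []
        skipped = []
        for cand in dataset3:
            gene = gene_by_protein.get(cand.protein.id)
            if gene is None:
                skipped.append(cand.protein.id)
                continue
            bgcs.append(extract_bgc(genes_by_contig[gene.contig], gene, th))
        if skipped:
            log.warning("extract: %d hybrids lack gene coordinates: %s",
                        len(skipped), skipped)
        write_bgc_report(bgcs, outdir / "bgc_report.tsv")

        stage = "profile"
        gene_to_hybrid = {b.hybrid_gene.protein_id: b for b in bgcs}
        profiles = {}
        for b in bgcs:
            profiles[b.bgc_id] = build_me_profile(b, proteome,
                                                  bundle.me_queries, th)
        write_me_profiles(profiles.values(), outdir / "me_profiles.tsv")

        stage = "classify"
        assignments: list[NpCladeAssignment] = []
        for b in bgcs:
            profile = profiles[b.bgc_id]
            placement = placements.get(b.hybrid_gene.protein_id)
            daase_candidates = [
                (gid, proteome[pid])
                for gid, _ident in profile.daase_hits
                for pid in [next(g.protein_id for g in b.member_genes
                                 if g.gene_id == gid)]
                if pid in proteome]
            daase = classify_daase(daase_candidates,
                                   bundle.daase_references,
                                   bundle.motif_model,
                                   min_identity=th.me_min_identity,
                                   min_query_coverage=th.me_min_query_coverage)
            major = placement.major_clade if placement else "unplaced"
            level1 = level1_classify(profile, major)
            assignments.append(level2_classify(
                profile, daase, level1, bundle.decision_table, placement))
        write_assignments(assignments, outdir / "classifications.tsv")

        stage = "summarize"
        summary = summarize(assignments)
        summary_to_tsv(summary, outdir / "summary.tsv")
        text = summary_to_text(summary, th)
        (outdir / "summary.txt").write_text(text + "\n")

        stage = "provenance"
        prov = {
            "pksnrps_version": __version__,
            "bundle_version": bundle.version,
            "seed": config.seed,
            "scan_backend": config.scan_backend,
            "distance_backend": config.distance_backend,
            "thresholds": asdict(th),
            "inputs": {"fasta": str(config.fasta), "gff3": str(config.gff3),
                       "taxonomy": str(config.taxonomy)},
            "counts": {"proteins": len(proteins), "dataset1": n1,
                       "dataset2": n2, "dataset3": len(dataset3),
                       "bgcs": len(bgcs),
                       "chemical_space": estimate_chemical_space(summary, th)},
        }
        (outdir / "provenance.yaml").write_text(
            yaml.safe_dump(prov, sort_keys=True))
    except PksNrpsError as exc:
        raise type(exc)(f"stage {stage!r}: {exc}") from exc

    return PipelineResult(outdir=outdir, n_proteins=len(proteins),
                          n_dataset1=n1, n_dataset2=n2,
                          n_dataset3=len(dataset3), n_bgcs=len(bgcs),
                          assignments=assignments, summary=summary, tree=tree)
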
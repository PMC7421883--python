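"""Synthetic annotated fungal contigs with planted hybrid BGCs.

Each planted BGC follows an NP-clade template: a hybrid gene whose protein
derives from the packaged reference hybrid of that clade (full
KS-AT-DH-CMeT-ER-KR-ACP-C-A-T-DKC block architecture, > 3,000 aa), the
clade's key modification-enzyme genes within the 20-kbp flanking window,
and decoy genes both inside and outside the window.  All sequences are
mutated copies of bundle material at a controlled per-position
substitution rate, and a ground-truth table links every planted gene to
its template, so end-to-end recovery is measurable without any external
data.

Genes carry protein sequences directly (protein-space planting);
coordinates use 3 bp per residue so window arithmetic is realistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import constants as C
from ._seqgen import mutate, random_protein
from .bundle import (ReferenceBundle, TEMPLATE_DAASE_REF, default_bundle)
from .classify import DecisionRule
from .errors import ConfigError, ValidationError
from .io import (GeneFeature, ProteinRecord, write_fasta, write_gff3,
                 write_taxonomy)


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Deterministic per-position substitution at probability `rate`."""
    return mutate(seq, rate, np.random.default_rng(seed))


@dataclass(frozen=True)
class CladeTemplate:
    """Blueprint of one NP clade's BGC: hybrid source + planted ME genes."""

    np_clade: str
    major_clade: str
    hybrid_source_id: str
    hybrid_sequence: str
    # (category token, source id, source sequence)
    me_genes: tuple[tuple[str, str, str], ...]


def default_templates(bundle: Optional[ReferenceBundle] = None
                      ) -> dict[str, CladeTemplate]:
    """One template per known NP clade, derived from the decision table.

    Each template's enzyme list satisfies exactly its own rule: the
    required key MEs, plus pKN and t-ER genes according to the rule's
    Level-I flags ("either" t-ER plants the gene, mirroring clades where
    most characterized BGCs carry it)."""
    bundle = bundle or default_bundle()
    templates: dict[str, CladeTemplate] = {}
    ref_by_clade = {np: rec for rec, _, np in bundle.characterized_hybrids}
    for rule in bundle.decision_table.rules:
        me_genes: list[tuple[str, str, str]] = []
        if rule.kn_required == "present":
            q = bundle.me_query("pKN")
            me_genes.append(("pKN", q.me_id, q.sequence))
        if rule.ter_required in ("present", "either"):
            q = bundle.me_query("tER")
            me_genes.append(("tER", q.me_id, q.sequence))
        for token in sorted(rule.required_mes):
            cat, _, _sub = token.partition(":")
            if cat == "DAase":
                ref = bundle.daase_reference(TEMPLATE_DAASE_REF[rule.np_clade])
                me_genes.append((token, ref.record.id, ref.record.sequence))
            else:
                q = bundle.me_query(cat)
                me_genes.append((token, q.me_id, q.sequence))
        rec = ref_by_clade[rule.np_clade]
        templates[rule.np_clade] = CladeTemplate(
            np_clade=rule.np_clade, major_clade=rule.level1_clade,
            hybrid_source_id=rec.id, hybrid_sequence=rec.sequence,
            me_genes=tuple(me_genes))
    return templates


@dataclass(frozen=True)
class CohortSpec:
    """What to generate: template multiplicities and nuisance parameters."""

    templates: dict  # np_clade -> multiplicity
    mutation_rate: float = 0.0
    seed: int = 0
    decoys_inside: tuple[int, int] = (2, 4)    # per contig, inclusive range
    decoys_outside: tuple[int, int] = (1, 2)
    decoy_length: tuple[int, int] = (250, 500)
    intergenic_gap: tuple[int, int] = (200, 1500)  # bp
    include_lovc_decoy: bool = True  # one HR-PKS-like contig (KS+AT, no C)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ConfigError("mutation_rate must be in [0, 0.5]")
        for _label, mult in self.templates.items():
            if mult < 0:
                raise ConfigError("template multiplicities must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    bgc_id: str
    contig: str
    hybrid_gene_id: str
    np_clade: str
    major_clade: str
    mutation_rate: float
    me_gene_ids: tuple[tuple[str, str], ...]  # (category token, gene id)


@dataclass
class Cohort:
    proteins: list[ProteinRecord]
    genes: list[GeneFeature]
    taxonomy: dict[str, tuple[str, str]]
    truth: list[TruthRecord]
    # decoys planted outside every extraction window, for leak checks
    outside_decoy_ids: list[str] = field(default_factory=list)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.faa",
            "gff3": outdir / "genes.gff3",
            "taxonomy": outdir / "taxonomy.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(sorted(self.proteins, key=lambda r: r.id), paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        write_taxonomy(self.taxonomy, paths["taxonomy"])
        with paths["truth"].open("w") as fh:
            fh.write("bgc_id\tcontig\thybrid_gene_id\tnp_clade\tmajor_clade\t"
                     "mutation_rate\tme_genes\n")
            for t in sorted(self.truth, key=lambda t: t.bgc_id):
                mes = ",".join(f"{cat}={gid}" for cat, gid in t.me_gene_ids)
                fh.write(f"{t.bgc_id}\t{t.contig}\t{t.hybrid_gene_id}\t"
                         f"{t.np_clade}\t{t.major_clade}\t"
                         f"{t.mutation_rate:.4f}\t{mes}\n")
        return paths


def read_truth(path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with Path(path).open() as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            (bgc_id, contig, hyb, np_clade, major, rate, mes) = \
                line.rstrip("\n").split("\t")
            me_ids = tuple(tuple(x.split("=", 1)) for x in mes.split(",")
                           if x)
            out.append(TruthRecord(bgc_id=bgc_id, contig=contig,
                                   hybrid_gene_id=hyb, np_clade=np_clade,
                                   major_clade=major,
                                   mutation_rate=float(rate),
                                   me_gene_ids=me_ids))
    return out


def _me_length_bp(protein_len: int) -> int:
    return protein_len * 3


def generate_cohort(spec: CohortSpec,
                    bundle: Optional[ReferenceBundle] = None) -> Cohort:
    """Deterministically generate a cohort under (spec, spec.seed)."""
    bundle = bundle or default_bundle()
    templates = default_templates(bundle)
    for label in spec.templates:
        if label not in templates:
            raise ValidationError(f"unknown template label {label!r}")
    rng = np.random.default_rng(spec.seed)

    proteins: list[ProteinRecord] = []
    genes: list[GeneFeature] = []
    taxonomy: dict[str, tuple[str, str]] = {}
    truth: list[TruthRecord] = []
    outside: list[str] = []

    instance = 0
    plan = [(label, templates[label])
            for label in sorted(spec.templates)
            for _ in range(spec.templates[label])]
    for label, tpl in plan:
        instance += 1
        asm = f"asm{instance:03d}"
        contig = f"{asm}_ctg1"
        genus = f"Genus{instance:03d}"
        taxonomy[asm] = (genus, f"sp{instance:03d}")
        taxonomy[contig] = taxonomy[asm]  # contig-keyed lookup for the pipeline
        taxon = taxonomy[asm]

        def add_gene(tag: str, seq: str, start: int) -> GeneFeature:
            gid = f"{asm}_{tag}"
            end = start + _me_length_bp(len(seq)) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            feat = GeneFeature(gene_id=gid, contig=contig, start=start,
                               end=end, strand=strand, protein_id=gid)
            genes.append(feat)
            proteins.append(ProteinRecord(id=gid, sequence=seq,
                                          source_assembly=asm, taxon=taxon))
            return feat

        def gap() -> int:
            return int(rng.integers(spec.intergenic_gap[0],
                                    spec.intergenic_gap[1] + 1))

        # upstream half of the planted MEs, then the hybrid, then the rest
        me_seqs = [(token, mutate(seq, spec.mutation_rate, rng), src)
                   for token, src, seq in tpl.me_genes]
        n_up = len(me_seqs) // 2
        n_decoys_in = int(rng.integers(spec.decoys_inside[0],
                                       spec.decoys_inside[1] + 1))
        pos = 1 + gap()
        me_gene_ids: list[tuple[str, str]] = []
        for k, (token, seq, _src) in enumerate(me_seqs[:n_up]):
            feat = add_gene(f"me{k:02d}", seq, pos)
            me_gene_ids.append((token, feat.gene_id))
            pos = feat.end + 1 + gap()
        hybrid_seq = mutate(tpl.hybrid_sequence, spec.mutation_rate, rng)
        hybrid = add_gene("hyb", hybrid_seq, pos)
        pos = hybrid.end + 1 + gap()
        for k, (token, seq, _src) in enumerate(me_seqs[n_up:], start=n_up):
            feat = add_gene(f"me{k:02d}", seq, pos)
            me_gene_ids.append((token, feat.gene_id))
            pos = feat.end + 1 + gap()
        for k in range(n_decoys_in):
            dlen = int(rng.integers(spec.decoy_length[0],
                                    spec.decoy_length[1] + 1))
            feat = add_gene(f"dec{k:02d}", random_protein(rng, dlen), pos)
            pos = feat.end + 1 + gap()
            if feat.start > hybrid.end + 20000:
                outside.append(feat.gene_id)  # drifted past the window
        # decoys guaranteed outside the 20-kbp window
        n_out = int(rng.integers(spec.decoys_outside[0],
                                 spec.decoys_outside[1] + 1))
        pos = max(pos, hybrid.end + 20001 + gap())
        for k in range(n_out):
            dlen = int(rng.integers(spec.decoy_length[0],
                                    spec.decoy_length[1] + 1))
            feat = add_gene(f"out{k:02d}", random_protein(rng, dlen), pos)
            outside.append(feat.gene_id)
            pos = feat.end + 1 + gap()

        truth.append(TruthRecord(
            bgc_id=hybrid.gene_id, contig=contig,
            hybrid_gene_id=hybrid.gene_id, np_clade=label,
            major_clade=tpl.major_clade, mutation_rate=spec.mutation_rate,
            me_gene_ids=tuple(me_gene_ids)))

    if spec.include_lovc_decoy and plan:
        # an HR-PKS-like protein: PKS module blocks but no NRPS module, so
        # the condensation-domain screen must reject it
        asm = "asm_lovc"
        contig = f"{asm}_ctg1"
        taxonomy[asm] = ("GenusLovc", "sp")
        taxonomy[contig] = taxonomy[asm]
        blocks = bundle.domain_blocks
        if blocks:
            pks = "".join(blocks[b] for b in
                          ("KS", "AT", "DH", "CMeT", "ER", "KR", "ACP"))
            seq = mutate(pks, spec.mutation_rate, rng) \
                + random_protein(rng, max(0, 3101 - len(pks)))
            gid = f"{asm}_hrpks"
            genes.append(GeneFeature(gene_id=gid, contig=contig, start=5001,
                                     end=5000 + 3 * len(seq), strand="+",
                                     protein_id=gid))
            proteins.append(ProteinRecord(id=gid, sequence=seq,
                                          source_assembly=asm,
                                          taxon=taxonomy[asm]))

    return Cohort(proteins=proteins, genes=genes, taxonomy=taxonomy,
                  truth=truth, outside_decoy_ids=outside)
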
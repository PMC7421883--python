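"""The packaged reference bundle.

A run needs reference material: characterized hybrid proteins anchoring
the 18 known NP clades, anchor sequences for the 11 predicted-clade
neighborhoods, NR-PKS and FAS outgroups, modification-enzyme query
sequences, subclade-labelled Diels-Alderase references, and the decision
table.  The default bundle uses synthetic stand-in sequences carrying the
real category and clade labels; they are generated deterministically from
a fixed, versioned seed, so redistribution of database proteins is
avoided while every label, length and divergence relationship is
realistic for the pipeline.  `write_bundle`/`load_reference_bundle`
round-trip a directory form, which is also how a user supplies real
sequences.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import constants as C
from ._seqgen import mutate, random_protein
from .bgc import MeReference
from .classify import (DaaseReference, DecisionTable, load_decision_table,
                       reference_id_for_clade)
from .errors import ValidationError
from .io import ProteinRecord, read_fasta, write_fasta
from .scan import PssmModel

BUNDLE_VERSION = "1.0"
BUNDLE_SEED = 910_884  # versioned: regenerating with this seed is byte-stable

# Synthetic stand-in for the SAM-binding motif that distinguishes type-I
# Diels-Alderases (glycine-rich methyltransferase-like core).
SAM_MOTIF = "LDIGGGTGQLAKELAQRHPHLE"

DOMAIN_BLOCK_LENGTHS = {
    "KS": 300, "AT": 320, "DH": 200, "CMeT": 240, "ER": 260, "KR": 260,
    "ACP": 90, "C": 320, "A": 460, "T": 90, "DKC": 260,
}
LINKER_LENGTH = 35

_SCANNED_DOMAINS = {"KS": C.PFAM_KS, "AT": C.PFAM_AT, "C": C.PFAM_C}
DOMAIN_THRESHOLD_FRACTION = 0.4
MOTIF_THRESHOLD_FRACTION = 0.5

# Divergence ladder of the synthetic reference genealogy.
_CLADE_DIVERGENCE = 0.18      # hybrid ancestor -> major-clade ancestor
_NP_DIVERGENCE = 0.08         # major-clade ancestor -> NP-clade reference
_OUTGROUP_DIVERGENCE = 0.08   # outgroup ancestor -> outgroup member
_DAASE_TYPE_DIVERGENCE = 0.15
_DAASE_SUBCLADE_DIVERGENCE = 0.10
_DAASE_REF_DIVERGENCE = 0.07

# Which packaged DAase reference a clade template plants.
TEMPLATE_DAASE_REF = {
    "Ia-D-2": "LepI", "Ia-D-3": "IccD", "Ib-C": "EqxF",
    "III-A": "CHGG_01241", "III-C": "PoxQ", "III-D": "CcsF",
}

OUTGROUP_KINDS = ("NR-PKS", "FAS")


@dataclass(frozen=True)
class ReferenceBundle:
    characterized_hybrids: tuple[tuple[ProteinRecord, str, str], ...]
    predicted_anchors: tuple[tuple[ProteinRecord, str, str], ...]
    outgroups: tuple[tuple[ProteinRecord, str], ...]
    me_queries: tuple[MeReference, ...]
    daase_references: tuple[DaaseReference, ...]
    decision_table: DecisionTable
    domain_models: tuple[PssmModel, ...]
    motif_model: PssmModel
    domain_blocks: dict
    version: str = BUNDLE_VERSION

    def __post_init__(self) -> None:
        if not self.outgroups:
            raise ValidationError("reference bundle requires outgroups")
        known = set(self.decision_table.known_labels)
        for _rec, _major, np_clade in self.characterized_hybrids:
            if np_clade not in known:
                raise ValidationError(
                    f"characterized hybrid clade {np_clade!r} not in the "
                    f"decision table")
        predicted = set(self.decision_table.predicted_labels)
        for _rec, _major, np_clade in self.predicted_anchors:
            if np_clade not in predicted:
                raise ValidationError(
                    f"anchor clade {np_clade!r} not a predicted label")
        covered = {r.subclade for r in self.daase_references}
        missing = set(C.DAASE_SUBCLADES) - covered
        if missing:
            raise ValidationError(
                f"DAase references missing subclade(s): {sorted(missing)}")

    # -- convenience views used by the pipeline --------------------------

    def reference_records(self) -> list[ProteinRecord]:
        return ([r for r, _, _ in self.characterized_hybrids]
                + [r for r, _, _ in self.predicted_anchors]
                + [r for r, _ in self.outgroups])

    def reference_clades(self) -> dict[str, str]:
        out = {r.id: major for r, major, _ in self.characterized_hybrids}
        out.update({r.id: major for r, major, _ in self.predicted_anchors})
        return out

    def reference_np_clades(self) -> dict[str, str]:
        out = {r.id: np for r, _, np in self.characterized_hybrids}
        out.update({r.id: np for r, _, np in self.predicted_anchors})
        return out

    def outgroup_ids(self) -> list[str]:
        return [r.id for r, _ in self.outgroups]

    def me_query(self, category: str) -> MeReference:
        for q in self.me_queries:
            if q.category == category and not q.me_id.startswith("DAase"):
                return q
        for q in self.me_queries:
            if q.category == category:
                return q
        raise KeyError(category)

    def daase_reference(self, name: str) -> DaaseReference:
        for r in self.daase_references:
            if r.record.id == name:
                return r
        raise KeyError(name)


def _major_of(np_clade: str) -> str:
    return np_clade.split("-")[0]


def _build_hybrid_ancestor(rng: np.random.Generator) -> tuple[str, dict]:
    blocks = {name: random_protein(rng, length)
              for name, length in DOMAIN_BLOCK_LENGTHS.items()}
    parts = []
    for name in C.HYBRID_DOMAIN_ORDER:
        parts.append(blocks[name])
        parts.append(random_protein(rng, LINKER_LENGTH))
    return "".join(parts[:-1]), blocks


@lru_cache(maxsize=1)
def default_bundle() -> ReferenceBundle:
    """The packaged default bundle, regenerated deterministically."""
    rng = np.random.default_rng(BUNDLE_SEED)
    ancestor, blocks = _build_hybrid_ancestor(rng)

    clade_anc = {m: mutate(ancestor, _CLADE_DIVERGENCE, rng)
                 for m in C.MAJOR_CLADES}
    characterized = []
    for np_clade in C.KNOWN_CLADES:
        major = _major_of(np_clade)
        rec = ProteinRecord(id=reference_id_for_clade(np_clade),
                            sequence=mutate(clade_anc[major],
                                            _NP_DIVERGENCE, rng),
                            source_assembly="bundle")
        characterized.append((rec, major, np_clade))
    anchors = []
    for np_clade in C.PREDICTED_CLADES:
        major = _major_of(np_clade)
        rec = ProteinRecord(id=reference_id_for_clade(np_clade),
                            sequence=mutate(clade_anc[major],
                                            _NP_DIVERGENCE, rng),
                            source_assembly="bundle")
        anchors.append((rec, major, np_clade))

    # Outgroups: NR-PKS shares (diverged) KS/AT/ACP blocks with the hybrids
    # but lacks the NRPS module; FAS is a separate lineage entirely.
    nr_anc = (mutate(blocks["KS"], 0.25, rng)
              + mutate(blocks["AT"], 0.25, rng)
              + random_protein(rng, 1300)
              + mutate(blocks["ACP"], 0.25, rng))
    fas_anc = random_protein(rng, 2000)
    outgroups = []
    for i in range(19):
        outgroups.append((ProteinRecord(
            id=f"NRPKS_{i + 1:02d}",
            sequence=mutate(nr_anc, _OUTGROUP_DIVERGENCE, rng),
            source_assembly="bundle"), "NR-PKS"))
    for i in range(6):
        outgroups.append((ProteinRecord(
            id=f"FAS_{i + 1:02d}",
            sequence=mutate(fas_anc, _OUTGROUP_DIVERGENCE, rng),
            source_assembly="bundle"), "FAS"))

    # Modification-enzyme queries, one per non-DAase category.
    me_queries: list[MeReference] = []
    for cat in C.ME_CATEGORIES:
        if cat == "DAase":
            continue
        length = int(rng.integers(320, 451))
        me_queries.append(MeReference(me_id=f"MEQ_{cat}", category=cat,
                                      sequence=random_protein(rng, length)))

    # Diels-Alderases: one ancestor, type-I gains the SAM motif, subclades
    # then individual references diverge below it.
    daase_anc = random_protein(rng, 400)
    type1 = mutate(daase_anc, _DAASE_TYPE_DIVERGENCE, rng)
    type1 = type1[:40] + SAM_MOTIF + type1[40 + len(SAM_MOTIF):]
    type2 = mutate(daase_anc, _DAASE_TYPE_DIVERGENCE, rng)
    daase_refs: list[DaaseReference] = []
    for subclade in C.DAASE_SUBCLADES:
        base = type1 if C.daase_type(subclade) == "typeI" else type2
        sub_anc = mutate(base, _DAASE_SUBCLADE_DIVERGENCE, rng)
        if C.daase_type(subclade) == "typeI":
            # keep the motif recognizable at the subclade level
            sub_anc = sub_anc[:40] + SAM_MOTIF + sub_anc[40 + len(SAM_MOTIF):]
        for name in C.DAASE_REFERENCE_NAMES[subclade]:
            seq = mutate(sub_anc, _DAASE_REF_DIVERGENCE, rng)
            daase_refs.append(DaaseReference(
                record=ProteinRecord(id=name, sequence=seq,
                                     source_assembly="bundle"),
                subclade=subclade))
    # DAase references double as the category's ME queries.
    for ref in daase_refs:
        me_queries.append(MeReference(me_id=f"DAase_{ref.record.id}",
                                      category="DAase",
                                      sequence=ref.record.sequence))

    domain_models = tuple(
        PssmModel.from_consensus(pfam, blocks[name],
                                 threshold_fraction=DOMAIN_THRESHOLD_FRACTION)
        for name, pfam in _SCANNED_DOMAINS.items())
    motif_model = PssmModel.from_consensus(
        "SAM_motif", SAM_MOTIF, threshold_fraction=MOTIF_THRESHOLD_FRACTION)

    return ReferenceBundle(
        characterized_hybrids=tuple(characterized),
        predicted_anchors=tuple(anchors),
        outgroups=tuple(outgroups),
        me_queries=tuple(me_queries),
        daase_references=tuple(daase_refs),
        decision_table=load_decision_table(),
        domain_models=domain_models,
        motif_model=motif_model,
        domain_blocks=blocks,
        version=BUNDLE_VERSION,
    )


# ---------------------------------------------------------------------------
# Directory form
# ---------------------------------------------------------------------------

def write_bundle(bundle: ReferenceBundle, outdir) -> None:
    """Materialize a bundle as a directory (FASTA + label TSVs + manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def dump(records, path):
        write_fasta(records, outdir / path)

    dump([r for r, _, _ in bundle.characterized_hybrids], "characterized.faa")
    with (outdir / "characterized.tsv").open("w") as fh:
        fh.write("id\tmajor_clade\tnp_clade\n")
        for rec, major, np_clade in bundle.characterized_hybrids:
            fh.write(f"{rec.id}\t{major}\t{np_clade}\n")
    dump([r for r, _, _ in bundle.predicted_anchors], "anchors.faa")
    with (outdir / "anchors.tsv").open("w") as fh:
        fh.write("id\tmajor_clade\tnp_clade\n")
        for rec, major, np_clade in bundle.predicted_anchors:
            fh.write(f"{rec.id}\t{major}\t{np_clade}\n")
    dump([r for r, _ in bundle.outgroups], "outgroups.faa")
    with (outdir / "outgroups.tsv").open("w") as fh:
        fh.write("id\tkind\n")
        for rec, kind in bundle.outgroups:
            fh.write(f"{rec.id}\t{kind}\n")
    with (outdir / "me_queries.tsv").open("w") as fh:
        fh.write("me_id\tcategory\n")
        for q in bundle.me_queries:
            fh.write(f"{q.me_id}\t{q.category}\n")
    write_fasta([ProteinRecord(id=q.me_id, sequence=q.sequence)
                 for q in bundle.me_queries], outdir / "me_queries.faa")
    dump([r.record for r in bundle.daase_references], "daase.faa")
    with (outdir / "daase.tsv").open("w") as fh:
        fh.write("id\tsubclade\n")
        for r in bundle.daase_references:
            fh.write(f"{r.record.id}\t{r.subclade}\n")
    with (outdir / "domain_models.tsv").open("w") as fh:
        fh.write("domain_id\tthreshold_fraction\tconsensus\n")
        for m in bundle.domain_models:
            fh.write(f"{m.domain_id}\t{DOMAIN_THRESHOLD_FRACTION}\t"
                     f"{m.consensus}\n")
    with (outdir / "manifest.cfg").open("w") as fh:
        fh.write(f"version={bundle.version}\n")
        fh.write(f"sam_motif={bundle.motif_model.consensus}\n")
        fh.write(f"motif_threshold_fraction={MOTIF_THRESHOLD_FRACTION}\n")
    import shutil
    from importlib import resources
    table_src = resources.files("pksnrps").joinpath("data/decision_table.tsv")
    (outdir / "decision_table.tsv").write_text(table_src.read_text())


def load_reference_bundle(path=None) -> ReferenceBundle:
    """Load a bundle directory, or the packaged default when `path` is None."""
    if path is None:
        return default_bundle()
    path = Path(path)
    manifest_path = path / "manifest.cfg"
    if not manifest_path.exists():
        raise ValidationError(f"bundle directory {path} lacks manifest.cfg")
    manifest = {}
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, _, v = line.partition("=")
        manifest[k.strip()] = v.strip()

    def labelled(faa: str, tsv: str, n_label_cols: int):
        records = {r.id: r for r in read_fasta(path / faa)}
        rows = []
        with (path / tsv).open() as fh:
            next(fh)  # header
            for line in fh:
                if not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if cols[0] not in records:
                    raise ValidationError(
                        f"{tsv}: id {cols[0]!r} missing from {faa}")
                rows.append((records[cols[0]], *cols[1:1 + n_label_cols]))
        return rows

    characterized = [(r, a, b) for r, a, b in
                     labelled("characterized.faa", "characterized.tsv", 2)]
    anchors = [(r, a, b) for r, a, b in
               labelled("anchors.faa", "anchors.tsv", 2)]
    outgroups = [(r, k) for r, k in labelled("outgroups.faa",
                                             "outgroups.tsv", 1)]
    me_rows = labelled("me_queries.faa", "me_queries.tsv", 1)
    me_queries = [MeReference(me_id=r.id, category=cat, sequence=r.sequence)
                  for r, cat in me_rows]
    daase = [DaaseReference(record=r, subclade=sub)
             for r, sub in labelled("daase.faa", "daase.tsv", 1)]
    models = []
    with (path / "domain_models.tsv").open() as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            dom, frac, consensus = line.rstrip("\n").split("\t")
            models.append(PssmModel.from_consensus(
                dom, consensus, threshold_fraction=float(frac)))
    motif_model = PssmModel.from_consensus(
        "SAM_motif", manifest["sam_motif"],
        threshold_fraction=float(manifest.get("motif_threshold_fraction",
                                              MOTIF_THRESHOLD_FRACTION)))
    table = load_decision_table(path / "decision_table.tsv")
    return ReferenceBundle(
        characterized_hybrids=tuple(characterized),
        predicted_anchors=tuple(anchors),
        outgroups=tuple(outgroups),
        me_queries=tuple(me_queries),
        daase_references=tuple(daase),
        decision_table=table,
        domain_models=tuple(models),
        motif_model=motif_model,
        domain_blocks={},
        version=manifest.get("version", "unknown"),
    )
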
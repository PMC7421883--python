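"""Biosynthetic-gene-cluster extraction and modification-enzyme profiling.

The BGC of a hybrid is the hybrid gene plus every gene overlapping the
window extending `bgc_window` (20 kbp) upstream of its start and
downstream of its end, on the same contig.  Each member gene's protein is
searched locally (Smith-Waterman) against the modification-enzyme query
set; a category is "present" when its best identity strictly exceeds the
identity cutoff and the aligned region covers enough of the query.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import constants as C
from .align import local_alignment_stats
from .errors import ValidationError
from .io import GeneFeature, ProteinRecord
from .mining import Thresholds

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bgc:
    hybrid_gene: GeneFeature
    member_genes: tuple[GeneFeature, ...]
    contig: str
    window_start: int
    window_end: int

    @property
    def bgc_id(self) -> str:
        return self.hybrid_gene.gene_id


def extract_bgc(genes: Sequence[GeneFeature], hybrid: GeneFeature,
                thresholds: Thresholds = Thresholds()) -> Bgc:
    """Collect all genes within the flanking window around `hybrid`.

    The window is [hybrid.start - w, hybrid.end + w] clipped at 1
    (1-based inclusive coordinates); membership requires >= 1 bp overlap
    and the hybrid's contig.
    """
    if not any(g.gene_id == hybrid.gene_id and g.contig == hybrid.contig
               for g in genes):
        raise ValidationError(
            f"hybrid gene {hybrid.gene_id!r} absent from gene list")
    w = thresholds.bgc_window
    wstart = max(1, hybrid.start - w)
    wend = hybrid.end + w
    members = tuple(sorted(
        (g for g in genes
         if g.contig == hybrid.contig and g.start <= wend and g.end >= wstart),
        key=lambda g: g.sort_key))
    return Bgc(hybrid_gene=hybrid, member_genes=members, contig=hybrid.contig,
               window_start=wstart, window_end=wend)


@dataclass(frozen=True)
class MeReference:
    """A modification-enzyme query sequence with its category."""

    me_id: str
    category: str
    sequence: str

    def __post_init__(self) -> None:
        if self.category not in C.ME_CATEGORIES:
            raise ValidationError(
                f"ME query {self.me_id!r}: unknown category {self.category!r}")
        if not self.sequence:
            raise ValidationError(f"ME query {self.me_id!r}: empty sequence")


@dataclass(frozen=True)
class CategoryHit:
    present: bool
    best_identity: float
    best_gene: str
    best_query: str


@dataclass
class MeProfile:
    """Presence/absence and best identities per ME category for one BGC."""

    bgc_id: str
    categories: dict[str, CategoryHit] = field(default_factory=dict)
    # individual DAase candidates for downstream subclade typing
    daase_hits: list[tuple[str, float]] = field(default_factory=list)

    def present(self, category: str) -> bool:
        hit = self.categories.get(category)
        return bool(hit and hit.present)

    def present_categories(self) -> set[str]:
        return {c for c, h in self.categories.items() if h.present}

    def best_identity(self, category: str) -> float:
        hit = self.categories.get(category)
        return hit.best_identity if hit else 0.0


def build_me_profile(bgc: Bgc,
                     proteome: Mapping[str, ProteinRecord],
                     me_queries: Sequence[MeReference],
                     thresholds: Thresholds = Thresholds()) -> MeProfile:
    """Best local identity per ME category over all member-gene proteins.

    The hybrid gene itself is excluded from matching.  `proteome` maps
    gene protein_ids to records; members without a resolvable protein are
    skipped with a warning.  Presence requires identity strictly above
    `me_min_identity` and query coverage >= `me_min_query_coverage` (the
    coverage condition screens out short spurious local blocks that a
    BLAST E-value filter would remove).
    """
    if not me_queries:
        raise ValidationError("build_me_profile requires a non-empty ME query set")
    profile = MeProfile(bgc_id=bgc.bgc_id)
    best: dict[str, CategoryHit] = {}
    daase_best: dict[str, float] = {}
    for gene in bgc.member_genes:
        if gene.gene_id == bgc.hybrid_gene.gene_id:
            continue
        record = proteome.get(gene.protein_id)
        if record is None:
            log.warning("BGC %s: member gene %s has no protein; skipped",
                        bgc.bgc_id, gene.gene_id)
            continue
        for query in me_queries:
            st = local_alignment_stats(query.sequence, record.sequence)
            if st.query_coverage < thresholds.me_min_query_coverage:
                continue
            if query.category == "DAase":
                prev = daase_best.get(gene.gene_id, -1.0)
                if st.identity > prev:
                    daase_best[gene.gene_id] = st.identity
            cur = best.get(query.category)
            if cur is None or st.identity > cur.best_identity:
                best[query.category] = CategoryHit(
                    present=st.identity > thresholds.me_min_identity,
                    best_identity=st.identity,
                    best_gene=gene.gene_id,
                    best_query=query.me_id)
    profile.categories = best
    profile.daase_hits = sorted(
        ((g, ident) for g, ident in daase_best.items()
         if ident > thresholds.me_min_identity),
        key=lambda t: t[0])
    return profile


def write_bgc_report(bgcs: Iterable[Bgc], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("bgc_id\tcontig\twindow_start\twindow_end\tn_members\t"
                 "member_genes\n")
        for b in sorted(bgcs, key=lambda b: b.bgc_id):
            members = ",".join(g.gene_id for g in b.member_genes)
            fh.write(f"{b.bgc_id}\t{b.contig}\t{b.window_start}\t"
                     f"{b.window_end}\t{len(b.member_genes)}\t{members}\n")


def write_me_profiles(profiles: Iterable[MeProfile], path) -> None:
    """One row per BGC, one column per category with its best identity
    (blank when the category was never seen)."""
    profiles = sorted(profiles, key=lambda p: p.bgc_id)
    with Path(path).open("w") as fh:
        fh.write("bgc_id\t" + "\t".join(C.ME_CATEGORIES) + "\n")
        for p in profiles:
            cells = []
            for cat in C.ME_CATEGORIES:
                hit = p.categories.get(cat)
                if hit is None:
                    cells.append("")
                else:
                    mark = "+" if hit.present else "-"
                    cells.append(f"{mark}{hit.best_identity:.1f}")
            fh.write(p.bgc_id + "\t" + "\t".join(cells) + "\n")


def read_blast_table(path, query_categories: Mapping[str, str]) -> dict:
    """Import a BLAST outfmt-6-like TSV (qseqid, sseqid, pident, length,
    evalue) as {(query, subject): (pident, length)} for parity runs.
    `query_categories` maps qseqid -> ME category and is used to reject
    unknown queries."""
    out: dict[tuple[str, str], tuple[float, int]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("qseqid"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValidationError(f"{path}:{lineno}: expected >=4 columns")
            q, s = cols[0], cols[1]
            if q not in query_categories:
                raise ValidationError(
                    f"{path}:{lineno}: unknown query id {q!r}")
            pident, length = float(cols[2]), int(cols[3])
            key = (q, s)
            if key not in out or pident > out[key][0]:
                out[key] = (pident, length)
    return out
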
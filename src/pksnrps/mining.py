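"""Hybrid identification and dereplication.

A PKS-NRPS hybrid candidate must carry ketosynthase (KS), acyltransferase
(AT) and condensation (C) domain hits (dataset 1); the condensation domain
separates true hybrids from LovC-type HR-PKSs.  Candidates longer than
3,000 aa form dataset 2.  Within each genus, near-identical hybrids
(p-distance < 0.05, single linkage) collapse to one representative,
yielding dataset 3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from . import constants as C
from .align import p_distance
from .errors import ConfigError
from .io import ProteinRecord
from .scan import DomainHit, group_hits

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """The pipeline's tunable cutoffs (defaults as commonly applied in
    fungal hybrid mining: >3,000 aa hybrids, <0.05 ortholog distance,
    20-kbp BGC window, >40% ME identity, ~100 derivatives per NP group)."""

    min_hybrid_length: int = 3000       # aa, strict 'more than'
    ortholog_distance: float = 0.05     # p-distance, strict 'less than'
    bgc_window: int = 20000             # bp each side of the hybrid gene
    me_min_identity: float = 40.0       # percent, strict 'more than'
    me_min_query_coverage: float = 0.5  # fraction of ME query aligned
    derivatives_per_group: int = 100

    def __post_init__(self) -> None:
        if self.min_hybrid_length <= 0 or self.bgc_window <= 0 \
                or self.derivatives_per_group <= 0:
            raise ConfigError("thresholds must be positive")
        if not 0 < self.ortholog_distance < 1:
            raise ConfigError("ortholog_distance must be in (0,1)")
        if not 0 < self.me_min_identity < 100:
            raise ConfigError("me_min_identity must be in (0,100)")
        if not 0 <= self.me_min_query_coverage <= 1:
            raise ConfigError("me_min_query_coverage must be in [0,1]")


@dataclass(frozen=True)
class HybridCandidate:
    protein: ProteinRecord
    hits: tuple[DomainHit, ...]
    dataset_stage: str  # dataset1 / dataset2 / dataset3

    @property
    def length_aa(self) -> int:
        return len(self.protein.sequence)

    @property
    def passes_length(self) -> bool:
        return self.dataset_stage in ("dataset2", "dataset3")

    @property
    def domains(self) -> set[str]:
        return {h.domain_id for h in self.hits}


def identify_hybrids(proteins: Sequence[ProteinRecord],
                     hits: Sequence[DomainHit],
                     thresholds: Thresholds = Thresholds()
                     ) -> list[HybridCandidate]:
    """Apply the KS/AT/C architecture screen and the length filter.

    Returns all dataset-1 candidates; those exceeding the length cutoff
    (strictly) are marked dataset2.
    """
    by_protein = group_hits(hits)
    out: list[HybridCandidate] = []
    for protein in proteins:
        phits = by_protein.get(protein.id, [])
        doms = {h.domain_id for h in phits}
        if not {C.PFAM_KS, C.PFAM_AT, C.PFAM_C} <= doms:
            continue
        stage = ("dataset2"
                 if len(protein.sequence) > thresholds.min_hybrid_length
                 else "dataset1")
        out.append(HybridCandidate(protein=protein,
                                   hits=tuple(sorted(phits,
                                                     key=lambda h: h.start)),
                                   dataset_stage=stage))
    out.sort(key=lambda c: c.protein.id)
    return out


def pairwise_distance(a: ProteinRecord, b: ProteinRecord,
                      backend: str = "edlib") -> float:
    """Evolutionary p-distance between two proteins (see align.p_distance)."""
    return p_distance(a, b, backend=backend)


def collapse_orthologs(candidates: Sequence[HybridCandidate],
                       taxonomy: Mapping[str, tuple[str, str]],
                       thresholds: Thresholds = Thresholds(),
                       backend: str = "edlib") -> list[HybridCandidate]:
    """Dereplicate near-identical hybrids within each genus (dataset 3).

    Single-linkage clusters under `ortholog_distance` collapse to one
    representative: the longest sequence, ties to the lexicographically
    smallest id.  Cross-genus pairs never collapse; candidates with
    unknown taxonomy are kept and never collapsed (a warning is logged).
    """
    ds2 = [c for c in candidates if c.dataset_stage in ("dataset2", "dataset3")]
    by_genus: dict[str, list[HybridCandidate]] = {}
    loose: list[HybridCandidate] = []
    for cand in ds2:
        taxon = cand.protein.taxon or taxonomy.get(cand.protein.source_assembly)
        if taxon is None:
            log.warning("candidate %s has unknown taxonomy; kept uncollapsed",
                        cand.protein.id)
            loose.append(cand)
        else:
            by_genus.setdefault(taxon[0], []).append(cand)

    kept: list[HybridCandidate] = list(loose)
    for genus in sorted(by_genus):
        group = sorted(by_genus[genus], key=lambda c: c.protein.id)
        n = len(group)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                dist = pairwise_distance(group[i].protein, group[j].protein,
                                         backend=backend)
                if dist < thresholds.ortholog_distance:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[HybridCandidate]] = {}
        for i, cand in enumerate(group):
            clusters.setdefault(find(i), []).append(cand)
        for members in clusters.values():
            rep = min(members,
                      key=lambda c: (-len(c.protein.sequence), c.protein.id))
            kept.append(rep)

    kept = [replace(c, dataset_stage="dataset3") for c in kept]
    kept.sort(key=lambda c: c.protein.id)
    return kept


def write_stage_report(candidates: Iterable[HybridCandidate], path) -> None:
    """Dataset-stage TSV: protein_id, stage, length, domains."""
    with Path(path).open("w") as fh:
        fh.write("protein_id\tstage\tlength\tdomains\n")
        for c in sorted(candidates, key=lambda c: c.protein.id):
            doms = ",".join(sorted(c.domains))
            fh.write(f"{c.protein.id}\t{c.dataset_stage}\t{c.length_aa}\t"
                     f"{doms}\n")
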
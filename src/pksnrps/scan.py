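"""Domain detection: position-specific scoring models and the scan stage.

The built-in backend scores every window of a protein against a per-model
PSSM derived from the model's consensus block (BLOSUM62 column of the
consensus residue at each position).  A hit is any non-overlapping window
scoring above the model's calibrated threshold.  Real HMMER/Pfam scans are
supported through the ``import_table`` backend, which validates and passes
through an externally produced tabular scan.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ParseError, ValidationError
from .io import ProteinRecord

# Alphabet used for PSSM indexing: 20 standard residues then X.
_ALPHA = "ACDEFGHIKLMNPQRSTVWYX"
_CODE = np.full(128, 20, dtype=np.int8)  # unknowns score as X
for _i, _c in enumerate(_ALPHA):
    _CODE[ord(_c)] = _i

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class DomainHit:
    """A domain-model match on a protein (1-based inclusive residue span)."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"hit {self.domain_id} on {self.protein_id}: bad span "
                f"{self.start}..{self.end}"
            )
        if not np.isfinite(self.score):
            raise ValidationError(
                f"hit {self.domain_id} on {self.protein_id}: non-finite score"
            )


@dataclass(frozen=True)
class PssmModel:
    """Log-odds-style scoring model for one domain family.

    `matrix` has shape (len(consensus), 21), indexed by residue code; the
    threshold is an absolute score calibrated as a fraction of the
    consensus self-score.
    """

    domain_id: str
    consensus: str
    matrix: np.ndarray
    threshold: float
    self_score: float

    @classmethod
    def from_consensus(cls, domain_id: str, consensus: str,
                       threshold_fraction: float = 0.4) -> "PssmModel":
        codes = _CODE[np.frombuffer(consensus.encode(), np.uint8)]
        mat = np.empty((len(consensus), 21), dtype=np.float32)
        for j, aa in enumerate(_ALPHA):
            col = np.array([_BLOSUM62[c][aa] for c in consensus],
                           dtype=np.float32)
            mat[:, j] = col
        self_score = float(mat[np.arange(len(consensus)), codes].sum())
        return cls(domain_id=domain_id, consensus=consensus, matrix=mat,
                   threshold=threshold_fraction * self_score,
                   self_score=self_score)

    def window_scores(self, sequence: str) -> np.ndarray:
        """Score of every length-W window of `sequence` (empty if too short)."""
        w = len(self.consensus)
        codes = _CODE[np.frombuffer(sequence.encode(), np.uint8)]
        n = len(codes) - w + 1
        if n <= 0:
            return np.empty(0, dtype=np.float64)
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        return self.matrix[np.arange(w)[None, :], windows].sum(axis=1,
                                                               dtype=np.float64)

    def best_score(self, sequence: str) -> float:
        scores = self.window_scores(sequence)
        return float(scores.max()) if scores.size else float("-inf")


def _scan_one(protein: ProteinRecord, model: PssmModel) -> list[DomainHit]:
    scores = model.window_scores(protein.sequence)
    if scores.size == 0:
        return []
    w = len(model.consensus)
    order = np.argsort(scores, kind="stable")[::-1]
    hits: list[DomainHit] = []
    taken: list[tuple[int, int]] = []
    for o in order:
        s = float(scores[o])
        if s <= model.threshold:
            break
        start, end = int(o) + 1, int(o) + w  # 1-based inclusive
        if any(start <= e and end >= b for b, e in taken):
            continue
        taken.append((start, end))
        hits.append(DomainHit(protein.id, model.domain_id, start, end, s))
    return hits


def scan_domains(proteins: Sequence[ProteinRecord],
                 models: Iterable[PssmModel] | None = None,
                 backend: str = "builtin_pssm",
                 table_path=None) -> list[DomainHit]:
    """Detect domain hits on each protein.

    backend ``builtin_pssm``: score the packaged PSSMs (`models` required).
    backend ``import_table``: read a TSV (protein_id, domain_id, start, end,
    score) produced by an external scanner and pass it through after
    coordinate validation.
    """
    if backend == "builtin_pssm":
        if not models:
            raise ValidationError("builtin_pssm backend requires models")
        hits: list[DomainHit] = []
        for protein in proteins:
            for model in models:
                hits.extend(_scan_one(protein, model))
    elif backend == "import_table":
        if table_path is None:
            raise ValidationError("import_table backend requires table_path")
        hits = read_domain_table(table_path, proteins)
    else:
        raise ValidationError(f"unknown scan backend {backend!r}")
    hits.sort(key=lambda h: (h.protein_id, h.start, h.domain_id))
    return hits


def read_domain_table(path, proteins: Sequence[ProteinRecord]) -> list[DomainHit]:
    """Import an external domain scan (TSV: protein_id, domain_id, start,
    end, score; header optional).  Rows referencing unknown proteins or
    spans beyond the protein length are rejected."""
    path = Path(path)
    lengths = {p.id: len(p.sequence) for p in proteins}
    hits: list[DomainHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "protein_id":
                continue  # header
            if len(cols) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            pid, dom = cols[0], cols[1]
            if pid not in lengths:
                raise ValidationError(
                    f"{path}:{lineno}: unknown protein id {pid!r}"
                )
            try:
                start, end, score = int(cols[2]), int(cols[3]), float(cols[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            if end > lengths[pid]:
                raise ValidationError(
                    f"{path}:{lineno}: hit end {end} exceeds length of {pid!r}"
                )
            hits.append(DomainHit(pid, dom, start, end, score))
    return hits


def write_domain_table(hits: Iterable[DomainHit], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_id\tdomain_id\tstart\tend\tscore\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_id}\t{h.start}\t{h.end}\t"
                     f"{h.score:.2f}\n")


def group_hits(hits: Iterable[DomainHit]) -> Mapping[str, list[DomainHit]]:
    out: dict[str, list[DomainHit]] = {}
    for h in hits:
        out.setdefault(h.protein_id, []).append(h)
    return out
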
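"""Aggregation of NP-clade assignments into the per-clade summary table
and the chemical-space estimate."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import constants as C
from .classify import NpCladeAssignment
from .mining import Thresholds


def round_half_up(x: float) -> int:
    """Round to nearest integer, exact halves away from zero-ward .5 up."""
    import math
    return int(math.floor(x + 0.5))


@dataclass
class CladeRow:
    clade: str
    known_groups: int = 0
    known_bgcs: int = 0
    predicted_groups: int = 0
    predicted_bgcs: int = 0
    unclassified_bgcs: int = 0

    @property
    def total_bgcs(self) -> int:
        return self.known_bgcs + self.predicted_bgcs + self.unclassified_bgcs

    def percent(self, status: str) -> int:
        count = {"known": self.known_bgcs, "predicted": self.predicted_bgcs,
                 "unclassified": self.unclassified_bgcs}[status]
        if self.total_bgcs == 0:
            return 0
        return round_half_up(100.0 * count / self.total_bgcs)


@dataclass
class ClassificationSummary:
    rows: dict[str, CladeRow] = field(default_factory=dict)

    @property
    def total(self) -> CladeRow:
        tot = CladeRow(clade="Total")
        for row in self.rows.values():
            tot.known_groups += row.known_groups
            tot.known_bgcs += row.known_bgcs
            tot.predicted_groups += row.predicted_groups
            tot.predicted_bgcs += row.predicted_bgcs
            tot.unclassified_bgcs += row.unclassified_bgcs
        return tot

    @property
    def classified_bgcs(self) -> int:
        t = self.total
        return t.known_bgcs + t.predicted_bgcs

    @property
    def total_groups(self) -> int:
        t = self.total
        return t.known_groups + t.predicted_groups


def summarize(assignments: Sequence[NpCladeAssignment]) -> ClassificationSummary:
    """Tally assignments per major clade.

    Groups are distinct NP-clade labels observed with the corresponding
    status; BGC counts tally every assignment exactly once.  Assignments
    whose major clade is not one of Ia/Ib/II/III are collected under an
    "other" row (present only when non-empty)."""
    summary = ClassificationSummary(
        rows={c: CladeRow(clade=c) for c in C.MAJOR_CLADES})
    groups: dict[tuple[str, str], set[str]] = {}
    for a in assignments:
        clade = a.major_clade if a.major_clade in C.MAJOR_CLADES else "other"
        if clade not in summary.rows:
            summary.rows[clade] = CladeRow(clade=clade)
        row = summary.rows[clade]
        if a.status == "known":
            row.known_bgcs += 1
            groups.setdefault((clade, "known"), set()).add(a.np_clade)
        elif a.status == "predicted":
            row.predicted_bgcs += 1
            groups.setdefault((clade, "predicted"), set()).add(a.np_clade)
        else:
            row.unclassified_bgcs += 1
    for (clade, status), labels in groups.items():
        if status == "known":
            summary.rows[clade].known_groups = len(labels)
        else:
            summary.rows[clade].predicted_groups = len(labels)
    return summary


def estimate_chemical_space(summary: ClassificationSummary,
                            thresholds: Thresholds = Thresholds()) -> int:
    """(known groups + predicted groups) x derivatives-per-group."""
    return summary.total_groups * thresholds.derivatives_per_group


def summary_to_tsv(summary: ClassificationSummary, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("clade\tknown_groups\tknown_bgcs\tknown_pct\t"
                 "predicted_groups\tpredicted_bgcs\tpredicted_pct\t"
                 "unclassified_bgcs\tunclassified_pct\ttotal_bgcs\n")
        ordered = [summary.rows[c] for c in C.MAJOR_CLADES
                   if c in summary.rows]
        ordered += [r for c, r in sorted(summary.rows.items())
                    if c not in C.MAJOR_CLADES]
        for row in ordered + [summary.total]:
            fh.write(
                f"{row.clade}\t{row.known_groups}\t{row.known_bgcs}\t"
                f"{row.percent('known')}\t{row.predicted_groups}\t"
                f"{row.predicted_bgcs}\t{row.percent('predicted')}\t"
                f"{row.unclassified_bgcs}\t{row.percent('unclassified')}\t"
                f"{row.total_bgcs}\n")


def summary_to_text(summary: ClassificationSummary,
                    thresholds: Thresholds = Thresholds()) -> str:
    lines = [
        f"{'Clade':<8}{'Known groups':>22}{'Predicted groups':>22}"
        f"{'Not classified':>18}",
    ]
    ordered = [summary.rows[c] for c in C.MAJOR_CLADES if c in summary.rows]
    ordered += [r for c, r in sorted(summary.rows.items())
                if c not in C.MAJOR_CLADES]
    for row in ordered + [summary.total]:
        lines.append(
            f"{row.clade:<8}"
            f"{row.known_groups:>4} ({row.percent('known'):>3}%, "
            f"{row.known_bgcs:>4})"
            f"{row.predicted_groups:>6} ({row.percent('predicted'):>3}%, "
            f"{row.predicted_bgcs:>4})"
            f"{'':>6}({row.percent('unclassified'):>3}%, "
            f"{row.unclassified_bgcs:>4})")
    est = estimate_chemical_space(summary, thresholds)
    lines.append("")
    lines.append(f"Classified BGCs: {summary.classified_bgcs} in "
                 f"{summary.total_groups} NP groups")
    lines.append(f"Estimated chemical space: ~{est} natural products "
                 f"({thresholds.derivatives_per_group} derivatives/group)")
    return "\n".join(lines)


def write_assignments(assignments: Iterable[NpCladeAssignment], path) -> None:
    with Path(path).open("w") as fh:
        fh.write("bgc_id\tmajor_clade\tnp_clade\tstatus\tscaffold\tring\t"
                 "nearest_reference\tlevel1_consistent\tevidence\n")
        for a in sorted(assignments, key=lambda a: a.bgc_id):
            fh.write(f"{a.bgc_id}\t{a.major_clade}\t{a.np_clade}\t{a.status}"
                     f"\t{a.scaffold}\t{a.ring}\t{a.nearest_reference}\t"
                     f"{'yes' if a.level1_consistent else 'no'}\t"
                     f"{a.evidence}\n")


def read_assignments(path) -> list[NpCladeAssignment]:
    out: list[NpCladeAssignment] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(NpCladeAssignment(
                bgc_id=row["bgc_id"], major_clade=row["major_clade"],
                np_clade=row["np_clade"], status=row["status"],
                scaffold=row["scaffold"], ring=row["ring"],
                evidence=row.get("evidence", ""),
                level1_consistent=row.get("level1_consistent", "yes") == "yes",
                nearest_reference=row.get("nearest_reference", "")))
    return out
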
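"""Hierarchical natural-product-clade classification.

Level I reads the putative Knoevenagelase (pKN) signal against the tree
placement: clades Ia/Ib lack pKN (tetramic-acid route, core I), clade II
carries it (pyrrolinone route, core II), clade III mixes both.  Level II
matches the BGC's modification-enzyme profile against the packaged
decision table of 18 known NP-clade rules; BGCs matching no rule fall back
to a predicted-clade neighborhood (11 labels) or "unclassified".  The core
scaffold and ring annotations follow from the matched rule and the DAase
subtype found in the cluster.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import constants as C
from .align import local_alignment_stats
from .errors import ValidationError
from .io import ProteinRecord


# ---------------------------------------------------------------------------
# Diels-Alderase typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DaaseReference:
    """A packaged reference DAase with its subclade label."""

    record: ProteinRecord
    subclade: str  # one of constants.DAASE_SUBCLADES

    def __post_init__(self) -> None:
        if self.subclade not in C.DAASE_SUBCLADES:
            raise ValidationError(
                f"DAase reference {self.record.id!r}: unknown subclade "
                f"{self.subclade!r}"
            )

    @property
    def major_type(self) -> str:
        return C.daase_type(self.subclade)


@dataclass(frozen=True)
class DaaseAssignment:
    gene_id: str
    major_type: str           # typeI / typeII / unknown
    subclade: str             # Iα / Iβ / IIα / IIβ-1 / IIβ-2 / unknown
    sam_motif_present: bool
    nearest_reference: str
    best_identity: float
    conflict: bool = False    # motif type and best-reference type disagree


def classify_daase(candidates: Sequence[tuple[str, ProteinRecord]],
                   references: Sequence[DaaseReference],
                   motif_model,
                   min_identity: float = 40.0,
                   min_query_coverage: float = 0.5) -> list[DaaseAssignment]:
    """Type candidate DAases by SAM-motif presence and nearest reference.

    The SAM-binding motif defines the major type (type I iff present); the
    subclade is the label of the best-identity reference *of that type*.
    When the overall best reference belongs to the other type the subclade
    is left unknown and the conflict is flagged.
    """
    if not references:
        raise ValidationError("classify_daase requires a non-empty reference set")
    out: list[DaaseAssignment] = []
    for gene_id, record in candidates:
        sam = motif_model.best_score(record.sequence) > motif_model.threshold
        per_ref: dict[str, float] = {}
        for ref in references:
            st = local_alignment_stats(ref.record, record)
            if st.query_coverage >= min_query_coverage:
                per_ref[ref.record.id] = st.identity
        sub_by_ref = {r.record.id: r.subclade for r in references}
        usable = {rid: ident for rid, ident in per_ref.items()
                  if ident > min_identity}
        if not usable:
            out.append(DaaseAssignment(
                gene_id=gene_id,
                major_type="typeI" if sam else "unknown",
                subclade="unknown", sam_motif_present=sam,
                nearest_reference="", best_identity=max(per_ref.values(), default=0.0)))
            continue
        best_ref = max(usable, key=lambda r: (usable[r], r))
        best_type = C.daase_type(sub_by_ref[best_ref])
        major = "typeI" if sam else "typeII"
        if best_type != major:
            out.append(DaaseAssignment(
                gene_id=gene_id, major_type=major, subclade="unknown",
                sam_motif_present=sam, nearest_reference=best_ref,
                best_identity=usable[best_ref], conflict=True))
            continue
        # best reference constrained to the detected major type
        same_type = {rid: ident for rid, ident in usable.items()
                     if C.daase_type(sub_by_ref[rid]) == major}
        best_same = max(same_type, key=lambda r: (same_type[r], r))
        out.append(DaaseAssignment(
            gene_id=gene_id, major_type=major,
            subclade=sub_by_ref[best_same], sam_motif_present=sam,
            nearest_reference=best_same, best_identity=same_type[best_same]))
    return out


# ---------------------------------------------------------------------------
# Decision table
# ---------------------------------------------------------------------------

_FLAG_VALUES = ("present", "absent", "either")


def _validate_me_token(token: str) -> None:
    cat, _, subtype = token.partition(":")
    if cat not in C.ME_CATEGORIES:
        raise ValidationError(f"decision table references undefined "
                              f"modification-enzyme category {cat!r}")
    if subtype and cat != "DAase":
        raise ValidationError(f"subtype {subtype!r} only allowed on DAase, "
                              f"got token {token!r}")
    if subtype and subtype not in C.DAASE_SUBCLADES + ("I", "II", "IIβ"):
        raise ValidationError(f"unknown DAase subtype {subtype!r}")


@dataclass(frozen=True)
class DecisionRule:
    """One known NP-clade row of the key-modification-enzyme table."""

    np_clade: str
    level1_clade: str
    kn_required: str           # present / absent
    ter_required: str          # present / absent / either
    required_mes: frozenset[str]
    forbidden_mes: frozenset[str]
    scaffold: str
    representative_np: str

    def __post_init__(self) -> None:
        if self.level1_clade not in C.MAJOR_CLADES:
            raise ValidationError(f"rule {self.np_clade}: bad level-1 clade "
                                  f"{self.level1_clade!r}")
        if self.kn_required not in ("present", "absent"):
            raise ValidationError(f"rule {self.np_clade}: bad kn flag")
        if self.ter_required not in _FLAG_VALUES:
            raise ValidationError(f"rule {self.np_clade}: bad t-ER flag")
        if self.required_mes & self.forbidden_mes:
            raise ValidationError(
                f"rule {self.np_clade}: required and forbidden sets overlap")
        for token in self.required_mes | self.forbidden_mes:
            _validate_me_token(token)
        if self.scaffold not in C.SCAFFOLDS:
            raise ValidationError(f"rule {self.np_clade}: unknown scaffold "
                                  f"{self.scaffold!r}")

    @property
    def specificity(self) -> int:
        return len(self.required_mes)


@dataclass(frozen=True)
class DecisionTable:
    rules: tuple[DecisionRule, ...]
    predicted_labels: tuple[str, ...]
    predicted_level1: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.np_clade for r in self.rules] + list(self.predicted_labels)
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValidationError(
                f"decision table has duplicate clade labels: {sorted(dupes)}")

    @property
    def known_labels(self) -> tuple[str, ...]:
        return tuple(r.np_clade for r in self.rules)

    def rule_for(self, np_clade: str) -> Optional[DecisionRule]:
        for r in self.rules:
            if r.np_clade == np_clade:
                return r
        return None


def load_decision_table(path=None) -> DecisionTable:
    """Load the packaged decision table, or a user-edited TSV copy.

    The packaged table holds the 18 known NP-clade rules and the 11
    predicted clade labels (which carry no enzyme rule and are assigned by
    tree neighborhood only).
    """
    if path is None:
        ref = resources.files("pksnrps").joinpath("data/decision_table.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["np_clade", "level1_clade", "status", "kn_required",
                "ter_required", "required_mes", "forbidden_mes", "scaffold",
                "representative_np"]
    if header != expected:
        raise ValidationError(
            f"decision table header mismatch: got {header!r}")
    rules: list[DecisionRule] = []
    predicted: list[str] = []
    predicted_level1: dict[str, str] = {}
    for ln in lines[1:]:
        cols = ln.split("\t")
        cols += [""] * (len(expected) - len(cols))
        (np_clade, level1, status, kn, ter, req, forb, scaffold, rep) = cols
        if status == "predicted":
            predicted.append(np_clade)
            predicted_level1[np_clade] = level1
            continue
        if status != "known":
            raise ValidationError(f"decision table row {np_clade!r}: "
                                  f"unknown status {status!r}")
        rules.append(DecisionRule(
            np_clade=np_clade, level1_clade=level1, kn_required=kn,
            ter_required=ter,
            required_mes=frozenset(t for t in req.split(",") if t),
            forbidden_mes=frozenset(t for t in forb.split(",") if t),
            scaffold=scaffold, representative_np=rep))
    return DecisionTable(rules=tuple(rules), predicted_labels=tuple(predicted),
                         predicted_level1=predicted_level1)


# ---------------------------------------------------------------------------
# Level I
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Level1Result:
    clade: str           # Ia / Ib / II / III / undetermined
    consistent: bool
    tentative: bool = False
    note: str = ""


def level1_classify(profile, major_clade_from_tree: str) -> Level1Result:
    """Combine tree placement with the pKN presence check.

    Tree placement is primary; the pKN signal is a consistency check.
    Ia/Ib expect pKN absent, II expects pKN present, III accepts both.  An
    inconsistency is recorded, never silently overridden.  Unplaced hybrids
    fall back to the pKN signal alone (tentative II) or "undetermined".
    """
    pkn = profile.present("pKN")
    if major_clade_from_tree in ("Ia", "Ib"):
        ok = not pkn
        return Level1Result(major_clade_from_tree, ok,
                            note="" if ok else "pKN present in a core-I clade")
    if major_clade_from_tree == "II":
        ok = pkn
        return Level1Result("II", ok,
                            note="" if ok else "pKN absent in clade II")
    if major_clade_from_tree == "III":
        return Level1Result("III", True)  # mixed clade: both states admissible
    if pkn:
        return Level1Result("II", True, tentative=True,
                            note="unplaced; pKN present")
    return Level1Result("undetermined", True, note="unplaced; pKN absent")


# ---------------------------------------------------------------------------
# Level II
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NpCladeAssignment:
    bgc_id: str
    major_clade: str
    np_clade: str            # known label, predicted label, or "unclassified"
    status: str              # known / predicted / unclassified
    scaffold: str
    ring: str
    evidence: str
    level1_consistent: bool = True
    nearest_reference: str = ""


def _token_satisfied(token: str, categories_present: set[str],
                     daase_subclades: set[str]) -> bool:
    cat, _, subtype = token.partition(":")
    if cat == "DAase":
        return any(C.daase_subclade_matches(subtype, s)
                   for s in daase_subclades)
    return cat in categories_present


def _rule_matches(rule: DecisionRule, level1: Level1Result, profile,
                  daase_subclades: set[str]) -> bool:
    if rule.level1_clade != level1.clade:
        return False
    if (rule.kn_required == "present") != profile.present("pKN"):
        return False
    if rule.ter_required != "either":
        if (rule.ter_required == "present") != profile.present("tER"):
            return False
    cats = profile.present_categories()
    for token in rule.required_mes:
        if not _token_satisfied(token, cats, daase_subclades):
            return False
    for token in rule.forbidden_mes:
        if _token_satisfied(token, cats, daase_subclades):
            return False
    return True


def level2_classify(profile, daase: Sequence[DaaseAssignment],
                    level1: Level1Result, table: DecisionTable,
                    placement=None) -> NpCladeAssignment:
    """Assign the BGC to an NP clade via the decision table.

    The most specific matching rule (largest required set) wins; remaining
    ties break by tree proximity of the hybrid to each rule's
    representative reference, then lexicographically.  The sparse Ib-D rule
    (empty enzyme signature) is accepted only when the hybrid's nearest
    reference neighborhood is Ib-D itself.  With no matching rule the BGC
    is labelled with the nearest predicted-clade neighborhood, if any, else
    "unclassified".
    """
    daase_subclades = {a.subclade for a in daase
                       if a.subclade in C.DAASE_SUBCLADES}
    nearest_np = getattr(placement, "nearest_np_clade", "") if placement else ""
    nearest_ref = getattr(placement, "nearest_reference", "") if placement else ""
    ref_dist = getattr(placement, "reference_distances", {}) if placement else {}

    evidence_bits = [
        f"level1={level1.clade}"
        + ("(tentative)" if level1.tentative else "")
        + ("" if level1.consistent else f"; WARN {level1.note}"),
        "MEs=" + (",".join(sorted(profile.present_categories())) or "none"),
        "DAase=" + (",".join(sorted(daase_subclades)) or "none"),
    ]

    candidates = []
    if level1.clade in C.MAJOR_CLADES:
        for rule in table.rules:
            if not _rule_matches(rule, level1, profile, daase_subclades):
                continue
            if rule.np_clade == "Ib-D" and nearest_np != "Ib-D":
                continue  # sparse-profile sink guard: require tree support
            candidates.append(rule)

    if candidates:
        top = max(r.specificity for r in candidates)
        finalists = [r for r in candidates if r.specificity == top]
        if len(finalists) > 1 and ref_dist:
            def rep_distance(rule: DecisionRule) -> float:
                rid = reference_id_for_clade(rule.np_clade)
                return ref_dist.get(rid, float("inf"))
            best_d = min(rep_distance(r) for r in finalists)
            finalists = [r for r in finalists if rep_distance(r) == best_d]
        winner = min(finalists, key=lambda r: r.np_clade)
        scaffold, ring = predict_scaffold_parts(winner.np_clade,
                                                winner.scaffold, profile,
                                                daase_subclades)
        evidence_bits.insert(0, f"rule={winner.np_clade} "
                                f"({winner.representative_np})")
        return NpCladeAssignment(
            bgc_id=profile.bgc_id, major_clade=level1.clade,
            np_clade=winner.np_clade, status="known", scaffold=scaffold,
            ring=ring, evidence="; ".join(evidence_bits),
            level1_consistent=level1.consistent, nearest_reference=nearest_ref)

    if nearest_np in table.predicted_labels:
        scaffold, ring = predict_scaffold_parts(nearest_np, None, profile,
                                                daase_subclades)
        evidence_bits.insert(0, f"predicted neighborhood={nearest_np}")
        return NpCladeAssignment(
            bgc_id=profile.bgc_id, major_clade=level1.clade,
            np_clade=nearest_np, status="predicted", scaffold=scaffold,
            ring=ring, evidence="; ".join(evidence_bits),
            level1_consistent=level1.consistent, nearest_reference=nearest_ref)

    scaffold, ring = predict_scaffold_parts("unclassified", None, profile,
                                            daase_subclades)
    evidence_bits.insert(0, "no rule matched")
    return NpCladeAssignment(
        bgc_id=profile.bgc_id, major_clade=level1.clade,
        np_clade="unclassified", status="unclassified", scaffold=scaffold,
        ring=ring, evidence="; ".join(evidence_bits),
        level1_consistent=level1.consistent, nearest_reference=nearest_ref)


def reference_id_for_clade(np_clade: str) -> str:
    """Leaf id of the packaged reference hybrid anchoring an NP clade."""
    safe = (np_clade.replace("-", "_").replace("α", "alpha")
            .replace("β", "beta").replace("γ", "gamma")
            .replace("δ", "delta").replace("ε", "epsilon"))
    return f"REF_{safe}"


# ---------------------------------------------------------------------------
# Scaffold prediction
# ---------------------------------------------------------------------------

def predict_scaffold_parts(np_clade: str, rule_scaffold: Optional[str],
                           profile, daase_subclades: set[str]) -> tuple[str, str]:
    """Core scaffold + ring annotation from the clade label and ME profile.

    pKN absent -> core-I tetramic acid (single Dieckmann cyclization by the
    DKC domain); pKN present -> core-II pyrrolinone (reductive release then
    Knoevenagel condensation).  An expandase converts the tetramic acid to
    a 2-pyridone; clade III-B overrides to a tetronic acid.  Ring
    annotations follow the DAase subtype: IIα/IIβ-2 decalin, IIβ-1
    macrocycle, Iα/Iβ pyridone polycycle.
    """
    if np_clade == "III-B" or rule_scaffold == "tetronic_acid":
        scaffold = "tetronic_acid"
    elif profile.present("expandase_P450"):
        scaffold = "2-pyridone"
    elif profile.present("pKN"):
        scaffold = "pyrrolinone"
    else:
        scaffold = "tetramic_acid"

    if daase_subclades & {"IIα", "IIβ-2"}:
        ring = "decalin"
    elif "IIβ-1" in daase_subclades:
        ring = "macrocycle"
    elif daase_subclades & {"Iα", "Iβ"}:
        ring = "pyridone_polycycle"
    else:
        ring = "none"
    return scaffold, ring


def predict_scaffold(assignment: NpCladeAssignment, profile,
                     daase: Sequence[DaaseAssignment] = ()) -> tuple[str, str]:
    """Pure (np_clade, profile) -> (scaffold, ring) mapping."""
    subclades = {a.subclade for a in daase if a.subclade in C.DAASE_SUBCLADES}
    return predict_scaffold_parts(assignment.np_clade, None, profile, subclades)
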
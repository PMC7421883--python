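"""Controlled vocabularies: modification-enzyme categories, clade labels,
Diels-Alderase subclades, Pfam domain accessions."""

# Pfam accessions used for the hybrid screen: ketosynthase, acyltransferase,
# condensation.
PFAM_KS = "PF00109"
PFAM_AT = "PF00698"
PFAM_C = "PF00668"

# Domain-block order of a fungal PKS-NRPS hybrid: iterative HR-PKS module
# (KS-AT-DH-CMeT-ER/ER0-KR-ACP) fused to an NRPS module (C-A-T) with a
# terminal off-loading domain (DKC or R).
HYBRID_DOMAIN_ORDER = ("KS", "AT", "DH", "CMeT", "ER", "KR", "ACP",
                       "C", "A", "T", "DKC")

# Closed set of modification-enzyme categories used by the decision table.
ME_CATEGORIES = (
    "expandase_P450",   # ring-expanding P450: tetramic acid -> 2-pyridone
    "pKN",              # putative Knoevenagelase (alpha/beta-hydrolase)
    "tER",              # trans-acting enoylreductase
    "FMO",
    "P450_Ia",
    "P450_Ib",
    "P450_IIA",
    "P450_IIB",
    "P450_IID",
    "P450_III",
    "PT",               # prenyltransferase
    "reductase",
    "aldolase",
    "transaminase",
    "MT",               # methyltransferase
    "monooxygenase",
    "alphaKG",          # alpha-ketoglutarate-dependent oxygenase
    "DAase",            # Diels-Alderase (typed separately by subclade)
    "glycosyltransferase",
)

MAJOR_CLADES = ("Ia", "Ib", "II", "III")

# The 18 natural-product clades anchored by characterized BGCs.
KNOWN_CLADES = (
    "Ia-A", "Ia-B", "Ia-C", "Ia-D-1", "Ia-D-2", "Ia-D-3",
    "Ib-A", "Ib-B", "Ib-C", "Ib-D",
    "II-A", "II-B", "II-C", "II-D",
    "III-A", "III-B", "III-C", "III-D",
)

# The 11 predicted (functionally uncharacterized) clade labels, assigned by
# tree neighborhood only.
PREDICTED_CLADES = (
    "Ia-α", "Ia-β", "Ia-γ", "Ia-δ", "Ia-ε",
    "Ib-α", "Ib-β", "Ib-γ",
    "II-α", "II-β", "II-γ",
)

# Diels-Alderase subclades and their packaged reference enzymes.  Type I
# (SAM-binding motif) covers Iα/Iβ; type II covers IIα (no ring system
# assigned), IIβ-1 (macrocycle-forming) and IIβ-2 (decalin-forming).
DAASE_SUBCLADES = ("Iα", "Iβ", "IIα", "IIβ-1", "IIβ-2")
DAASE_REFERENCE_NAMES = {
    "Iα": ("LepI",),
    "Iβ": ("IccD",),
    "IIα": ("EqxF", "Fsa2", "Phm7", "Tas3"),
    "IIβ-1": ("CcsF", "CHGG_01241"),
    "IIβ-2": ("PoxQ", "MycB"),
}

SCAFFOLDS = ("tetramic_acid", "pyrrolinone", "2-pyridone", "tetronic_acid",
             "undetermined")
RING_ANNOTATIONS = ("decalin", "macrocycle", "pyridone_polycycle", "none")


def daase_type(subclade: str) -> str:
    """Major DAase type implied by a subclade label."""
    if subclade in ("Iα", "Iβ"):
        return "typeI"
    if subclade in ("IIα", "IIβ-1", "IIβ-2"):
        return "typeII"
    return "unknown"


def daase_subclade_matches(required: str, observed: str) -> bool:
    """Whether an observed DAase subclade satisfies a required subtype token.

    Tokens may name a subclade exactly ("Iα", "IIβ-1"), a subclade family
    ("IIβ" matches IIβ-1 and IIβ-2; "I"/"II" match their whole type), or be
    empty (any DAase).
    """
    if observed not in DAASE_SUBCLADES:
        return False
    if not required:
        return True
    if required in DAASE_SUBCLADES:
        return observed == required
    if required == "IIβ":
        return observed in ("IIβ-1", "IIβ-2")
    if required == "I":
        return observed in ("Iα", "Iβ")
    if required == "II":
        return observed in ("IIα", "IIβ-1", "IIβ-2")
    return False
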
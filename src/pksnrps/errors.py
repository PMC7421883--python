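"""Exception hierarchy shared across the pipeline stages."""


class PksNrpsError(Exception):
    """Base class for all package errors."""


class ParseError(PksNrpsError):
    """Malformed input file (FASTA, GFF3, Newick, TSV)."""


class ValidationError(PksNrpsError):
    """Input violates a documented invariant (duplicate ids, bad coordinates,
    inconsistent reference bundle, undefined decision-table category)."""


class ConfigError(PksNrpsError):
    """Invalid run configuration or thresholds."""


class UndefinedDistanceError(PksNrpsError):
    """Pairwise distance requested for a pair with no comparable columns."""
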
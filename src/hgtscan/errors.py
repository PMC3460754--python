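"""Exception hierarchy shared by all stages."""


class HgtscanError(Exception):
    """Base class for all package errors."""


class FormatError(HgtscanError):
    """A file violated its declared format (FASTA, newick, TSV)."""


class ValidationError(HgtscanError):
    """Well-formed input violated a semantic invariant."""
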
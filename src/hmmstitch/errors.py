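"""Exception hierarchy."""


class HmmstitchError(Exception):
    """Base class for all errors raised by hmmstitch."""


class SequenceFormatError(HmmstitchError, ValueError):
    """Malformed FASTA input or illegal residue symbols."""


class AlignmentError(HmmstitchError, ValueError):
    """Violated alignment invariants (ragged rows, bad flags, ...)."""


class TreeError(HmmstitchError, ValueError):
    """Malformed Newick or tree/leaf-set inconsistencies."""


class ConfigError(HmmstitchError, ValueError):
    """Invalid run configuration."""
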
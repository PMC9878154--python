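"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation/configuration problems exit 2,
data-consistency problems exit 3.
"""


class SweepMethError(Exception):
    """Base class for all package errors."""


class FormatError(SweepMethError):
    """Malformed input file (FASTA/GFF3/VCF/cytosine report)."""


class ValidationError(SweepMethError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataConsistencyError(SweepMethError):
    """Inputs contradict each other, e.g. VCF REF vs reference base (exit 3)."""
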
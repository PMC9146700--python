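"""Exception types shared across the pipeline stages."""


class MitotrioError(Exception):
    """Base class for package errors."""


class ParseError(MitotrioError):
    """A GenBank/FASTA record could not be parsed; the message names the line."""


class IntegrityError(MitotrioError):
    """A biological consistency check failed (e.g. internal stop codon)."""


class AnchorError(MitotrioError):
    """No rotation anchor could be seeded between two circular sequences."""


class BandError(MitotrioError):
    """The optimal alignment path escaped the band even at the band cap."""


class SaturationError(MitotrioError):
    """A distance is undefined because the observed divergence is saturated."""
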
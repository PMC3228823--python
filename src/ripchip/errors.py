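"""Exception hierarchy shared across the pipeline."""


class RipChipError(Exception):
    """Base class for all ripchip-specific errors."""


class FormatError(RipChipError, ValueError):
    """An input file violates its declared schema (missing column, bad value)."""


class DegenerateProfileError(RipChipError, ValueError):
    """The background enrichment distribution has zero spread (SD = 0)."""


class BackgroundTooSmallError(RipChipError, ValueError):
    """Too few genes survive filtering to estimate the background distribution.

    Consumed by the perturbation layer, where a detectable mRNA over an
    uncomputable background is reported with the code "P".
    """

    def __init__(self, n_genes: int, min_background: int):
        self.n_genes = n_genes
        self.min_background = min_background
        super().__init__(
            f"only {n_genes} genes in profile; at least {min_background} "
            "required to estimate the background distribution"
        )


class GeneNotOnArrayError(RipChipError, KeyError):
    """The requested gene has no probes on the array design (distinct from ND)."""


class ConfigError(RipChipError, ValueError):
    """Invalid pipeline or simulation configuration."""
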
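"""Exception hierarchy shared across the package."""


class TlsigError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TlsigError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(TlsigError):
    """Parsed data violates a domain invariant (e.g. negative TPM)."""


class SpecError(TlsigError):
    """A simulation or analysis specification is self-inconsistent."""


class CollinearityError(TlsigError):
    """Design matrix is rank deficient; carries the offending covariates."""

    def __init__(self, covariates, message=None):
        self.covariates = list(covariates)
        super().__init__(
            message or f"collinear covariates: {', '.join(self.covariates)}"
        )
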
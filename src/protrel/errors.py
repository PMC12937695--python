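"""Exception hierarchy shared across the package."""


class ProtrelError(Exception):
    """Base class for all package errors."""


class InputError(ProtrelError):
    """User-facing input problem (bad file, too few proteins, duplicates)."""


class BundleError(ProtrelError):
    """Annotation bundle is missing data or internally inconsistent."""


class UnmappableSequenceError(ProtrelError):
    """A supplied custom sequence cannot be located in the canonical one."""

    def __init__(self, accession: str, detail: str = ""):
        self.accession = accession
        msg = f"unmappable custom sequence for {accession}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class AlignerUnavailableError(ProtrelError):
    """A requested external alignment binary is not on PATH."""


class ConfigError(ProtrelError):
    """A bundled data asset or configuration file is malformed."""


class ParameterError(ProtrelError):
    """Fixture-generator parameters are infeasible."""
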
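"""Exception hierarchy shared by all dgrpkit modules."""


class DgrpkitError(Exception):
    """Base class for all errors raised by dgrpkit."""


class MalformedIdentifierError(DgrpkitError):
    """A line identifier could not be parsed into a DGRP line number."""


class TableFormatError(DgrpkitError):
    """A phenotype/genotype/covariate table violates the expected layout."""


class ConfigError(DgrpkitError):
    """An invalid simulation or analysis configuration."""


class InsufficientDataError(DgrpkitError):
    """Too few observations to run the requested computation."""


class OverlapError(InsufficientDataError):
    """Fewer shared lines than the configured minimum overlap."""


class DegeneratePhenotypeError(DgrpkitError):
    """A phenotype with no variation (all values identical)."""


class MonomorphicVariantError(DgrpkitError):
    """A variant with a single genotype among the usable lines."""


class LookupError_(DgrpkitError):
    """A referenced study/phenotype/variant does not exist."""


class EmptySelectionError(DgrpkitError):
    """A filter removed every phenotype or record."""
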
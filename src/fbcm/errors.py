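"""Exception types shared across the package."""


class InvalidGenotypeError(ValueError):
    """A genotypic score lies outside {0, 1, 2}."""


class DimensionError(ValueError):
    """Array arguments have incompatible shapes."""


class MissingDataError(ValueError):
    """Required data are entirely missing (e.g. an all-missing locus)."""


class NonInformativeGeneError(RuntimeError):
    """The gene carries no transmission deviation, so the model has nothing
    to fit.  Callers performing a genome scan should treat this as a skip
    signal rather than a failure."""


class ConvergenceDiagnosticError(ValueError):
    """A convergence diagnostic was requested on inputs where it is
    undefined (e.g. R-hat with a single chain)."""
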
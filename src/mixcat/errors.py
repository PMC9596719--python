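"""Exception hierarchy for mixcat."""

from __future__ import annotations


class MixcatError(Exception):
    """Base class for all mixcat errors."""


class DegeneratePartitionError(MixcatError):
    """All category means are equal (between-category variation is zero),
    so the loss is undefined for this partition."""


class InfeasibleKError(MixcatError):
    """The requested number of categories cannot be formed from the data
    (too few distinct values, or too few observations)."""


class NoCandidateError(MixcatError):
    """No admissible boundary position exists for a further split
    (single-valued categories, or the minimum-size constraint excludes
    every candidate)."""


class ConfigurationError(MixcatError):
    """Inconsistent or invalid run configuration."""


class CollinearityError(MixcatError):
    """Rank-deficient design matrix.

    Attributes
    ----------
    columns : list of str
        Names of the columns implicated in the linear dependency.
    """

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = list(columns or [])


class ConvergenceError(MixcatError):
    """A likelihood fit failed to converge (e.g. separation in a logistic
    model).

    Attributes
    ----------
    diagnostics : dict
        Optimizer diagnostics available at failure time.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})


class BootstrapError(MixcatError):
    """Too many bootstrap resamples failed to produce an estimate."""


class InputError(MixcatError):
    """Malformed input table (non-numeric cells, missing columns, ...)."""
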
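"""Exception hierarchy.

All configuration problems raise :class:`ConfigError`, malformed or
inconsistent data raise :class:`DataError`, and statistical procedures that
cannot produce a valid answer raise :class:`EstimationError` or
:class:`FitFailureError`.  Everything derives from :class:`SatkitError` so
callers can catch the package's errors with one clause.
"""


class SatkitError(Exception):
    """Base class for all satkit errors."""


class ConfigError(SatkitError, ValueError):
    """An invalid configuration value or violated design invariant."""


class DataError(SatkitError, ValueError):
    """Malformed, incomplete or inconsistent input data."""


class ComparisonError(SatkitError, ValueError):
    """Model-comparison requested between incomparable fits."""


class FitFailureError(SatkitError, RuntimeError):
    """Every optimization run failed; carries the per-run log."""

    def __init__(self, message, run_log=None):
        super().__init__(message)
        self.run_log = run_log or []


class EstimationError(SatkitError, RuntimeError):
    """A statistical estimate could not be computed (e.g. singular model)."""
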
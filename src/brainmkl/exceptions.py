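"""Exception hierarchy for brainmkl.

All package-raised errors derive from :class:`BrainMKLError` so callers can
catch the package's failures with a single except clause while still
distinguishing user-input faults from solver faults.
"""


class BrainMKLError(Exception):
    """Base class for all brainmkl errors."""


class InputError(BrainMKLError, ValueError):
    """Invalid data passed to an operation (shapes, ranges, degenerate input)."""


class ConfigError(BrainMKLError, ValueError):
    """Invalid configuration (unknown keys, out-of-range parameters, empty grids)."""


class ParseError(BrainMKLError, ValueError):
    """A file on disk could not be parsed; message carries the line number."""


class CompatibilityError(BrainMKLError, ValueError):
    """Two artifacts (model vs. cohort, report vs. report) do not share the
    same region table or modality set."""


class SolverError(BrainMKLError, RuntimeError):
    """The dual solver failed to converge; message reports the final KKT
    violation."""


class StratificationError(BrainMKLError, ValueError):
    """A cross-validation fold lost one of the two classes."""


class UndefinedMetricError(BrainMKLError, ValueError):
    """A requested metric has an empty denominator (no positive or no
    negative truth instances)."""
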
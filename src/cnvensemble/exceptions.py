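"""Exception hierarchy for cnvensemble.

All toolkit errors derive from :class:`CnvEnsembleError` so callers can
catch one base class; the CLI maps the subclasses to distinct exit codes.
"""


class CnvEnsembleError(Exception):
    """Base class for all cnvensemble errors."""


class ValidationError(CnvEnsembleError, ValueError):
    """An in-memory object violates a structural invariant."""


class ConfigError(CnvEnsembleError, ValueError):
    """A configuration value or combination of values is invalid."""


class InputError(CnvEnsembleError, ValueError):
    """An input file is missing, malformed, or inconsistent with the request."""
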
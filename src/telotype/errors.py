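"""Exception hierarchy.

The CLI maps :class:`InputError` to exit code 2 and :class:`ConfigError`
to exit code 3; everything else is a plain failure.
"""


class TelotypeError(Exception):
    """Base class for all telotype errors."""


class InputError(TelotypeError):
    """Malformed or insufficient input data (bad characters, empty streams,
    undefined ratios, missing required fields)."""


class ConfigError(TelotypeError):
    """Invalid configuration (nonsensical thresholds, unknown rule names)."""


class DegenerateFitError(TelotypeError):
    """A model fit collapsed (e.g. a mixture component with vanishing
    variance or weight) and its output cannot be trusted."""
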
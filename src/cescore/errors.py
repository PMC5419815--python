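"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 1,
:class:`ConfigError` -> 2.
"""


class CescoreError(Exception):
    """Base class for all errors raised by cescore."""


class InputError(CescoreError):
    """Malformed or inconsistent input data (panel rows, mortality tables, values)."""


class ConfigError(CescoreError):
    """Invalid model configuration (indicator schema, unknown indicator names)."""
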
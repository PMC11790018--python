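"""Package-wide exception types.

``ConfigError`` and ``SchemaError`` both derive from ``ValueError`` so that
callers who do not care about the distinction can catch a single type; the
CLI maps them to exit code 2 (validation failure) while any other exception
is a runtime failure (exit code 1).
"""


class ConfigError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(ValueError):
    """An input table violating its schema; the message names file/column/row."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
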
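"""Exception types shared across the pipeline.

The CLI maps these onto exit codes: configuration problems exit 2,
input-format problems exit 3, any other stage failure exits 4.
"""


class ConfigError(Exception):
    """A run configuration is missing, malformed, or out of range."""


class InputFormatError(ValueError):
    """An input file exists but cannot be parsed under its declared format."""
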
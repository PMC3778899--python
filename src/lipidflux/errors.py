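"""Exception hierarchy.

Configuration errors (bad parameters, unknown species keys, schema
violations) and data errors (malformed or missing input files) are kept
distinct so the command-line layer can map them to distinct exit codes.
"""


class LipidfluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LipidfluxError):
    """Invalid configuration: unknown keys, bad parameter values, missing anchors."""


class DataError(LipidfluxError):
    """Invalid input data: malformed rows, missing files, rejected samples."""
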
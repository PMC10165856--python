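"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so shell pipelines can tell a
malformed run configuration apart from a malformed input file or a
statistical precondition failure.
"""


class HaschseqError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(HaschseqError):
    """A run configuration is invalid (missing column mapping, bad option)."""

    exit_code = 2


class InputError(HaschseqError):
    """An input file violates its declared dialect."""

    exit_code = 3


class StatisticsError(HaschseqError):
    """A statistical precondition is not met (e.g. empirical null too small)."""

    exit_code = 4
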
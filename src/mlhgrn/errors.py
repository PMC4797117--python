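"""Exception hierarchy shared across the package."""


class MlhgrnError(Exception):
    """Base class for all package-specific errors."""


class InputError(MlhgrnError, ValueError):
    """Malformed or inconsistent user input (files, identifier sets)."""


class DegenerateInputError(MlhgrnError, ValueError):
    """A data vector is unusable (constant expression, wrong length)."""


class DegenerateConditioningError(MlhgrnError, ValueError):
    """A conditioning correlation has |r| = 1, so the first-order partial
    correlation is undefined (zero denominator)."""


class ConfigurationError(MlhgrnError, ValueError):
    """Invalid run configuration (unknown method name, bad parameter)."""


class LambdaTooLargeError(MlhgrnError, RuntimeError):
    """The sparsity penalty zeroed every coordinate of v; the caller should
    retry with a smaller lambda."""
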
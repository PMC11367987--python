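"""Exception types shared across the package."""


class ScmetabError(Exception):
    """Base class for all package errors."""


class InputError(ScmetabError, ValueError):
    """A data input violates a contract (unknown cells, bad values, missing fields)."""


class ConfigurationError(ScmetabError, ValueError):
    """A configuration value is out of range or a config is internally inconsistent."""


class ConfigValidationError(ConfigurationError):
    """Raised with the full list of validation problems, not just the first.

    Attributes
    ----------
    problems : list of str
        Every violation found in the configuration.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )
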
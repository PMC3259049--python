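"""Exception hierarchy for csrdesign."""


class CSRDesignError(Exception):
    """Base class for all csrdesign errors."""


class InvalidParameterError(CSRDesignError, ValueError):
    """A parameter is outside its valid domain (e.g. non-positive median)."""


class InvalidConfigurationError(CSRDesignError, ValueError):
    """A configuration is internally contradictory (e.g. r_nul >= r_alt)."""


class DegenerateConfigurationError(CSRDesignError, RuntimeError):
    """The simulation cannot make progress (e.g. endless replacement loop)."""


class DesignInfeasibleError(CSRDesignError, RuntimeError):
    """No stopping rule satisfies the requested error constraints."""


class DesignWarning(UserWarning):
    """Non-fatal design issue (e.g. alpha limit unattainable at this size)."""
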
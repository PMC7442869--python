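"""Exception hierarchy shared across crowdkit modules."""


class CrowdkitError(Exception):
    """Base class for all crowdkit errors."""


class ConfigError(CrowdkitError, ValueError):
    """Invalid configuration value (non-positive mean, missing amplitude, ...)."""


class ScheduleError(CrowdkitError, ValueError):
    """Invalid block schedule (overlap, block outside run, ...)."""


class SingularDesignError(CrowdkitError, ValueError):
    """Rank-deficient design matrix; message names the collinear columns."""


class DomainError(CrowdkitError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class IncompleteDesignError(CrowdkitError, ValueError):
    """Within-subject crossing has missing or duplicated cells."""
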
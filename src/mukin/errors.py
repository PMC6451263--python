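"""Exception hierarchy shared by all mukin stages."""


class MukinError(Exception):
    """Base class for all mukin errors."""


class InvalidConfigError(MukinError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(MukinError, ValueError):
    """An input array or argument violates a precondition."""


class CorruptSessionError(MukinError):
    """On-disk session artifacts are missing, truncated or inconsistent."""


class DegenerateInputError(MukinError, ValueError):
    """Input is formally valid but carries no usable information
    (e.g. all channels masked, constant feature matrix)."""


class InsufficientDataError(MukinError, ValueError):
    """Too few observations to estimate the requested quantity."""


class MissingTemplateError(MukinError, KeyError):
    """A spike train refers to a unit with no template in the bank."""


class UnsupportedDesignError(MukinError, ValueError):
    """Session layout does not match the fixed experimental design
    (three trials per degree of freedom)."""


class EmptyPoolError(MukinError, ValueError):
    """No motor units available for an activation pool."""
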
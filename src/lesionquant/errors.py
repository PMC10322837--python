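"""Exception hierarchy for lesionquant.

All pipeline-level failures derive from :class:`LesionQuantError` so callers
can catch one type; the subclasses distinguish bad parameters from bad data.
"""


class LesionQuantError(Exception):
    """Base class for all lesionquant errors."""


class InvalidParameterError(LesionQuantError, ValueError):
    """A configuration value or function argument is out of its valid range."""


class InvalidInputError(LesionQuantError, ValueError):
    """An input image/table is malformed (wrong shape, empty, mismatched)."""


class DegenerateImageError(LesionQuantError, ValueError):
    """The image has no contrast (constant), so a threshold is undefined."""


class SingularBasisError(LesionQuantError, ValueError):
    """Stain absorbance vectors are linearly dependent; unmixing is singular."""


class GenerationError(LesionQuantError, RuntimeError):
    """A simulator could not satisfy its constraints within bounded retries."""


class ConfigError(LesionQuantError, ValueError):
    """A run configuration file is unreadable or names an invalid field."""
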
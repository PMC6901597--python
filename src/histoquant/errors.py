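"""Exception hierarchy.

All package-raised errors derive from :class:`HistoQuantError` so callers can
catch one base class at CLI boundaries.
"""


class HistoQuantError(Exception):
    """Base class for all errors raised by histoquant."""


class FormatError(HistoQuantError):
    """Malformed input file (bad header, missing field, duplicate entry)."""


class HierarchyError(FormatError):
    """Region parent links are cyclic or dangling."""


class DecodeError(FormatError):
    """Atlas-map content cannot be mapped onto the label table."""


class NamingError(HistoQuantError):
    """Section-key extraction from filenames is ambiguous or collides."""


class SizeError(HistoQuantError):
    """An image operation would produce a degenerate (empty) image."""


class TemplateError(HistoQuantError):
    """A rename template does not contain exactly one counter placeholder."""


class CollisionError(HistoQuantError):
    """A rename mapping would send two inputs to the same output."""


class ParameterError(HistoQuantError):
    """A parameter is outside its documented range."""


class GeometryError(HistoQuantError):
    """A pixel coordinate falls outside the image or map it refers to."""


class SpecError(HistoQuantError):
    """A custom-region specification references unknown or overlapping ids."""


class AggregationError(HistoQuantError):
    """Per-section reports being aggregated disagree on region identity."""


class ConfigError(HistoQuantError):
    """A run configuration is missing, unknown, or inconsistent."""


class GenerationError(HistoQuantError):
    """Synthetic-scene generation could not satisfy its constraints."""
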
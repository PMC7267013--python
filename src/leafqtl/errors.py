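"""Exception hierarchy for leafqtl.

All data-dependent failures derive from :class:`LeafQTLError`; argument
misuse raises plain :class:`ValueError` subclasses so callers can keep
using ``except ValueError`` idioms.
"""


class LeafQTLError(Exception):
    """Base class for leafqtl data errors."""


class DegenerateContourError(LeafQTLError):
    """Outline violates the star-shaped precondition of equal-angle resampling."""


class DegenerateShapeError(LeafQTLError):
    """Shape has zero centroid size (all landmarks coincide)."""


class GeometryError(LeafQTLError):
    """Invalid polygon geometry (e.g. self-intersecting contour)."""


class DegenerateDataError(LeafQTLError):
    """Data carry no residual variation, likelihood undefined."""


class UndefinedStatisticError(LeafQTLError):
    """A population-genetic statistic is undefined for these inputs."""


class AliasedTermError(LeafQTLError):
    """A model term is completely confounded with earlier terms."""

    def __init__(self, term: str):
        super().__init__(
            f"model term {term!r} is aliased with preceding terms "
            "(adds no estimable contrasts)"
        )
        self.term = term


class ParseError(LeafQTLError):
    """Malformed input file."""


class PipelineError(LeafQTLError):
    """A pipeline stage failed; the message names the stage."""
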
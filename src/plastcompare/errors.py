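"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`PlastcompareError`, so callers (and
the CLI) can distinguish input/format problems from structural ones.
"""


class PlastcompareError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PlastcompareError):
    """Malformed input file or illegal sequence alphabet."""


class CoordinateError(PlastcompareError):
    """Feature coordinates inconsistent with the genome they annotate."""


class IntegrityError(PlastcompareError):
    """A biological integrity constraint is violated (e.g. CDS length % 3)."""


class CollinearityError(PlastcompareError):
    """The two genomes are not co-linear; anchor chaining failed."""


class StructureError(PlastcompareError):
    """No quadripartite structure (inverted repeat) could be found."""


class SaturationError(PlastcompareError):
    """A substitution-distance correction is undefined (too many changes)."""


class SpecError(PlastcompareError):
    """A synthetic-genome specification is infeasible as stated."""
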
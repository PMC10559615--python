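"""Exception hierarchy shared across genesim modules."""


class GenesimError(Exception):
    """Base class for all genesim errors."""


class OboFormatError(GenesimError, ValueError):
    """The OBO file could not be parsed."""


class CycleError(GenesimError, ValueError):
    """The term graph contains a cycle; message names one member."""


class UnknownTermError(GenesimError, KeyError):
    """A term id is not present in the ontology."""


class AnnotationError(GenesimError, ValueError):
    """A gene has no usable ontology annotations; message names the gene(s)."""


class ClassBalanceError(GenesimError, ValueError):
    """A dataset does not contain both classes, or the minority is too small."""


class StratificationError(GenesimError, ValueError):
    """A class is too small to be split into the requested number of folds."""


class ShapeError(GenesimError, ValueError):
    """Array dimensions do not line up."""


class SpecError(GenesimError, ValueError):
    """A generator or model specification is invalid or unsatisfiable."""
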
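"""Exception hierarchy."""


class MapstratError(Exception):
    """Base class for all package errors."""


class PanelError(MapstratError):
    """A gene symbol outside the 22-gene panel."""


class ParseError(MapstratError):
    """A protein-change string a whitelist rule needs could not be parsed."""


class CurationConflictError(MapstratError):
    """The same variant string carries conflicting pathogenicity labels."""


class ConsistencyError(MapstratError):
    """Inputs that should describe the same cohort disagree."""


class DegenerateInputError(MapstratError):
    """A statistic is undefined on the given input (zero margin, no variance...)."""


class FeasibilityError(MapstratError):
    """A requested odds ratio is outside the Frechet bounds for the marginals."""
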
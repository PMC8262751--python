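"""Exception hierarchy for liprot."""


class LiprotError(Exception):
    """Base class for all liprot errors."""


class ParseError(LiprotError):
    """A coordinate or trajectory file could not be parsed."""


class SolventError(LiprotError):
    """Strict classification found water/ion residues in the input."""


class SystemError_(LiprotError):
    """The topology/trajectory pair does not form a valid analysis system."""


class ParameterError(LiprotError):
    """An analysis parameter is outside its valid range."""
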
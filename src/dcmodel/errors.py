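"""Exception hierarchy for dcmodel."""


class DCModelError(Exception):
    """Base class for all dcmodel errors."""


class InvalidParameterError(DCModelError, ValueError):
    """A model parameter is outside its admissible range."""


class DegenerateConditionError(DCModelError):
    """Conditioning on an event of probability zero (e.g. asking for the
    genotype distribution of left-handers in a model that produces none)."""


class NoSolutionError(DCModelError):
    """A requested target (e.g. prevalence) is unattainable for any
    admissible parameter value."""
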
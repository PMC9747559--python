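"""Exception hierarchy."""


class VarconcordError(Exception):
    """Base class for all package errors."""


class ValidationError(VarconcordError):
    """Invalid input: malformed records, out-of-range values, broken invariants."""


class SamplingError(VarconcordError):
    """A rejection sampler exhausted its attempt budget."""
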
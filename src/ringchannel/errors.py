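"""Exception hierarchy for ringchannel."""


class RingChannelError(Exception):
    """Base class for all ringchannel errors."""


class ParseError(RingChannelError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(RingChannelError):
    """A structure or selection contains no atoms."""


class FieldOverflowError(RingChannelError):
    """A value does not fit a fixed-width PDB field."""


class CorrespondenceError(RingChannelError):
    """Too few matched atom pairs for a superposition."""


class DegenerateInputError(RingChannelError):
    """Point set is rank-deficient (collinear or coincident points)."""
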
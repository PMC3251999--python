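"""Exception types shared across the toolkit."""


class ContractError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateRegionError(RuntimeError):
    """A level-set region carries (almost) no mass, so region statistics
    such as means or histograms are undefined."""


class FormatError(ValueError):
    """A file does not conform to the documented on-disk format."""


class ArchiveError(ValueError):
    """A model archive is missing fields or has an unsupported version."""
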
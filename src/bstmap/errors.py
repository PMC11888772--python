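"""Exception hierarchy."""


class BstmapError(Exception):
    """Base class for all bstmap errors."""


class ValidationError(BstmapError):
    """An input violates a documented contract (bad mesh, malformed table, ...)."""


class UndefinedResultError(BstmapError):
    """The requested statistic is mathematically undefined on this input
    (e.g. ICC on a zero-variance table, correlation of a constant)."""
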
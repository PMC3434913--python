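"""Exception hierarchy for otudelim.

All errors raised by the library derive from :class:`OtudelimError` so callers
can catch one base class at pipeline level.
"""


class OtudelimError(Exception):
    """Base class for all otudelim errors."""


class AlignmentError(OtudelimError):
    """Sequences violate alignment invariants (e.g. ragged lengths)."""


class InputError(OtudelimError):
    """Invalid user input: duplicate ids, illegal characters, bad groups."""


class ParseError(OtudelimError):
    """A file (Newick, TSV) could not be parsed."""


class ModelError(OtudelimError):
    """A model precondition is violated (e.g. non-ultrametric tree for GMYC)."""
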
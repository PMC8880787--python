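"""Exception hierarchy shared across the toolkit.

All domain errors derive from :class:`PragtagError` so the CLI can map
them uniformly onto exit code 1.
"""


class PragtagError(Exception):
    """Base class for all toolkit domain errors."""


class SchemaError(PragtagError):
    """Annotation-scheme file is malformed or violates scheme invariants."""


class FormatError(PragtagError):
    """A corpus/lexicon/span file does not conform to its dialect."""


class ReferenceError_(PragtagError):
    """A tag or heading reference does not resolve against the scheme."""


class DuplicateEntryError(PragtagError):
    """A lexicon entry (tag_id, pattern) pair occurs more than once."""


class SpanOverlapError(PragtagError):
    """Within-channel span overlap where IOB2 encoding forbids it."""


class SpanBoundsError(PragtagError):
    """A span lies outside the token range of its sentence."""


class InputError(PragtagError):
    """An operation precondition on caller-supplied data is violated."""


class DegenerateVarianceError(PragtagError):
    """Both samples of a two-sample test have zero variance."""


class SynthSpecError(PragtagError):
    """A synthetic-corpus specification is infeasible or inconsistent."""
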
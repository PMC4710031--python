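"""Error taxonomy.

Three categories beyond plain I/O errors, so callers (and the CLI exit
codes) can distinguish *what kind* of failure occurred:

* schema/invariant violations surface as :class:`pydantic.ValidationError`;
* dangling identifiers (unit costs, course labels, scenario parameters,
  question target paths) raise :class:`ReferenceResolutionError`;
* mathematically undefined requests (zero prevalence, non-positive
  survival, empty ranking input) raise :class:`DomainError`.
"""


class ReferenceResolutionError(LookupError):
    """An identifier does not resolve to a known entity."""


class DomainError(ValueError):
    """An operation was called outside its mathematical domain."""
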
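"""Exception hierarchy for the mixpeq engine."""


class MixpeqError(Exception):
    """Base class for all mixpeq errors."""


class DomainError(MixpeqError, ValueError):
    """An input violates a physical-domain constraint (negative mass, zero body weight...)."""


class MissingRpfError(MixpeqError, LookupError):
    """A compound has no relative potency factor assignment."""


class AggregationError(MixpeqError, ValueError):
    """Cells with mixed food categories / groups / modes were aggregated together."""


class MissingLimitError(MixpeqError, ValueError):
    """An upper-bound substitution was requested for a censored record with no LOD or LOQ."""


class NonInvertibleError(MixpeqError, ZeroDivisionError):
    """The intake equation cannot be inverted (zero potency or zero consumption)."""


class ConfigurationError(MixpeqError, ValueError):
    """Inconsistent configuration (e.g. occurrence compound with no RPF and no skip entry)."""


class FixtureError(MixpeqError, RuntimeError):
    """A bundled reference table failed its integrity check."""
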
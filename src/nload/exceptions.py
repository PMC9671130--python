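"""Exception hierarchy for nload.

All package-specific errors derive from :class:`NloadError` so callers can
catch everything from one base class. Validation problems that should be
collected rather than raised go through :class:`~nload.parcels.ValidationReport`
instead.
"""


class NloadError(Exception):
    """Base class for all nload errors."""


class SchemaError(NloadError):
    """A CSV file does not match the documented schema (missing/unknown columns,
    unsupported schema version)."""


class ValidationError(NloadError):
    """Input rows violate domain invariants (bounds, duplicates).

    Carries the full :class:`~nload.parcels.ValidationReport` on ``.report``.
    """

    def __init__(self, report):
        self.report = report
        super().__init__(str(report))


class ReferentialError(NloadError):
    """A record references an id (parcel or watershed) that does not exist."""


class SchedulingError(NloadError):
    """A load event is inconsistent with its parcel (e.g. dated before the
    parcel existed)."""


class ConfigurationError(NloadError):
    """An engine/scenario/generator configuration is invalid; the message names
    the offending field."""
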
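"""Exception hierarchy shared by all sheafkit modules."""


class SheafKitError(Exception):
    """Base class for all sheafkit errors."""


class TopologyError(SheafKitError):
    """A family of sets fails one of the topology axioms."""


class UnknownPointError(SheafKitError):
    """A point label is not part of the ambient space."""


class NotOpenError(SheafKitError):
    """A set of points is not open in the given space."""


class InclusionError(SheafKitError):
    """An operation required U to be a subset of V and it was not."""


class UnknownSectionError(SheafKitError):
    """A section is not an element of the table it was claimed to be in."""


class MalformedTableError(SheafKitError):
    """A table row does not assign a value to exactly the open set's points."""


class CoverError(SheafKitError):
    """A claimed cover does not union to its target open set."""


class PresheafError(SheafKitError):
    """A presheaf violates a structural precondition (functoriality, terminal F(emptyset))."""


class SizeError(SheafKitError):
    """An exhaustive verification was requested beyond its enforced size bounds."""


class SchemaError(SheafKitError):
    """A JSON/CSV artefact does not match the expected schema."""


class ConfigError(SheafKitError):
    """A demo was invoked with a missing or contradictory configuration."""


class ParallelLinesError(SheafKitError):
    """Two lines of sight are (numerically) parallel, so no unique intersection exists."""


class BehindEyesWarning(UserWarning):
    """The triangulated intersection lies at a negative distance from at least one eye."""
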
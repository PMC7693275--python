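"""Exception hierarchy for taxonym."""


class TaxonymError(Exception):
    """Base class for all taxonym errors."""


class NameParseError(TaxonymError):
    """A submitted name string cannot be decomposed into its parts."""


class HybridNotationError(NameParseError):
    """The multiplication sign U+00D7 was used to mark a hybrid."""


class ReferenceFormatError(TaxonymError):
    """A reference backbone file does not conform to the expected dialect."""


class StatusMappingError(ReferenceFormatError):
    """A status value in the file has no mapping to the status enum."""

    def __init__(self, values):
        self.values = sorted(set(values))
        super().__init__(
            "unmappable status value(s): " + ", ".join(repr(v) for v in self.values)
        )


class SynonymCycleError(TaxonymError):
    """Synonym cross-references form a cycle and cannot be flattened."""

    def __init__(self, cycles):
        self.cycles = cycles
        members = "; ".join(" <-> ".join(sorted(c)) for c in cycles)
        super().__init__(f"synonym cross-references contain cycle(s): {members}")


class FixtureSpecError(TaxonymError):
    """A fixture specification is infeasible or inconsistent."""
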
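"""Exception hierarchy for fragshift.

All package errors derive from :class:`FragshiftError` so callers can catch
one base class at tool boundaries.
"""


class FragshiftError(Exception):
    """Base class for all fragshift errors."""


class FormatError(FragshiftError):
    """A file or table could not be parsed (carries location info when known)."""


class EmptyStructureError(FragshiftError):
    """A structure with zero residues was produced."""


class MissingChargeError(FragshiftError):
    """An operation needed per-atom charges that are absent."""


class ChargeLookupError(FragshiftError):
    """A charge table does not cover every structure atom."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            f"{len(self.missing)} atom(s) missing from charge table: "
            + ", ".join(f"({r}, {n!r})" for r, n in self.missing)
        )


class ConfigurationError(FragshiftError):
    """Inconsistent configuration (e.g. no chromophore designated)."""


class InvalidChromophorePositionError(FragshiftError):
    """Chromophore too close to a chain terminus for fragmentation."""


class SizeError(FragshiftError):
    """Structure too small to fragment (N < 5)."""


class CappingError(FragshiftError):
    """A severed peptide bond could not be capped."""


class SingularityError(FragshiftError):
    """Two point charges coincide; Coulomb interaction undefined."""


class CompletenessError(FragshiftError):
    """QM results do not cover every required fragment."""

    def __init__(self, missing_ids):
        self.missing_ids = sorted(missing_ids)
        super().__init__("missing QM results for fragments: " + ", ".join(self.missing_ids))


class InvariantError(FragshiftError):
    """A QM result violates a physical invariant (e.g. negative excitation)."""


class DegenerateDataError(FragshiftError):
    """Statistics requested on degenerate data (zero variance, too short)."""


class ParameterError(FragshiftError):
    """Invalid fixture or generator parameters."""
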
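"""Exception taxonomy for rfamkit.

Errors are grouped so the CLI can map them onto distinct exit codes:
validation problems (bad input), not-found (unknown family / expired job),
and service problems (network, replay miss).
"""

from __future__ import annotations


class RfamKitError(Exception):
    """Base class for all rfamkit errors."""


class ValidationError(RfamKitError):
    """Invalid user input (sequence, options, coordinates, formats)."""


class EmptySequenceError(ValidationError):
    def __init__(self) -> None:
        super().__init__("sequence is empty after whitespace stripping")


class IllegalResidueError(ValidationError):
    """A residue outside the RNA alphabet plus IUPAC ambiguity codes.

    ``position`` is 1-based.
    """

    def __init__(self, position: int, char: str) -> None:
        self.position = position
        self.char = char
        super().__init__(f"illegal residue {char!r} at position {position}")


class BadOverlapError(ValidationError):
    def __init__(self, overlap: int, window: int) -> None:
        super().__init__(
            f"fragment overlap ({overlap} nt) must be smaller than the window ({window} nt)"
        )


class CoordinateOutOfRangeError(ValidationError):
    pass


class FragmentTooLongError(ValidationError):
    def __init__(self, length: int, limit: int) -> None:
        super().__init__(f"fragment of {length} nt exceeds the {limit}-nt search limit")


class NotFoundError(RfamKitError):
    """Requested entity does not exist on the service / in the replay store."""


class FamilyNotFoundError(NotFoundError):
    def __init__(self, family: str) -> None:
        self.family = family
        super().__init__(f"Rfam family {family!r} not found")


class JobExpiredError(NotFoundError):
    def __init__(self, job_id: str) -> None:
        super().__init__(f"search job {job_id!r} unknown or expired")


class ServiceError(RfamKitError):
    """Transport-level failures."""


class ServiceUnavailableError(ServiceError):
    pass


class ReplayMissError(ServiceError):
    """Replay mode received a request with no recorded response.

    Raised instead of ever falling back to the network.
    """

    def __init__(self, key: str, description: str) -> None:
        self.key = key
        super().__init__(f"no recorded response for request {description} (key {key})")


class FragmentSearchFailedError(ServiceError):
    """A per-fragment search failed; the whole search aborts (no partial results)."""

    def __init__(self, fragment: object, cause: Exception) -> None:
        self.fragment = fragment
        self.__cause__ = cause
        super().__init__(f"search failed for fragment {fragment}: {cause}")


class FormatError(RfamKitError):
    """Malformed data in one of the supported file formats."""


class MalformedStockholmError(FormatError):
    def __init__(self, line_number: int, message: str) -> None:
        self.line_number = line_number
        super().__init__(f"malformed Stockholm record at line {line_number}: {message}")


class RaggedAlignmentError(FormatError):
    pass


class UnbalancedStructureError(FormatError):
    def __init__(self, family: str, position: int) -> None:
        self.family = family
        self.position = position
        super().__init__(
            f"unbalanced structure: bracket family {family!r} at position {position}"
        )


class MalformedNewickError(FormatError):
    def __init__(self, message: str) -> None:
        super().__init__(f"malformed Newick/NHX tree: {message}")


class NotACovarianceModelError(FormatError):
    def __init__(self) -> None:
        super().__init__("payload does not start with the Infernal covariance-model header")


class NotAnSvgError(FormatError):
    def __init__(self) -> None:
        super().__init__("payload does not contain an XML <svg> root element")
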
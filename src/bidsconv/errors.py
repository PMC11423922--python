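"""Exception taxonomy; each class maps to one CLI exit code."""


class BidsconvError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class UsageError(BidsconvError):
    exit_code = 2


class InputError(BidsconvError):
    """A named input path is missing or unreadable."""

    exit_code = 3


class ArchiveError(InputError):
    """A zip archive could not be opened or extracted."""

    exit_code = 3


class HeuristicContractError(BidsconvError):
    """A heuristic module lacks a required hook or returned invalid output."""

    exit_code = 4


class PlanError(BidsconvError):
    """A conversion plan references series that do not exist."""

    exit_code = 4


class IdInferenceError(BidsconvError):
    """Subject/session ids could not be inferred; operator must supply -s."""

    exit_code = 4


class AssemblyError(BidsconvError):
    """Slice stacking failed (missing slices, inconsistent geometry)."""

    exit_code = 5


class CollisionError(BidsconvError):
    """An output path exists with different content and overwrite is off."""

    exit_code = 6


class TemplateError(BidsconvError):
    """An output template contains an unresolvable placeholder."""

    exit_code = 4


class ValidationError(BidsconvError):
    """An edited conversion table violates plan invariants."""

    exit_code = 4
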
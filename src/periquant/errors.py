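"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError (and subclasses) -> 2,
I/O problems (OSError, FormatError on unreadable input) -> 3.
"""


class PeriquantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PeriquantError):
    """Invalid arguments or inconsistent inputs."""


class FormatError(PeriquantError):
    """A file decoded, but not to a supported format (e.g. 16-bit TIFF)."""


class DegenerateInputError(ValidationError):
    """Analysis is meaningless for this input (empty specimen/structure)."""


class UndefinedFractionError(DegenerateInputError):
    """A density fraction has a vanishing denominator.

    ``denominator`` names which area was empty (``"a_n"`` or ``"a_d"``).
    """

    def __init__(self, denominator: str):
        self.denominator = denominator
        super().__init__(f"density fraction undefined: |{denominator}| = 0")


class InfeasibleDensityError(ValidationError):
    """More seed points requested than available pixels."""
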
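"""Exception hierarchy shared by all chirobiophore modules."""


class ChirobiophoreError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ChirobiophoreError):
    """A structure file could not be parsed."""


class EmptyStructureError(ChirobiophoreError):
    """No protein atoms remain after filtering solvent/heteroatoms."""


class FrameUndefinedError(ChirobiophoreError):
    """No usable transmembrane helix to define the membrane frame.

    Callers may supply an explicit membrane normal instead (``--normal``).
    """


class UndefinedDescriptorError(ChirobiophoreError):
    """A descriptor is mathematically undefined for the given structure.

    Carries the name of the failing descriptor slot in ``descriptor``.
    """

    def __init__(self, descriptor: str, message: str):
        self.descriptor = descriptor
        super().__init__(f"{descriptor}: {message}")


class TooShortHelixError(ChirobiophoreError):
    """Fewer than four C-alpha positions supplied for an axis fit."""


class DegenerateProfileError(ChirobiophoreError):
    """Density profile has no z-extent (single atom or coincident atoms)."""
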
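"""Exception hierarchy shared across the package."""


class CgdockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CgdockError, ValueError):
    """A file could not be parsed in the expected format."""


class EmptyStructureError(CgdockError, ValueError):
    """A structure selection yielded no atoms or beads."""


class UnmappedResidueError(CgdockError, KeyError):
    """A residue has no entry in the coarse-graining scheme."""

    def __init__(self, residues):
        self.residues = tuple(residues)
        super().__init__(
            "no scheme entry for residue(s): " + ", ".join(map(str, self.residues))
        )


class ParameterLookupError(CgdockError, KeyError):
    """A bead type code is missing from the pair parameter table."""

    def __init__(self, code):
        self.code = code
        super().__init__(f"bead type code {code!r} not in parameter table")


class RoleError(CgdockError, ValueError):
    """An operation was applied to a molecule of the wrong kind."""
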
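"""Exception hierarchy for pharmflow."""


class PharmflowError(Exception):
    """Base class for all pharmflow errors."""


class PDBParseError(PharmflowError):
    """Malformed PDB record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MoleculeError(PharmflowError):
    """Invalid molecule (bad bond indices, empty, conformer mismatch...)."""


class SelectorError(PharmflowError):
    """A residue/atom selector did not resolve to exactly one target."""


class EmptyModelError(PharmflowError):
    """No protein-ligand interactions found; cannot build a model."""


class ConnectivityError(PharmflowError):
    """Two molecules that should share a molecular graph do not."""


class TrajectoryError(PharmflowError):
    """Inconsistent multi-model coordinates or too few frames."""
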
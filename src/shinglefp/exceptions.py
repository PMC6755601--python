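"""Exception hierarchy for shinglefp."""


class ShingleFPError(Exception):
    """Base class for all shinglefp errors."""


class SmilesParseError(ShingleFPError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class KekulizationError(ShingleFPError):
    """Raised when an aromatic system cannot be kekulized.

    Carries the molecule SMILES and, when known, the offending atom index.
    """

    def __init__(self, smiles: str, atom_index: int | None = None):
        self.smiles = smiles
        self.atom_index = atom_index
        loc = f", atom {atom_index}" if atom_index is not None else ""
        super().__init__(f"kekulization failed for {smiles!r}{loc}")


class EmptyShinglingError(ShingleFPError):
    """Raised when a molecule yields no substructure SMILES at all.

    Happens for single heavy atoms such as methane ("C"): there is no bond
    within any radius and no ring, so the shingling is empty and a MinHash
    over it would be undefined.
    """

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"molecule {smiles!r} produced an empty shingling")


class EmptyInputError(ShingleFPError):
    """Raised when an operation is applied to an empty set (undefined)."""


class ParameterMismatchError(ShingleFPError):
    """Raised when two MinHash vectors built from different hash families
    (or different k) are compared or mixed in one index."""
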
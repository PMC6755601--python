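"""Molecular shingling: circular substructure SMILES extraction.

A molecular shingling is the set of canonical, kekulized SMILES strings of
the circular substructures centred on every heavy atom of a molecule, for
every radius from ``min_radius`` up to ``radius`` bonds, optionally joined
by one SMILES per ring of the symmetrized smallest set of smallest rings
(SSSR).  It is the molecular analogue of the w-shingling of a document:
instead of word n-grams, the "shingles" are rooted substructure SMILES of
varying length.

The shingling is a graph invariant: any two SMILES spellings of the same
molecule yield the same set, because every substructure is written with the
canonical SMILES writer (rooted at its centre atom for circular shingles,
unrooted for rings).  For a molecule with ``n`` heavy atoms and maximum
radius ``r`` the set holds at most ``n * (r + 1)`` circular strings plus one
string per ring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from rdkit import Chem
from rdkit import RDLogger

from .exceptions import EmptyShinglingError, KekulizationError, SmilesParseError

# RDKit logs every rejected SMILES to stderr; errors are raised as exceptions
# instead, so silence the C++ logger.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "MoleculeRecord",
    "Shingling",
    "atom_environment_smiles",
    "ring_smiles",
    "shingling_from_smiles",
    "shingling_from_mol",
    "mol_from_smiles",
    "read_smiles_file",
]

DEFAULT_RADIUS = 3


@dataclass(frozen=True)
class MoleculeRecord:
    """A single input molecule: SMILES plus an optional identifier."""

    smiles: str
    identifier: str = ""


@dataclass(frozen=True)
class Shingling:
    """The deduplicated set of substructure SMILES describing one molecule.

    Attributes
    ----------
    shingles:
        Canonical kekulized substructure SMILES (set semantics).
    radius:
        Maximum radius, in bonds, of the circular substructures.
    rings_included:
        Whether SSSR ring SMILES were added to the set.
    """

    shingles: frozenset[str]
    radius: int
    rings_included: bool = True

    def __len__(self) -> int:
        return len(self.shingles)

    def __iter__(self) -> Iterator[str]:
        return iter(self.shingles)


def mol_from_smiles(smiles: str, strip_stereo: bool = True) -> Chem.Mol:
    """Parse a SMILES string into a kekulized RDKit molecule.

    Stereochemistry is stripped by default so that substructure SMILES are
    plain (non-isomeric); aromatic flags are cleared so every substructure
    is written with explicit alternating bonds.

    The molecule is first respelled canonically and re-parsed, which puts
    the atoms in canonical order.  Kekulization depends on atom order (a
    substituted benzene admits two alternating-bond assignments), so
    without this step two spellings of one molecule could shingle
    differently; with it the shingling is a graph invariant.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if mol.GetNumHeavyAtoms() == 0:
        raise SmilesParseError(smiles, "no heavy atoms")
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if mol is None:  # canonical respelling should always re-parse
        raise SmilesParseError(smiles, "canonical respelling failed")
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # unparseable aromatic system
        raise KekulizationError(smiles) from exc
    return mol


def atom_environment_smiles(mol: Chem.Mol, atom_index: int, radius: int) -> str:
    """Canonical kekulized SMILES of the circular environment of one atom.

    The environment is the subgraph of all bonds within ``radius`` bonds of
    the centre atom; the SMILES is written rooted at the centre.  Returns an
    empty string when no bond lies within the radius (isolated atoms, or a
    radius that exceeds the fragment).

    Parameters
    ----------
    mol:
        Kekulized molecule (as produced by :func:`mol_from_smiles`).
    atom_index:
        Index of the centre heavy atom, ``0 <= atom_index < num_atoms``.
    radius:
        Environment radius in bonds, ``>= 1`` (use ``radius=0`` for the
        bare single-atom SMILES).
    """
    if not 0 <= atom_index < mol.GetNumAtoms():
        raise ValueError(f"atom index {atom_index} out of range")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return Chem.MolFragmentToSmiles(
            mol, atomsToUse=[atom_index], canonical=True, isomericSmiles=False
        )
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_index)
    if not bonds:
        return ""
    atoms: set[int] = {atom_index}
    for bond_idx in bonds:
        bond = mol.GetBondWithIdx(bond_idx)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=sorted(atoms),
        bondsToUse=list(bonds),
        rootedAtAtom=atom_index,
        canonical=True,
        isomericSmiles=False,
    )


def ring_smiles(mol: Chem.Mol) -> set[str]:
    """One canonical kekulized SMILES per ring of the symmetrized SSSR.

    Acyclic molecules return the empty set.  Ring SMILES are written
    unrooted, since a ring has no distinguished centre atom.
    """
    out: set[str] = set()
    for ring in Chem.GetSymmSSSR(mol):
        ring_atoms = list(ring)
        n = len(ring_atoms)
        bond_ids = []
        for i in range(n):
            bond = mol.GetBondBetweenAtoms(ring_atoms[i], ring_atoms[(i + 1) % n])
            bond_ids.append(bond.GetIdx())
        out.add(
            Chem.MolFragmentToSmiles(
                mol,
                atomsToUse=ring_atoms,
                bondsToUse=bond_ids,
                canonical=True,
                isomericSmiles=False,
            )
        )
    return out


def shingling_from_mol(
    mol: Chem.Mol,
    radius: int = DEFAULT_RADIUS,
    include_rings: bool = True,
    min_radius: int = 1,
) -> set[str]:
    """Shingling of an already-parsed (kekulized) molecule, as a plain set."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not 0 <= min_radius <= radius:
        raise ValueError("min_radius must satisfy 0 <= min_radius <= radius")
    shingles: set[str] = set()
    for atom_index in range(mol.GetNumAtoms()):
        for r in range(min_radius, radius + 1):
            s = atom_environment_smiles(mol, atom_index, r)
            if s:
                shingles.add(s)
    if include_rings:
        shingles |= ring_smiles(mol)
    return shingles


def shingling_from_smiles(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    include_rings: bool = True,
    min_radius: int = 1,
    strip_stereo: bool = True,
    allow_empty: bool = False,
) -> Shingling:
    """Compute the molecular shingling of a SMILES string.

    Enumerates the circular substructure SMILES of every heavy atom for all
    radii ``min_radius..radius``, adds one SMILES per SSSR ring when
    ``include_rings``, drops empty environments and deduplicates.

    Raises
    ------
    SmilesParseError
        If the SMILES does not parse.
    EmptyShinglingError
        If the molecule yields no shingles at all (e.g. methane "C") and
        ``allow_empty`` is False.
    """
    mol = mol_from_smiles(smiles, strip_stereo=strip_stereo)
    shingles = shingling_from_mol(
        mol, radius=radius, include_rings=include_rings, min_radius=min_radius
    )
    if not shingles and not allow_empty:
        raise EmptyShinglingError(smiles)
    return Shingling(
        shingles=frozenset(shingles), radius=radius, rings_included=include_rings
    )


def read_smiles_file(path: str | Path) -> Iterator[MoleculeRecord]:
    """Iterate over a SMILES file: one record per line.

    Fields are tab-separated; the first field is the SMILES, the optional
    second field an identifier (defaults to the 1-based line number).  Blank
    lines and lines starting with '#' are skipped.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            smiles = fields[0].strip()
            identifier = fields[1].strip() if len(fields) > 1 and fields[1].strip() else str(lineno)
            yield MoleculeRecord(smiles=smiles, identifier=identifier)
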
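"""Molecular-structure queries needed by the assignment stages.

Reads MDL MOL/SDF files through RDKit and extracts the facts the
pipeline needs: proton/carbon inventories, labile (exchangeable)
protons, and methyl groups.  Atom labels are the element symbol plus the
1-based atom index in file order (``C1``, ``H12`` ...), the convention
expected of the calculated-shift tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["StructureInfo", "read_structure"]

#: Protons bonded to these elements exchange with solvent and may be
#: absent from the spectrum.
_LABILE_NEIGHBOURS = {"O", "N", "S"}


@dataclass
class StructureInfo:
    """Assignment-relevant facts about one candidate structure."""

    candidate_id: str
    atom_labels: list[str]
    carbon_labels: list[str]
    proton_labels: list[str]
    labile_protons: list[str]
    methyl_groups: list[tuple[str, str, str]]  # H-label trios

    @property
    def n_carbons(self) -> int:
        return len(self.carbon_labels)

    @property
    def n_protons(self) -> int:
        return len(self.proton_labels)

    @property
    def n_labile(self) -> int:
        return len(self.labile_protons)


def read_structure(path: str | Path, candidate_id: str | None = None) -> StructureInfo:
    """Parse a MOL/SDF file into a :class:`StructureInfo`.

    Explicit hydrogens are added if the file stores them implicitly, so
    labels are stable only for files with explicit H; shift tables must
    use the same convention as the structure file they accompany.
    """
    from rdkit import Chem

    path = Path(path)
    mol = Chem.MolFromMolFile(str(path), removeHs=False, sanitize=True)
    if mol is None:
        raise ValueError(f"could not parse structure file {path}")
    if not any(a.GetSymbol() == "H" for a in mol.GetAtoms()):
        mol = Chem.AddHs(mol)

    labels = [f"{a.GetSymbol()}{a.GetIdx() + 1}" for a in mol.GetAtoms()]
    carbons, protons, labile = [], [], []
    methyls: list[tuple[str, str, str]] = []
    for atom in mol.GetAtoms():
        label = labels[atom.GetIdx()]
        sym = atom.GetSymbol()
        if sym == "C":
            carbons.append(label)
            h_neigh = [n for n in atom.GetNeighbors() if n.GetSymbol() == "H"]
            if len(h_neigh) == 3:  # a methyl carbon
                trio = tuple(sorted(labels[n.GetIdx()] for n in h_neigh))
                methyls.append(trio)  # type: ignore[arg-type]
        elif sym == "H":
            protons.append(label)
            neigh = atom.GetNeighbors()
            if neigh and neigh[0].GetSymbol() in _LABILE_NEIGHBOURS:
                labile.append(label)
    return StructureInfo(
        candidate_id=candidate_id or path.stem,
        atom_labels=labels,
        carbon_labels=carbons,
        proton_labels=protons,
        labile_protons=labile,
        methyl_groups=methyls,
    )
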
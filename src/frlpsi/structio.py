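"""Structure parsing and alignment-to-chain residue mapping.

Structures are read with gemmi (PDB or mmCIF; first model, highest-occupancy
altloc).  Protein chains are exposed as author-numbered residues — author
numbering is authoritative throughout, matching how residues such as
PsaB2-666/667/673 are referred to in structural work on photosystem I.
Chlorophyll-type cofactors (component CLA by default; deposited FRL-PSI
models build chlorophyll f as CLA) are extracted with their tetrapyrrole
ring-atom groups: pyrrole rings A-D each carry one of the nitrogens NA-ND,
and ring E is the isocyclic cyclopentanone ring carrying the 13(1)-keto
oxygen OBD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from Bio.Align import PairwiseAligner
from Bio.Data.IUPACData import protein_letters_3to1

from .seqio import GroupedAlignment

PYRROLE_NITROGENS = ("NA", "NB", "NC", "ND")

#: Tetrapyrrole ring-atom groups using chemical-component-dictionary names
#: for chlorophyll (CLA/CHL-style).  Ring E shares C3C/C4C with ring C and
#: closes through the C15 methine (CHD); CAD carries the keto oxygen OBD.
RING_DEFINITIONS: dict[str, tuple[str, ...]] = {
    "A": ("NA", "C1A", "C2A", "C3A", "C4A"),
    "B": ("NB", "C1B", "C2B", "C3B", "C4B"),
    "C": ("NC", "C1C", "C2C", "C3C", "C4C"),
    "D": ("ND", "C1D", "C2D", "C3D", "C4D"),
    "E": ("C3C", "C4C", "CHD", "CAD", "CBD"),
}

DEFAULT_CHLOROPHYLL_COMPONENTS = ("CLA", "CHL", "CL0", "F6C", "G9R")


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # (3,) in Angstrom


@dataclass
class Residue:
    author_number: int
    insertion_code: str
    name: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name} {self.author_number}: no atom {name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Cofactor:
    component_id: str
    chain: str
    number: int
    atoms: list[Atom]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.component_id} {self.chain}{self.number}: no atom {name}")

    def has_atoms(self, names) -> bool:
        have = {a.name for a in self.atoms}
        return all(n in have for n in names)

    def ring_coordinates(self, ring: str) -> np.ndarray:
        names = RING_DEFINITIONS[ring]
        return np.array([self.atom(n).xyz for n in names])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.author_number == number:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {number}")

    def observed_sequence(self) -> tuple[str, list[int]]:
        """One-letter sequence of modelled residues and their author numbers."""
        letters, numbers = [], []
        for r in self.residues:
            one = protein_letters_3to1.get(r.name.capitalize())
            if one:
                letters.append(one)
                numbers.append(r.author_number)
        return "".join(letters), numbers


@dataclass
class StructureModel:
    structure_id: str
    chains: list[Chain]
    cofactors: list[Cofactor]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain '{chain_id}' in {self.structure_id}")

    def cofactor(self, chain: str, number: int) -> Cofactor:
        for c in self.cofactors:
            if c.chain == chain and c.number == number:
                return c
        raise KeyError(f"no cofactor {chain}:{number} in {self.structure_id}")


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid():
        return True
    return protein_letters_3to1.get(resname.capitalize()) is not None


def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy altloc per atom name; ties prefer 'A'."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if (
            prev is None
            or atom.occ > prev.occ
            or (atom.occ == prev.occ and (atom.altloc or "A") < (prev.altloc or "A"))
        ):
            best[atom.name] = atom
    return list(best.values())


def read_structure(
    path: str | Path,
    chlorophyll_components: tuple[str, ...] = DEFAULT_CHLOROPHYLL_COMPONENTS,
) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel (first model only)."""
    path = str(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    chains: list[Chain] = []
    cofactors: list[Cofactor] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in _pick_altloc(res)
            ]
            if res.name in chlorophyll_components:
                cof = Cofactor(res.name, ch.name, res.seqid.num, atoms)
                if not cof.has_atoms(PYRROLE_NITROGENS):
                    warnings.warn(
                        f"{path}: {res.name} {ch.name}{res.seqid.num} lacks "
                        "pyrrole nitrogens NA-ND; excluded from geometry"
                    )
                    continue
                cofactors.append(cof)
            elif _is_amino_acid(res.name):
                residues.append(
                    Residue(res.seqid.num, res.seqid.icode.strip(), res.name, atoms)
                )
        if residues:
            chains.append(Chain(ch.name, residues))
    sid = st.name or Path(path).stem
    return StructureModel(structure_id=sid, chains=chains, cofactors=cofactors)


@dataclass
class StructureResidueMap:
    """Bijection between alignment columns and author residue numbers."""

    sequence_id: str
    chain_id: str
    column_to_resnum: dict[int, int]
    identity: float

    @property
    def resnum_to_column(self) -> dict[int, int]:
        return {v: k for k, v in self.column_to_resnum.items()}


def map_alignment_to_chain(
    sequence_id: str,
    aln: GroupedAlignment,
    chain: Chain,
    min_identity: float = 0.95,
) -> StructureResidueMap:
    """Map alignment columns of one row onto a chain's author numbering.

    The chain's observed (modelled) sequence is globally aligned to the
    ungapped alignment row; matched positions with >= *min_identity* over the
    mapped span become (column, author number) pairs.  Unmodelled stretches
    (e.g. flexible loops absent from the deposited model) are simply missing
    from the map.
    """
    row = aln.sequence(sequence_id)
    cmap = {}  # ungapped position -> column
    pos = 0
    for col, ch in enumerate(row, 1):
        if ch != "-":
            pos += 1
            cmap[pos] = col
    row_seq = row.replace("-", "")
    chain_seq, chain_numbers = chain.observed_sequence()
    if len(chain_seq) < 20:
        raise StructureError(
            f"chain {chain.chain_id}: only {len(chain_seq)} observed residues"
        )
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(row_seq, chain_seq)[0]
    pairs: list[tuple[int, int]] = []  # (row position 1-based, chain index 0-based)
    n_match = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i in range(a1 - a0):
            pairs.append((a0 + i + 1, b0 + i))
            if row_seq[a0 + i] == chain_seq[b0 + i]:
                n_match += 1
    if not pairs:
        raise StructureError("chain does not match alignment row: no aligned span")
    identity = n_match / len(pairs)
    if identity < min_identity:
        raise StructureError(
            f"chain {chain.chain_id} does not match alignment row "
            f"'{sequence_id}': identity {identity:.1%} < {min_identity:.0%}"
        )
    column_to_resnum = {cmap[p]: chain_numbers[ci] for p, ci in pairs}
    return StructureResidueMap(
        sequence_id=sequence_id,
        chain_id=chain.chain_id,
        column_to_resnum=column_to_resnum,
        identity=identity,
    )


def read_site_table(path: str | Path) -> list[dict]:
    """Chlorophyll-site table: structure_id, site_name, chain, resnum, component_id."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise StructureError(f"{path}:{lineno}: expected 5 tab-separated fields")
        rows.append(
            {
                "structure_id": parts[0],
                "site_name": parts[1],
                "chain": parts[2],
                "resnum": int(parts[3]),
                "component_id": parts[4],
            }
        )
    return rows
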
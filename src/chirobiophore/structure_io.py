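"""Structure input/output: PDB/mmCIF parsing, bond inference, PDB writing.

The internal model is deliberately minimal: an ordered list of heavy atoms
with per-chain sequential residue indices, helix annotations taken from the
deposited HELIX records (or the mmCIF ``struct_conf`` category), and a set of
inferred covalent bonds.  Everything downstream (tetrahedron enumeration,
backbone torsions, helix axes) works from this model only.

Loading filters the deposited model down to the protein heavy atoms:
solvent and hetero-compounds are removed, hydrogens are dropped (most
crystal structures do not resolve them), only the first model of
multi-model files is kept, and alternate conformations are resolved to the
highest-occupancy location.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, ParseError

# Covalent radii (Angstrom) for elements that occur in protein heavy-atom
# models; bonding is purely distance-based so it is independent of atom
# naming conventions.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "SE": 1.20, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "FE": 1.32, "ZN": 1.22, "MG": 1.41, "MN": 1.39, "CU": 1.32,
    "NA": 1.66, "K": 2.03, "CA": 1.76, "NI": 1.24, "CO": 1.26,
}

# Standard atomic masses (u) for the mass-weighted center of mass.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "FE": 55.845, "ZN": 65.38, "MG": 24.305, "MN": 54.938,
    "CU": 63.546, "NA": 22.990, "K": 39.098, "CA": 40.078, "NI": 58.693,
    "CO": 58.933,
}


@dataclass(eq=False)
class Atom:
    """One heavy atom.

    ``residue_index`` is the sequential 0-based position of the atom's
    residue within its chain in file order (author numbering gaps and
    insertion codes are ignored).  ``name`` is informational only; no
    computation keys off it except the C-alpha selection for backbone
    operations.
    """

    serial: int
    element: str
    coords: np.ndarray
    residue_index: int
    chain_id: str
    name: str = ""


@dataclass
class HelixAnnotation:
    chain_id: str
    start_residue: int
    end_residue: int

    def __post_init__(self):
        if self.start_residue > self.end_residue:
            raise ValueError("helix start_residue must be <= end_residue")

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1


class Structure:
    """Ordered heavy-atom model with helix annotations and inferred bonds."""

    def __init__(self, atoms, helices=None, bonds=None, id=""):
        self.atoms: list[Atom] = list(atoms)
        self.helices: list[HelixAnnotation] = list(helices or [])
        self.bonds: set[tuple[int, int]] = set(bonds or ())
        self.id: str = id
        serials = {a.serial for a in self.atoms}
        for a, b in self.bonds:
            if a == b:
                raise ValueError("self-bond in bond set")
            if a not in serials or b not in serials:
                raise ValueError("bond references unknown atom serial")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates (same order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.element, coords[i].copy(), a.residue_index,
                 a.chain_id, a.name)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, self.helices, self.bonds, self.id)

    def atom_by_serial(self, serial: int) -> Atom:
        return self._serial_map()[serial]

    def _serial_map(self) -> dict[int, Atom]:
        return {a.serial: a for a in self.atoms}

    def adjacency(self) -> dict[int, list[int]]:
        """Bonded-neighbor serials per atom serial (sorted, deterministic)."""
        adj: dict[int, list[int]] = {a.serial: [] for a in self.atoms}
        for a, b in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        for v in adj.values():
            v.sort()
        return adj

    def residues(self):
        """Iterate (chain_id, residue_index, [atoms]) in file order."""
        out: dict[tuple[str, int], list[Atom]] = {}
        order = []
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_index)
            if key not in out:
                out[key] = []
                order.append(key)
            out[key].append(atom)
        for key in order:
            yield key[0], key[1], out[key]

    def ca_trace(self) -> dict[str, list[tuple[int, np.ndarray]]]:
        """Per chain: ordered (residue_index, coords) of C-alpha atoms."""
        trace: dict[str, list[tuple[int, np.ndarray]]] = {}
        for atom in self.atoms:
            if atom.name.strip() == "CA" and atom.element == "C":
                trace.setdefault(atom.chain_id, []).append(
                    (atom.residue_index, atom.coords))
        return trace

    def helix_ca_coords(self, helix: HelixAnnotation) -> np.ndarray:
        """C-alpha coordinates of an annotated helix, N- to C-terminal."""
        trace = self.ca_trace().get(helix.chain_id, [])
        pts = [c for idx, c in trace
               if helix.start_residue <= idx <= helix.end_residue]
        return np.array(pts) if pts else np.zeros((0, 3))


def _is_protein_residue(res: gemmi.Residue) -> bool:
    # ATOM records only: solvent and hetero-compounds (HETATM) are stripped.
    return res.het_flag == "A"


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy altloc per atom name; ties go to the first in file."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    # preserve file order
    names_seen = []
    for atom in res:
        if atom.name not in names_seen:
            names_seen.append(atom.name)
    return [chosen[n] for n in names_seen]


def load_structure(path, format: str = "auto") -> Structure:
    """Load a PDB or mmCIF file into the internal heavy-atom model.

    Parameters
    ----------
    path : str or Path
        Structure file.
    format : {"auto", "pdb", "mmcif"}
        File format; "auto" detects from contents/extension.

    Returns
    -------
    Structure
        Protein heavy atoms only; waters, hetero-atoms and hydrogens
        removed; first model of multi-model files; altlocs resolved to
        highest occupancy; helix annotations from HELIX records or the
        mmCIF ``struct_conf`` category, clipped to resolved residues.
    """
    path = Path(path)
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path.name}: no models")
    model = st[0]  # first model only for multi-model (NMR) files

    atoms: list[Atom] = []
    # author seqid -> sequential index, for helix-annotation conversion
    seq_map: dict[tuple[str, int, str], int] = {}
    serial = 0
    for chain in model:
        res_counter = 0
        for res in chain:
            if not _is_protein_residue(res):
                continue
            kept = []
            for gatom in _resolve_altlocs(res):
                if gatom.element.is_hydrogen:
                    continue
                serial += 1
                kept.append(Atom(
                    serial=serial,
                    element=gatom.element.name.upper(),
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    residue_index=res_counter,
                    chain_id=chain.name,
                    name=gatom.name,
                ))
            if kept:
                atoms.extend(kept)
                seq_map[(chain.name, res.seqid.num, res.seqid.icode or " ")] \
                    = res_counter
                res_counter += 1
    if not atoms:
        raise EmptyStructureError(
            f"{path.name}: zero protein atoms after filtering")

    helices = []
    for hel in st.helices:
        chain_name = hel.start.chain_name
        per_chain = {num: idx for (cn, num, _ic), idx in seq_map.items()
                     if cn == chain_name}
        lo, hi = hel.start.res_id.seqid.num, hel.end.res_id.seqid.num
        resolved = [idx for num, idx in per_chain.items() if lo <= num <= hi]
        if not resolved:
            continue  # annotation points entirely at unresolved residues
        helices.append(HelixAnnotation(chain_name, min(resolved),
                                       max(resolved)))

    return Structure(atoms, helices, id=st.name or path.stem)


def infer_bonds(structure: Structure, scale: float = 1.15) -> Structure:
    """Infer covalent bonds from interatomic distances.

    Two atoms are bonded iff their distance is at most
    ``scale * (r_cov(a) + r_cov(b))``.  Atoms of unknown element are
    excluded from bonding with a warning.  Returns a new Structure with
    the bond set populated; coordinates and annotations are untouched.
    """
    known = []
    radii = []
    for i, atom in enumerate(structure.atoms):
        r = COVALENT_RADII.get(atom.element)
        if r is None:
            warnings.warn(
                f"unknown element {atom.element!r} (serial {atom.serial}) "
                "excluded from bond inference")
            continue
        known.append(i)
        radii.append(r)
    bonds: set[tuple[int, int]] = set()
    if len(known) >= 2:
        coords = structure.coords[known]
        radii_arr = np.array(radii)
        max_cut = scale * 2.0 * radii_arr.max()
        tree = cKDTree(coords)
        for ia, ib in tree.query_pairs(max_cut):
            d = np.linalg.norm(coords[ia] - coords[ib])
            if d <= scale * (radii_arr[ia] + radii_arr[ib]):
                sa = structure.atoms[known[ia]].serial
                sb = structure.atoms[known[ib]].serial
                bonds.add((min(sa, sb), max(sa, sb)))
    return Structure(structure.atoms, structure.helices, bonds, structure.id)


def write_pdb(structure: Structure, path) -> None:
    """Write the structure as standard PDB ATOM records (plus HELIX).

    Residues are renumbered ``residue_index + 1``; residue names are not
    part of the model and are written as ALA.  The writer is deterministic:
    write -> load -> write reproduces the file byte for byte.
    """
    if not structure.atoms:
        raise EmptyStructureError("cannot write an empty structure")
    path = Path(path)
    lines = []
    for i, hel in enumerate(structure.helices, start=1):
        lines.append(
            f"HELIX  {i:>3d} {i:>3d} ALA {hel.chain_id:1s} "
            f"{hel.start_residue + 1:>4d}  ALA {hel.chain_id:1s} "
            f"{hel.end_residue + 1:>4d}  1"
            f"{'':30s}{hel.length:>6d}"
        )
    for n, atom in enumerate(structure.atoms, start=1):
        name = atom.name.strip() or atom.element
        name_field = name if len(name) == 4 else f" {name:<3s}"
        x, y, z = atom.coords
        if not all(math.isfinite(v) and abs(v) < 10000 for v in (x, y, z)):
            raise ValueError(f"coordinates of atom {atom.serial} not "
                             "representable in PDB format")
        lines.append(
            f"ATOM  {n:>5d} {name_field}ALA {atom.chain_id:1s}"
            f"{atom.residue_index + 1:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"{'':10s}{atom.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
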
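"""Atomic-scale chirality: signed tetrahedral volumes (LTA) and angular
entropy of local environments (AES).

LTA (Local Tetrahedral Asymmetry) averages the signed volumes of all
tetrahedra formed by an atom and three of its bonded neighbors, normalized
by the mean absolute volume:

    V = (1/6) (r_j - r_i) . ((r_k - r_i) x (r_l - r_i))
    LTA = mean(V) / mean(|V|)            in [-1, +1]

The sign of V flips under reflection, so LTA is exactly negated by a mirror
image.  Because the scalar triple product is antisymmetric under neighbor
permutation, the three neighbors of every tetrahedron are put in a
canonical order (by distance from the center, ties by membrane-frame
coordinates) so the sign is deterministic and label-independent.

AES (Asymmetric Environment Score) is the mean Shannon entropy of the
(theta, phi) angular histogram of each atom's spatial neighborhood within
a 6 A cutoff, with 15 degree bins in both angles (12 x 24 = 288 bins),
measured against the membrane frame's +z axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .errors import UndefinedDescriptorError
from .structure_io import Structure

AES_CUTOFF = 6.0       # A, neighborhood radius
THETA_BIN_DEG = 15.0   # polar bin width (divides 180)
PHI_BIN_DEG = 15.0     # azimuthal bin width (divides 360)


@dataclass
class Tetrahedron:
    center: int                      # atom serial
    neighbors: tuple                 # canonical (serial, serial, serial)
    signed_volume: float             # A^3


@dataclass
class AtomEnvironment:
    center: int
    neighbor_count: int
    bin_counts: np.ndarray
    probabilities: np.ndarray
    entropy: float


def signed_tetrahedron_volume(r_i, r_j, r_k, r_l) -> float:
    """Signed volume (1/6) (r_j-r_i) . ((r_k-r_i) x (r_l-r_i))."""
    r_i = np.asarray(r_i, float)
    a = np.asarray(r_j, float) - r_i
    b = np.asarray(r_k, float) - r_i
    c = np.asarray(r_l, float) - r_i
    return float(np.dot(a, np.cross(b, c))) / 6.0


def _canonical_neighbor_order(center_coords, neighbor_atoms):
    """Sort neighbors by distance from the center; ties break on coords."""
    def key(atom):
        d = float(np.linalg.norm(atom.coords - center_coords))
        return (d, atom.coords[0], atom.coords[1], atom.coords[2])
    return sorted(neighbor_atoms, key=key)


def enumerate_tetrahedra(structure: Structure) -> list[Tetrahedron]:
    """All center+3-neighbor tetrahedra over the inferred bond graph.

    Atoms with fewer than three bonded neighbors contribute none; an atom
    with k >= 3 neighbors contributes C(k, 3) tetrahedra.
    """
    serial_map = structure._serial_map()
    adj = structure.adjacency()
    tets: list[Tetrahedron] = []
    for atom in structure.atoms:
        nbr_serials = adj[atom.serial]
        if len(nbr_serials) < 3:
            continue
        nbrs = _canonical_neighbor_order(
            atom.coords, [serial_map[s] for s in nbr_serials])
        for trio in combinations(nbrs, 3):
            v = signed_tetrahedron_volume(
                atom.coords, trio[0].coords, trio[1].coords, trio[2].coords)
            tets.append(Tetrahedron(atom.serial,
                                    tuple(t.serial for t in trio), v))
    return tets


def compute_lta(structure: Structure,
                tetrahedra: list[Tetrahedron] | None = None) -> dict:
    """LTA = mean(V) / mean(|V|) over all tetrahedra.

    Returns ``{"lta", "mean_abs_volume", "n_tetrahedra"}``.
    """
    tets = enumerate_tetrahedra(structure) if tetrahedra is None else tetrahedra
    if not tets:
        raise UndefinedDescriptorError(
            "LTA", "no atom has three or more bonded neighbors")
    vols = np.array([t.signed_volume for t in tets])
    vbar = float(np.abs(vols).mean())
    if vbar == 0.0:
        import warnings
        warnings.warn("all tetrahedral volumes are zero; LTA set to 0")
        lta = 0.0
    else:
        lta = float(vols.mean()) / vbar
    return {"lta": lta, "mean_abs_volume": vbar, "n_tetrahedra": len(tets)}


def _angular_bin_indices(rel: np.ndarray,
                         theta_bin_deg: float,
                         phi_bin_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) bin index per relative position vector."""
    r = np.linalg.norm(rel, axis=1)
    n_theta = int(round(180.0 / theta_bin_deg))
    n_phi = int(round(360.0 / phi_bin_deg))
    cos_t = np.clip(rel[:, 2] / r, -1.0, 1.0)
    theta_deg = np.degrees(np.arccos(cos_t))
    ti = np.minimum((theta_deg // theta_bin_deg).astype(int), n_theta - 1)
    phi_deg = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
    pi_ = np.minimum((phi_deg // phi_bin_deg).astype(int), n_phi - 1)
    return ti, pi_


def angular_entropy(center, neighbors,
                    theta_bin_deg: float = THETA_BIN_DEG,
                    phi_bin_deg: float = PHI_BIN_DEG,
                    log_base: float = math.e,
                    center_serial: int = -1) -> AtomEnvironment:
    """Shannon entropy of the (theta, phi) histogram of neighbor directions.

    theta is the polar angle against the frame's +z, phi the azimuth; bin
    widths must divide 180 and 360 degrees exactly.  Empty bins contribute
    zero (0 log 0 := 0); entropy is in nats by default.
    """
    if not (math.isclose(180.0 % theta_bin_deg, 0.0, abs_tol=1e-9)
            or math.isclose(180.0 % theta_bin_deg, theta_bin_deg,
                            abs_tol=1e-9)):
        raise ValueError("theta bin width must divide 180 degrees")
    if not (math.isclose(360.0 % phi_bin_deg, 0.0, abs_tol=1e-9)
            or math.isclose(360.0 % phi_bin_deg, phi_bin_deg, abs_tol=1e-9)):
        raise ValueError("phi bin width must divide 360 degrees")
    neighbors = np.atleast_2d(np.asarray(neighbors, float))
    if neighbors.shape[0] == 0:
        raise ValueError("angular entropy needs at least one neighbor")
    rel = neighbors - np.asarray(center, float)
    n_theta = int(round(180.0 / theta_bin_deg))
    n_phi = int(round(360.0 / phi_bin_deg))
    ti, pi_ = _angular_bin_indices(rel, theta_bin_deg, phi_bin_deg)
    counts = np.zeros((n_theta, n_phi), dtype=int)
    np.add.at(counts, (ti, pi_), 1)
    p = counts[counts > 0].astype(float) / counts.sum()
    entropy = float(-(p * np.log(p)).sum())
    if log_base != math.e:
        entropy /= math.log(log_base)
    probs = counts.astype(float) / counts.sum()
    return AtomEnvironment(center_serial, len(rel), counts, probs, entropy)


def compute_aes(structure: Structure, cutoff: float = AES_CUTOFF,
                theta_bin_deg: float = THETA_BIN_DEG,
                phi_bin_deg: float = PHI_BIN_DEG,
                log_base: float = math.e) -> dict:
    """AES = mean angular entropy over all atoms with >= 1 spatial neighbor.

    The neighbor set of an atom is every other heavy atom within ``cutoff``
    (spatial, not bonded).  The structure must already be in the membrane
    frame: the polar axis of the histogram is +z.
    """
    coords = structure.coords
    if len(coords) == 0:
        raise UndefinedDescriptorError("AES", "empty structure")
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, cutoff)
    per_atom: list[AtomEnvironment] = []
    for i, nbrs in enumerate(neighbor_lists):
        nbrs = [j for j in nbrs if j != i]
        if not nbrs:
            continue
        env = angular_entropy(coords[i], coords[nbrs],
                              theta_bin_deg, phi_bin_deg, log_base,
                              center_serial=structure.atoms[i].serial)
        per_atom.append(env)
    if not per_atom:
        raise UndefinedDescriptorError(
            "AES", f"no atom has a neighbor within {cutoff} A")
    aes = float(np.mean([e.entropy for e in per_atom]))
    return {"aes": aes, "per_atom": per_atom}


def export_atom_environments(per_atom, path) -> None:
    """TSV export: serial, neighbor_count, entropy per atom."""
    with open(path, "w") as fh:
        fh.write("serial\tneighbor_count\tentropy\n")
        for env in per_atom:
            fh.write(f"{env.center}\t{env.neighbor_count}\t"
                     f"{env.entropy!r}\n")


def per_residue_field(structure: Structure,
                      cutoff: float = AES_CUTOFF,
                      theta_bin_deg: float = THETA_BIN_DEG,
                      phi_bin_deg: float = PHI_BIN_DEG,
                      log_base: float = math.e):
    """Per-residue local chirality: [LTA_i, AES_i] for every residue.

    LTA_i averages the signed volumes of tetrahedra whose *center* atom
    lies in residue i, normalized by the structure-global mean absolute
    volume; residues without qualifying tetrahedra get NaN.  AES_i is the
    mean entropy over the residue's atoms (atoms without neighbors are
    skipped; NaN if none have neighbors).

    Returns a list of ``(chain_id, residue_index, lta_i, aes_i)``.
    """
    tets = enumerate_tetrahedra(structure)
    serial_map = structure._serial_map()
    vbar = None
    if tets:
        vols = np.array([t.signed_volume for t in tets])
        vbar = float(np.abs(vols).mean())
    tet_by_res: dict[tuple, list[float]] = {}
    for t in tets:
        atom = serial_map[t.center]
        key = (atom.chain_id, atom.residue_index)
        tet_by_res.setdefault(key, []).append(t.signed_volume)

    try:
        aes_res = compute_aes(structure, cutoff, theta_bin_deg,
                              phi_bin_deg, log_base)
        ent_by_serial = {e.center: e.entropy for e in aes_res["per_atom"]}
    except UndefinedDescriptorError:
        ent_by_serial = {}

    entries = []
    for chain_id, res_idx, atoms in structure.residues():
        key = (chain_id, res_idx)
        vols_i = tet_by_res.get(key)
        if vols_i and vbar:
            lta_i = float(np.mean(vols_i)) / vbar
        else:
            lta_i = float("nan")
        ents = [ent_by_serial[a.serial] for a in atoms
                if a.serial in ent_by_serial]
        aes_i = float(np.mean(ents)) if ents else float("nan")
        entries.append((chain_id, res_idx, lta_i, aes_i))
    return entries
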
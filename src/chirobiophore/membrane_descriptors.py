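"""Membrane-referenced descriptors: DDP, LAI, OTS and the tensor-skew
auxiliary.

All operations here assume the structure is expressed in the membrane
frame (center of mass at the origin, membrane normal along +z).

* DDP (Directional/Depth Density Profile): skewness of the atom-density
  distribution along z.  Two modes are kept: ``normalized`` (counts
  divided by the total, the standard count-weighted skewness) and ``raw``
  (the literal sum (1/(sigma^3 N)) sum_b (z_b - mu)^3 n_b over N bins with
  raw counts n_b, which scales with atom count).  The extended moment
  vector [mu_z, skewness, kurtosis] and its Euclidean norm are also
  provided; kurtosis is non-excess (a Gaussian gives 3).
* LAI (Leaflet Asymmetry Index): (N_upper - N_lower)/(N_upper + N_lower)
  over atoms above/below the midplane z = 0.  Atoms exactly on the
  midplane belong to neither leaflet, preserving exact antisymmetry under
  z-mirroring.  A weighted variant accepts per-site magnitudes.
* OTS (Orientation Twist Score): handedness-signed mean tilt of annotated
  helix axes against the membrane normal, OTS = (1/n) sum_i s_i theta_i,
  with s_i from the backbone pseudo-torsion sign and theta_i =
  arccos(v_i . z).  A vectorial form (1/n) sum_i s_i v_i is reported
  alongside.
* Orientation tensor skew: ((l3-l2) - (l2-l1)) / (l1+l2+l3) over the
  sorted gyration-tensor eigenvalues — a shape anisotropy measure (0 for a
  cube, +1 for a rod, -0.5 for a disc), reported separately from the
  twist score and never conflated with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .backbone_chirality import helix_handedness
from .errors import (ChirobiophoreError, DegenerateProfileError,
                     UndefinedDescriptorError)
from .membrane_frame import MIN_HELIX_CA, helix_axis
from .structure_io import ATOMIC_MASSES, Structure

DEFAULT_N_BINS = 50


@dataclass
class DensityProfile:
    """Binned z-density plus the first two moments of the underlying
    z-values.  ``mu`` and ``sigma`` are the count-weighted (population)
    mean and SD of the atom z-coordinates themselves; the bins are the
    substrate for the skewness sums."""

    bin_centers: np.ndarray    # z_b, A
    counts: np.ndarray         # n_b
    total_atoms: int
    mu: float                  # mean of atom z-values
    sigma: float               # population SD of atom z-values
    z_values: np.ndarray = None

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class DDPMoments:
    mean_z: float
    skewness: float
    kurtosis: float            # non-excess; Gaussian -> 3

    @property
    def norm(self) -> float:
        return math.sqrt(self.mean_z ** 2 + self.skewness ** 2
                         + self.kurtosis ** 2)


@dataclass
class HelixTilt:
    axis: np.ndarray           # unit helix axis in the membrane frame
    tilt: float                # radians in [0, pi]
    handedness: int            # +1 right, -1 left


def density_profile(structure: Structure,
                    n_bins: int = DEFAULT_N_BINS) -> DensityProfile:
    """Histogram of atom z-coordinates over uniform bins spanning the
    structure's z-extent; moments are computed from the binned profile."""
    z = structure.coords[:, 2]
    if len(z) < 2:
        raise DegenerateProfileError("need at least two atoms")
    zmin, zmax = float(z.min()), float(z.max())
    if zmax - zmin == 0.0:
        raise DegenerateProfileError("zero z-extent")
    width = (zmax - zmin) / n_bins
    idx = np.minimum(((z - zmin) // width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    centers = zmin + (np.arange(n_bins) + 0.5) * width
    mu = float(z.mean())
    sigma = float(z.std())
    return DensityProfile(centers, counts, int(counts.sum()), mu, sigma,
                          z_values=z.copy())


def compute_ddp(profile: DensityProfile, mode: str = "normalized") -> float:
    """Skewness of the binned z-density.

    ``normalized`` uses probabilities n_b / total (dimensionless, O(1));
    ``raw`` evaluates the literal (1/(sigma^3 N)) sum (z_b-mu)^3 n_b with
    raw counts and the number of bins N, which grows with atom count.
    """
    if profile.sigma == 0.0:
        raise UndefinedDescriptorError("DDP", "zero z spread")
    dev3 = (profile.bin_centers - profile.mu) ** 3
    if mode == "normalized":
        p = profile.counts / profile.total_atoms
        return float((dev3 * p).sum() / profile.sigma ** 3)
    if mode == "raw":
        return float((dev3 * profile.counts).sum()
                     / (profile.sigma ** 3 * profile.n_bins))
    raise ValueError(f"unknown DDP mode {mode!r}")


def ddp_moments(profile: DensityProfile) -> DDPMoments:
    """Count-weighted mean, skewness and (non-excess) kurtosis of the
    binned z-density, packaged with their Euclidean norm."""
    if profile.sigma == 0.0:
        raise UndefinedDescriptorError("DDP", "zero z spread")
    z = profile.z_values if profile.z_values is not None \
        else np.repeat(profile.bin_centers, profile.counts)
    dev = z - profile.mu
    skew = float((dev ** 3).mean() / profile.sigma ** 3)
    kurt = float((dev ** 4).mean() / profile.sigma ** 4)
    return DDPMoments(profile.mu, skew, kurt)


def compute_lai(structure: Structure, selection: str = "all_heavy") -> float:
    """(N_upper - N_lower)/(N_upper + N_lower) about the midplane z = 0.

    Atoms exactly at z = 0 count toward neither leaflet.  ``selection``
    chooses all heavy atoms (default) or the C-alpha trace only.
    """
    if selection == "all_heavy":
        z = structure.coords[:, 2]
    elif selection == "ca_only":
        z = np.array([a.coords[2] for a in structure.atoms
                      if a.name.strip() == "CA" and a.element == "C"])
    else:
        raise ValueError(f"unknown selection {selection!r}")
    n_upper = int((z > 0).sum())
    n_lower = int((z < 0).sum())
    if n_upper + n_lower == 0:
        raise UndefinedDescriptorError(
            "LAI", "no atom off the membrane midplane")
    return (n_upper - n_lower) / (n_upper + n_lower)


def compute_lai_weighted(values_upper, values_lower) -> float:
    """Weighted leaflet asymmetry over per-site magnitudes |w|:
    (sum_upper - sum_lower) / (sum_upper + sum_lower), in [-1, 1]."""
    wu = float(np.sum(np.abs(values_upper))) if len(values_upper) else 0.0
    wl = float(np.sum(np.abs(values_lower))) if len(values_lower) else 0.0
    if wu + wl == 0.0:
        raise UndefinedDescriptorError("LAI_weighted", "zero total weight")
    return (wu - wl) / (wu + wl)


def compute_ots(structure: Structure, flip_torsion_sign: bool = False) -> dict:
    """Handedness-signed mean helix tilt and its vectorial companion.

    Uses every annotated helix with at least four resolved C-alpha atoms.
    Returns ``{"ots", "per_helix", "vector_ots"}``.
    """
    tilts: list[HelixTilt] = []
    for hel in structure.helices:
        pts = structure.helix_ca_coords(hel)
        if len(pts) < MIN_HELIX_CA:
            continue
        ha = helix_axis(pts, hel)
        tilt = math.acos(max(-1.0, min(1.0, float(ha.axis[2]))))
        try:
            s = helix_handedness(pts, flip_sign=flip_torsion_sign)
        except ChirobiophoreError:
            continue
        tilts.append(HelixTilt(ha.axis, tilt, s))
    if not tilts:
        raise UndefinedDescriptorError(
            "OTS", "no annotated helix with >= 4 C-alpha atoms")
    ots = float(np.mean([t.handedness * t.tilt for t in tilts]))
    vec = np.mean([t.handedness * t.axis for t in tilts], axis=0)
    return {"ots": ots, "per_helix": tilts, "vector_ots": vec}


def export_density_profile(profile: DensityProfile, path) -> None:
    """Two-column TSV: bin center z (A), atom count."""
    with open(path, "w") as fh:
        fh.write("z_center\tcount\n")
        for z, n in zip(profile.bin_centers, profile.counts):
            fh.write(f"{z!r}\t{int(n)}\n")


def export_helix_tilts(tilts, path) -> None:
    """CSV: helix index, tilt (rad), handedness."""
    with open(path, "w") as fh:
        fh.write("helix_id,tilt_rad,handedness\n")
        for i, t in enumerate(tilts):
            fh.write(f"{i},{t.tilt!r},{t.handedness}\n")


def orientation_tensor_skew(structure: Structure,
                            weights: str = "uniform") -> float:
    """Eigenvalue skew of the gyration tensor about the center of mass.

    ((l3 - l2) - (l2 - l1)) / (l1 + l2 + l3), eigenvalues ascending.
    """
    coords = structure.coords
    if len(coords) < 3:
        raise UndefinedDescriptorError("tensor_skew", "need >= 3 atoms")
    if weights == "uniform":
        w = np.ones(len(coords))
    elif weights == "mass":
        w = np.array([ATOMIC_MASSES.get(a.element, 12.0)
                      for a in structure.atoms])
    else:
        raise ValueError(f"unknown weights {weights!r}")
    com = (coords * w[:, None]).sum(axis=0) / w.sum()
    dev = coords - com
    T = (w[:, None, None] * dev[:, :, None] * dev[:, None, :]).sum(axis=0)
    evals = np.sort(np.linalg.eigvalsh(T))
    total = float(evals.sum())
    if total == 0.0:
        raise UndefinedDescriptorError("tensor_skew", "all atoms coincident")
    l1, l2, l3 = (float(v) for v in evals)
    return ((l3 - l2) - (l2 - l1)) / total
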
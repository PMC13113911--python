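"""Membrane reference frame: COM centering and helix-axis alignment to +z.

All membrane-referenced descriptors (AES binning, DDP, LAI, OTS) are
computed in a frame where the protein center of mass sits at the origin and
the mean transmembrane-helix axis points along +z (the membrane normal).
The frame is derived from the structure itself, so descriptors become
invariant under rigid motion of the input coordinates.

Conventions (the deposited structures do not record membrane sidedness):

* the +z sign is chosen so that the first annotated helix runs N- to
  C-terminal with a non-negative z component;
* the in-plane rotation is fixed by mapping the largest in-plane gyration
  axis to x, with the x sign chosen so the third moment of the x
  coordinates is non-negative.  This pins the azimuthal bin registration
  of the angular-entropy descriptor; the descriptors themselves are
  insensitive to an x flip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FrameUndefinedError, TooShortHelixError
from .structure_io import ATOMIC_MASSES, HelixAnnotation, Structure

MIN_HELIX_CA = 4
LOCAL_WINDOW = 7  # residues per sliding-window axis fit


@dataclass
class MembraneFrame:
    """Rigid transform: coords' = rotation @ (coords + translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        # a reflection here would silently invert every chirality sign
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det -1 (improper rotation)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, float) + self.translation) @ self.rotation.T

    def inverse(self) -> "MembraneFrame":
        R = self.rotation
        return MembraneFrame(R.T, -(R @ self.translation))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.ravel().tolist(),
                "translation": self.translation.tolist()}


@dataclass
class HelixAxis:
    """Global and sliding-window axes of one annotated helix."""

    helix: HelixAnnotation | None
    axis: np.ndarray
    centroid: np.ndarray
    local_axes: list

    @property
    def n_points(self) -> int:
        return len(self.local_axes)


def _principal_direction(points: np.ndarray) -> np.ndarray:
    """Unit dominant principal direction of a point set (sign arbitrary)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0] / np.linalg.norm(vt[0])


def helix_axis(ca_coords: np.ndarray,
               helix: HelixAnnotation | None = None) -> HelixAxis:
    """Fit global and local axes through an ordered C-alpha trace.

    The global axis is the dominant principal direction of the point set,
    sign-fixed to run from the centroid of the N-terminal half toward the
    centroid of the C-terminal half.  Local axes come from a 7-residue
    sliding window (shrunk to >= 4 residues at the termini), each
    sign-aligned with the global axis.
    """
    pts = np.asarray(ca_coords, dtype=float)
    n = len(pts)
    if n < MIN_HELIX_CA:
        raise TooShortHelixError(f"need >= {MIN_HELIX_CA} C-alpha, got {n}")
    axis = _principal_direction(pts)
    half = n // 2
    direction = pts[n - half:].mean(axis=0) - pts[:half].mean(axis=0)
    if np.dot(axis, direction) < 0:
        axis = -axis
    local_axes = []
    hw = LOCAL_WINDOW // 2
    for j in range(n):
        lo, hi = max(0, j - hw), min(n, j + hw + 1)
        if hi - lo < MIN_HELIX_CA:
            # widen toward the interior so terminal windows keep >= 4 points
            if lo == 0:
                hi = min(n, MIN_HELIX_CA)
            else:
                lo = max(0, hi - MIN_HELIX_CA)
        window = pts[lo:hi]
        la = _principal_direction(window)
        if np.dot(la, axis) < 0:
            la = -la
        local_axes.append(la)
    return HelixAxis(helix, axis, pts.mean(axis=0), local_axes)


def center_of_mass(structure: Structure, mode: str = "mass") -> np.ndarray:
    coords = structure.coords
    if mode == "geometric":
        return coords.mean(axis=0)
    if mode != "mass":
        raise ValueError(f"unknown com mode {mode!r}")
    masses = np.array([ATOMIC_MASSES.get(a.element, 12.0)
                       for a in structure.atoms])
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def _usable_helix_axes(structure: Structure):
    out = []
    for hel in structure.helices:
        pts = structure.helix_ca_coords(hel)
        if len(pts) >= MIN_HELIX_CA:
            out.append((hel, helix_axis(pts, hel)))
    return out


def compute_membrane_frame(structure: Structure,
                           com_mode: str = "mass",
                           flip_normal: bool = False,
                           normal: np.ndarray | None = None) -> MembraneFrame:
    """Derive the membrane frame from annotated transmembrane helices.

    The membrane normal is the dominant principal direction of the helix
    axis vectors (each weighted by helix length); ``normal`` overrides the
    helix-based estimate for structures without usable annotations.
    """
    com = center_of_mass(structure, com_mode)
    if normal is not None:
        z = np.asarray(normal, float)
        nz = np.linalg.norm(z)
        if nz == 0:
            raise ValueError("explicit normal must be non-zero")
        z = z / nz
    else:
        axes = _usable_helix_axes(structure)
        if not axes:
            raise FrameUndefinedError(
                "no annotated helix with >= 4 resolved C-alpha atoms; "
                "supply an explicit membrane normal")
        M = np.zeros((3, 3))
        for hel, ha in axes:
            w = float(hel.length)
            M += w * np.outer(ha.axis, ha.axis)
        evals, evecs = np.linalg.eigh(M)
        z = evecs[:, np.argmax(evals)]
        # sign: first annotated helix points N->C "up"
        if np.dot(z, axes[0][1].axis) < 0:
            z = -z
    if flip_normal:
        z = -z

    centered = structure.coords - com
    # in-plane gyration: largest in-plane axis becomes x
    proj = centered - np.outer(centered @ z, z)
    gyr = proj.T @ proj
    # restrict to the plane orthogonal to z via an orthonormal plane basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, z)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, z) * z
    u /= np.linalg.norm(u)
    v = np.cross(z, u)
    plane = np.stack([u, v])                # 2x3
    gyr2 = plane @ gyr @ plane.T            # 2x2 in-plane gyration
    w2, e2 = np.linalg.eigh(gyr2)
    x = e2[:, np.argmax(w2)] @ plane
    x /= np.linalg.norm(x)
    # deterministic x sign: non-negative third moment along x
    m3 = float(np.sum((centered @ x) ** 3))
    if m3 < 0:
        x = -x
    y = np.cross(z, x)
    R = np.stack([x, y, z])                 # rows are the new basis
    return MembraneFrame(R, -com)


def apply_frame(structure: Structure, frame: MembraneFrame) -> Structure:
    """Return the structure expressed in the given membrane frame."""
    return structure.with_coords(frame.transform(structure.coords))


def frame_structure(structure: Structure, **kwargs) -> Structure:
    """Convenience: compute and apply the membrane frame in one step."""
    return apply_frame(structure, compute_membrane_frame(structure, **kwargs))
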
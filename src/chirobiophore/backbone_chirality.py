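"""Backbone handedness from C-alpha pseudo-torsions.

A four-residue window of consecutive C-alpha atoms defines a pseudo-torsion

    b1 = r2 - r1,  b2 = r3 - r2,  b3 = r4 - r3
    n1 = b1 x b2,  n2 = b2 x b3
    theta = atan2(|b2| (b1 . n2), n1 . n2)       in (-pi, pi]

whose sign encodes the local handedness of the backbone path.  HPC
(Helical Path Curvature) is the mean of sign(theta) over every valid
window: +1 for a uniformly right-handed trace, -1 for its mirror image.

Under this convention an ideal right-handed alpha-helix has theta of about
+0.87 rad in every window.  A ``flip_sign`` option negates all torsions for
users who prefer the opposite sign convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ChirobiophoreError, UndefinedDescriptorError
from .structure_io import Structure

CHAIN_BREAK_DISTANCE = 4.5   # A between consecutive C-alpha
SIGN_EPSILON = 1e-6          # |theta| below this counts as sign 0


@dataclass
class TorsionWindow:
    chain_id: str
    ca_indices: tuple          # 4 consecutive residue indices
    theta: float               # radians, signed


def torsion_angle(r1, r2, r3, r4) -> float:
    """Signed pseudo-torsion of four points; NaN if degenerate (collinear)."""
    r1, r2, r3, r4 = (np.asarray(v, float) for v in (r1, r2, r3, r4))
    b1, b2, b3 = r2 - r1, r3 - r2, r4 - r3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) == 0.0 or np.linalg.norm(n2) == 0.0:
        return float("nan")
    return math.atan2(np.linalg.norm(b2) * np.dot(b1, n2), np.dot(n1, n2))


def _contiguous_runs(trace):
    """Split an ordered C-alpha trace at chain breaks (> 4.5 A gaps)."""
    runs, current = [], []
    prev = None
    for idx, coords in trace:
        if prev is not None and np.linalg.norm(coords - prev) \
                > CHAIN_BREAK_DISTANCE:
            if len(current) >= 2:
                runs.append(current)
            current = []
        current.append((idx, coords))
        prev = coords
    if current:
        runs.append(current)
    return runs


def iter_torsion_windows(structure: Structure, helices_only: bool = False,
                         flip_sign: bool = False):
    """All valid four-residue C-alpha torsion windows of the structure.

    Windows never span chain breaks; windows with collinear points are
    skipped.  With ``helices_only`` the trace is restricted to annotated
    helix residues.
    """
    allowed = None
    if helices_only:
        allowed = set()
        for hel in structure.helices:
            for r in range(hel.start_residue, hel.end_residue + 1):
                allowed.add((hel.chain_id, r))
    sign = -1.0 if flip_sign else 1.0
    for chain_id, trace in structure.ca_trace().items():
        if allowed is not None:
            trace = [(i, c) for i, c in trace if (chain_id, i) in allowed]
        for run in _contiguous_runs(trace):
            for k in range(len(run) - 3):
                quad = run[k:k + 4]
                theta = torsion_angle(*(c for _, c in quad))
                if math.isnan(theta):
                    continue
                yield TorsionWindow(chain_id,
                                    tuple(i for i, _ in quad),
                                    sign * theta)


def compute_hpc(structure: Structure, helices_only: bool = False,
                flip_sign: bool = False) -> dict:
    """HPC = mean of sign(theta) over all valid torsion windows.

    Windows with |theta| below machine-noise threshold count as sign 0 but
    stay in the denominator.  Returns ``{"hpc", "m_windows", "torsions"}``.
    """
    windows = list(iter_torsion_windows(structure, helices_only, flip_sign))
    if not windows:
        raise UndefinedDescriptorError(
            "HPC", "no valid four-residue C-alpha window")
    signs = [0.0 if abs(w.theta) < SIGN_EPSILON else math.copysign(1.0, w.theta)
             for w in windows]
    return {"hpc": float(np.mean(signs)), "m_windows": len(windows),
            "torsions": windows}


def export_torsions(windows, path) -> None:
    """CSV export: chain, first residue index, theta (rad), sign."""
    with open(path, "w") as fh:
        fh.write("chain,residue_index,theta_rad,sign\n")
        for w in windows:
            s = 0 if abs(w.theta) < SIGN_EPSILON \
                else int(math.copysign(1, w.theta))
            fh.write(f"{w.chain_id},{w.ca_indices[0]},{w.theta!r},{s}\n")


def helix_handedness(ca_coords, flip_sign: bool = False) -> int:
    """Handedness sign of a helix: sign of its mean C-alpha pseudo-torsion.

    Returns +1 (right-handed) or -1 (left-handed); a zero mean ties to +1
    with a warning.  Raises if every window is degenerate (straight line).
    """
    pts = np.asarray(ca_coords, float)
    if len(pts) < 4:
        raise ChirobiophoreError("handedness needs >= 4 C-alpha positions")
    thetas = []
    for k in range(len(pts) - 3):
        t = torsion_angle(*pts[k:k + 4])
        if not math.isnan(t):
            thetas.append(t)
    if not thetas:
        raise ChirobiophoreError(
            "handedness undefined: all torsion windows degenerate")
    mean = float(np.mean(thetas))
    if flip_sign:
        mean = -mean
    if mean == 0.0:
        warnings.warn("zero mean torsion; handedness tie-broken to +1")
        return 1
    return 1 if mean > 0 else -1
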
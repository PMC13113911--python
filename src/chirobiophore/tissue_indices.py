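"""Tissular indices: fixed linear projections of standardized descriptors.

Eleven proposed molecular-to-tissue asymmetry indices, each a weighted
linear combination of the z-scored chirality descriptors; collected into
a projection matrix W (11 x 6) so that T = W @ C-tilde.  The coefficients
are illustrative model definitions, not regression fits, and the indices
carry no clamping: TPI = OTS~ + LAI~ can exceed [-1, 1].

Note: the MCI and API rows are identical linear combinations
(AES~ + LTA~ + DDP~).  Both are kept verbatim as defined; the duplication
is documented rather than "fixed".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .chirality_space import DESCRIPTOR_NAMES, DescriptorMatrix

INDEX_NAMES = ["PSI", "RBI", "PDI", "MECI", "TMOI", "HRS",
               "ABAI", "TPI", "MCI", "FCI", "API"]

# rows over columns [LTA, HPC, AES, DDP, LAI, OTS]
INDEX_WEIGHTS = pd.DataFrame(
    [
        [0.0, 0.0, 0.0, 0.6, 0.4, 0.0],    # PSI  = 0.6 DDP + 0.4 LAI
        [0.0, 0.3, 0.0, 0.0, 0.0, 0.7],    # RBI  = 0.7 OTS + 0.3 HPC
        [0.5, 0.0, 0.5, 0.0, 0.0, 0.0],    # PDI  = 0.5 AES + 0.5 LTA
        [0.0, 0.0, 0.0, 0.5, 0.0, -0.5],   # MECI = 0.5 (DDP - OTS)
        [0.0, 0.0, 0.0, 0.0, 0.4, 0.6],    # TMOI = 0.6 OTS + 0.4 LAI
        [0.5, 0.5, 0.0, 0.0, 0.0, 0.0],    # HRS  = 0.5 HPC + 0.5 LTA
        [0.0, 0.0, 0.0, 0.5, 0.5, 0.0],    # ABAI = 0.5 DDP + 0.5 LAI
        [0.0, 0.0, 0.0, 0.0, 1.0, 1.0],    # TPI  = OTS + LAI
        [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],    # MCI  = AES + LTA + DDP
        [0.0, 1.0, 1.0, 0.0, 0.0, 1.0],    # FCI  = HPC + OTS + AES
        [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],    # API  = LTA + AES + DDP
    ],
    index=INDEX_NAMES, columns=DESCRIPTOR_NAMES,
)

# the same indices written out one formula at a time; kept as an internal
# consistency check of the matrix route
_FORMULAS = {
    "PSI": lambda d: 0.6 * d["DDP"] + 0.4 * d["LAI"],
    "RBI": lambda d: 0.7 * d["OTS"] + 0.3 * d["HPC"],
    "PDI": lambda d: 0.5 * d["AES"] + 0.5 * d["LTA"],
    "MECI": lambda d: 0.5 * (d["DDP"] - d["OTS"]),
    "TMOI": lambda d: 0.6 * d["OTS"] + 0.4 * d["LAI"],
    "HRS": lambda d: 0.5 * d["HPC"] + 0.5 * d["LTA"],
    "ABAI": lambda d: 0.5 * d["DDP"] + 0.5 * d["LAI"],
    "TPI": lambda d: d["OTS"] + d["LAI"],
    "MCI": lambda d: d["AES"] + d["LTA"] + d["DDP"],
    "FCI": lambda d: d["HPC"] + d["OTS"] + d["AES"],
    "API": lambda d: d["LTA"] + d["AES"] + d["DDP"],
}


def compute_indices(matrix: DescriptorMatrix,
                    weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Project a standardized descriptor matrix onto the tissular indices.

    Returns a DataFrame (structures x indices).  With the built-in weight
    matrix the result is cross-checked against the per-index formulas;
    ``weights`` accepts a custom (n x 6) matrix with named rows for
    user-defined index sets.
    """
    if not matrix.standardized:
        raise ValueError("tissular indices are defined on the standardized "
                         "descriptor matrix only")
    W = INDEX_WEIGHTS if weights is None else weights
    if list(W.columns) != DESCRIPTOR_NAMES:
        raise ValueError(f"weight columns must be {DESCRIPTOR_NAMES}")
    T = matrix.values @ W.to_numpy().T
    out = pd.DataFrame(T, index=matrix.ids, columns=list(W.index))
    if weights is None:
        for name, formula in _FORMULAS.items():
            d = {c: matrix.frame[c].to_numpy() for c in DESCRIPTOR_NAMES}
            expected = formula(d)
            if not np.allclose(out[name].to_numpy(), expected,
                               rtol=0, atol=1e-12):
                raise AssertionError(
                    f"matrix and formula routes disagree for {name}")
    return out


def export_indices(indices: pd.DataFrame, path) -> None:
    """CSV with header ``id,PSI,...,API`` and one row per structure."""
    out = indices.copy()
    out.insert(0, "id", out.index)
    out.to_csv(path, index=False)


def load_weights_csv(path) -> pd.DataFrame:
    """Custom weight matrix: CSV with a ``name`` column plus the six
    descriptor columns."""
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise ValueError("weights CSV needs a 'name' column")
    missing = [c for c in DESCRIPTOR_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"weights CSV lacks columns {missing}")
    return df.set_index("name")[DESCRIPTOR_NAMES]
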
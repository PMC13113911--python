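"""Chirality space: descriptor vectors, matrices, distances, PCA,
clustering and gradient fields.

Each structure maps to a six-component chirality vector
C = [LTA, HPC, AES, DDP, LAI, OTS]; a set of structures forms an N x 6
descriptor matrix.  Downstream analytics operate on the z-scored matrix:
Euclidean and variance-whitened distances, PCA of the standardized
columns (equivalently, the correlation-matrix eigendecomposition of the
raw ones), average-linkage hierarchical clustering, and kernel-smoothed
gradient fields of individual descriptors over the PC1-PC2 chart.

A packaged 9 x 6 reference matrix for nine membrane proteins (1C3W, 1F88,
1J4N, 2RH1, 3ODU, 4DKL, 2A79, 1C17, 1OTS) ships with the library; see
``load_reference_matrix``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from . import atomic_chirality, backbone_chirality, membrane_descriptors
from .config import RunConfig
from .errors import UndefinedDescriptorError
from .membrane_frame import apply_frame, compute_membrane_frame
from .structure_io import Structure, infer_bonds, load_structure

DESCRIPTOR_NAMES = ["LTA", "HPC", "AES", "DDP", "LAI", "OTS"]


@dataclass
class ChirobiophoreVector:
    """One structure's six-descriptor chirality vector plus auxiliaries."""

    id: str
    lta: float
    hpc: float
    aes: float
    ddp: float
    lai: float
    ots: float
    metadata: dict = field(default_factory=dict)
    auxiliaries: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.lta, self.hpc, self.aes,
                         self.ddp, self.lai, self.ots])

    def as_dict(self) -> dict:
        return dict(zip(DESCRIPTOR_NAMES, self.as_array().tolist()))


class DescriptorMatrix:
    """Labeled N x 6 table of chirality vectors, raw or z-scored."""

    def __init__(self, ids, values, standardized=False,
                 column_means=None, column_sds=None):
        self.frame = pd.DataFrame(np.asarray(values, float),
                                  index=list(ids),
                                  columns=DESCRIPTOR_NAMES)
        self.standardized = standardized
        self.column_means = column_means
        self.column_sds = column_sds

    @property
    def ids(self):
        return list(self.frame.index)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def __len__(self):
        return len(self.frame)

    @classmethod
    def from_vectors(cls, vectors) -> "DescriptorMatrix":
        return cls([v.id for v in vectors],
                   np.stack([v.as_array() for v in vectors]))

    @classmethod
    def from_csv(cls, path) -> "DescriptorMatrix":
        df = pd.read_csv(path)
        if "id" not in df.columns:
            raise ValueError("descriptor CSV needs an 'id' column")
        missing = [c for c in DESCRIPTOR_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"descriptor CSV lacks columns {missing}")
        return cls(df["id"].astype(str), df[DESCRIPTOR_NAMES].to_numpy())

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "id", out.index)
        out.to_csv(path, index=False)

    def dropna(self) -> "DescriptorMatrix":
        """Rows with any missing descriptor removed (with a warning)."""
        mask = self.frame.notna().all(axis=1)
        if not mask.all():
            dropped = list(self.frame.index[~mask])
            warnings.warn(f"excluding rows with missing descriptors: "
                          f"{dropped}")
        return DescriptorMatrix(self.frame.index[mask],
                                self.frame[mask].to_numpy(),
                                self.standardized,
                                self.column_means, self.column_sds)


@dataclass
class PCAResult:
    loadings: np.ndarray               # 6 x k, unit-norm columns
    explained_variance_ratio: np.ndarray
    scores: np.ndarray                 # N x k

    def oriented(self, rule: str = "max_abs_positive") -> np.ndarray:
        """Loadings under a deterministic sign convention.

        ``max_abs_positive`` orients each component so its largest-|loading|
        entry is positive.  Both orientations of every component describe
        the same subspace; printed loading tables are convention-dependent.
        """
        L = self.loadings.copy()
        for j in range(L.shape[1]):
            if L[np.argmax(np.abs(L[:, j])), j] < 0:
                L[:, j] = -L[:, j]
        return L


def load_reference_matrix() -> DescriptorMatrix:
    """The packaged 9 x 6 reference descriptor matrix.

    Descriptor values for the nine membrane proteins of the reference
    dataset, as originally reported.  These are documented reference
    values: several of them depend on conventions that cannot be
    reconstructed from the reported formulas alone (see docs/methods.md),
    so they serve PCA/clustering/index analytics and comparisons, not as
    ground truth for the descriptor pipeline.
    """
    with resources.files("chirobiophore.data") \
            .joinpath("reference_membrane9.csv").open() as fh:
        return DescriptorMatrix.from_csv(fh)


def assemble_vector(source, config: RunConfig | None = None,
                    structure_id: str | None = None,
                    normal=None) -> ChirobiophoreVector:
    """Run the full pipeline on a structure file or Structure.

    load -> bond inference -> membrane frame -> six descriptors.
    Undefined descriptors become NaN slots with a warning (the vector
    still reports the rest); the failing slot is named in the warning.
    ``normal`` supplies an explicit membrane normal for structures whose
    annotations cannot define one.
    """
    config = config or RunConfig()
    if isinstance(source, Structure):
        structure = source
    else:
        structure = load_structure(source)
    if not structure.bonds:
        structure = infer_bonds(structure, scale=config.bond_scale)
    frame = compute_membrane_frame(structure, com_mode=config.com_mode,
                                   flip_normal=config.flip_normal,
                                   normal=normal)
    framed = apply_frame(structure, frame)

    values = {}
    aux = {}

    def slot(name, fn):
        try:
            values[name] = fn()
        except UndefinedDescriptorError as exc:
            warnings.warn(f"descriptor undefined for "
                          f"{structure_id or structure.id}: {exc}")
            values[name] = float("nan")

    def lta():
        res = atomic_chirality.compute_lta(framed)
        aux["mean_abs_volume"] = res["mean_abs_volume"]
        aux["n_tetrahedra"] = res["n_tetrahedra"]
        return res["lta"]

    def hpc():
        res = backbone_chirality.compute_hpc(
            framed, helices_only=config.hpc_helices_only,
            flip_sign=config.flip_torsion_sign)
        aux["m_windows"] = res["m_windows"]
        return res["hpc"]

    def aes():
        res = atomic_chirality.compute_aes(
            framed, cutoff=config.cutoff, theta_bin_deg=config.theta_bin,
            phi_bin_deg=config.phi_bin, log_base=config.log_base_value)
        return res["aes"]

    def ddp():
        profile = membrane_descriptors.density_profile(
            framed, n_bins=config.z_bins)
        moments = membrane_descriptors.ddp_moments(profile)
        aux["ddp_moments"] = {"mean_z": moments.mean_z,
                              "skewness": moments.skewness,
                              "kurtosis": moments.kurtosis,
                              "norm": moments.norm}
        return membrane_descriptors.compute_ddp(profile, mode=config.ddp_mode)

    def lai():
        return membrane_descriptors.compute_lai(
            framed, selection=config.lai_selection)

    def ots():
        res = membrane_descriptors.compute_ots(
            framed, flip_torsion_sign=config.flip_torsion_sign)
        aux["vector_ots"] = res["vector_ots"].tolist()
        aux["per_helix_tilt"] = [
            {"tilt_rad": t.tilt, "handedness": t.handedness}
            for t in res["per_helix"]]
        return res["ots"]

    slot("LTA", lta)
    slot("HPC", hpc)
    slot("AES", aes)
    slot("DDP", ddp)
    slot("LAI", lai)
    slot("OTS", ots)
    try:
        aux["tensor_skew"] = membrane_descriptors.orientation_tensor_skew(
            framed)
    except UndefinedDescriptorError:
        aux["tensor_skew"] = float("nan")

    return ChirobiophoreVector(
        id=structure_id or structure.id,
        lta=values["LTA"], hpc=values["HPC"], aes=values["AES"],
        ddp=values["DDP"], lai=values["LAI"], ots=values["OTS"],
        metadata={"config": config.to_dict(), "frame": frame.to_dict()},
        auxiliaries=aux)


def standardize(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Per-column z-scoring with sample SD (ddof=1).

    Constant columns map to all zeros with a warning (their SD is zero,
    so no finite z-score exists).
    """
    if len(matrix) < 2:
        raise ValueError("standardization needs at least two rows")
    X = matrix.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    Z = np.zeros_like(X)
    for j, sd in enumerate(sds):
        if sd == 0.0:
            warnings.warn(f"constant column {DESCRIPTOR_NAMES[j]} "
                          "standardized to zeros")
            Z[:, j] = 0.0
        else:
            Z[:, j] = (X[:, j] - means[j]) / sd
    return DescriptorMatrix(matrix.ids, Z, standardized=True,
                            column_means=means, column_sds=sds)


def distance(c1, c2, metric: str = "euclidean", sds=None) -> float:
    """Distance between two chirality vectors.

    ``euclidean`` is the plain L2 norm of the difference; ``whitened``
    divides each component difference by the descriptor's standard
    deviation first (the diagonal variance-whitened metric).
    """
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    if metric == "euclidean":
        return float(np.linalg.norm(c1 - c2))
    if metric == "whitened":
        if sds is None:
            raise ValueError("whitened metric needs per-descriptor SDs")
        sds = np.asarray(sds, float)
        if np.any(sds <= 0):
            raise ValueError("whitened metric undefined for zero sigma")
        return float(np.linalg.norm((c1 - c2) / sds))
    raise ValueError(f"unknown metric {metric!r}")


def pca(matrix: DescriptorMatrix) -> PCAResult:
    """PCA of the standardized descriptor matrix.

    Eigendecomposition of the sample covariance of the z-scored columns
    (the correlation matrix of the raw data).  Explained-variance ratios
    are eigenvalue fractions; loading columns are unit-norm eigenvectors
    ordered by decreasing eigenvalue.  Eigenvector signs are as returned
    by the decomposition; use :meth:`PCAResult.oriented` for a fixed sign
    convention.
    """
    if not matrix.standardized:
        raise ValueError("PCA is defined on the standardized matrix")
    if len(matrix) < 3:
        raise ValueError("PCA needs at least three rows")
    Z = matrix.values
    cov = np.cov(Z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    ratios = evals / evals.sum()
    scores = Z @ evecs
    return PCAResult(evecs, ratios, scores)


def hcluster(matrix: DescriptorMatrix, method: str = "average") -> list:
    """Agglomerative clustering on Euclidean distances of the z-scored
    matrix.  Returns the merge list [(i, j, height), ...] in merge order;
    cluster indices follow the usual linkage numbering (new clusters get
    indices N, N+1, ...)."""
    if not matrix.standardized:
        raise ValueError("clustering is defined on the standardized matrix")
    if len(matrix) < 2:
        raise ValueError("clustering needs at least two rows")
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {method!r}")
    Z = linkage(pdist(matrix.values), method=method)
    return [(int(a), int(b), float(h)) for a, b, h, _ in Z]


def gradient_field(matrix: DescriptorMatrix, descriptor: str,
                   grid: int = 20, bandwidth: float | None = None) -> dict:
    """Kernel-smoothed gradient of one descriptor over the PC1-PC2 chart.

    The descriptor values are interpolated with a Gaussian kernel
    (Nadaraya-Watson; bandwidth defaults to the median pairwise PC-score
    distance) over a regular grid spanning the scores, and the gradient
    is taken by central finite differences.

    Returns ``{"grid_x", "grid_y", "value", "grad_x", "grad_y"}``.
    """
    if descriptor not in DESCRIPTOR_NAMES:
        raise ValueError(f"unknown descriptor {descriptor!r}")
    res = pca(matrix)
    pts = res.scores[:, :2]
    vals = matrix.frame[descriptor].to_numpy()
    d = pdist(pts)
    if np.all(d == 0):
        raise ValueError("all points coincide in the PC1-PC2 plane")
    if bandwidth is None:
        bandwidth = float(np.median(d[d > 0]))
    span = pts.max(axis=0) - pts.min(axis=0)
    lo = pts.min(axis=0) - 0.05 * span
    hi = pts.max(axis=0) + 0.05 * span
    gx = np.linspace(lo[0], hi[0], grid)
    gy = np.linspace(lo[1], hi[1], grid)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    P = np.stack([XX.ravel(), YY.ravel()], axis=1)
    d2 = ((P[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    W = np.exp(-0.5 * d2 / bandwidth ** 2)
    F = (W @ vals) / W.sum(axis=1)
    F = F.reshape(grid, grid)
    grad_x = np.gradient(F, gx, axis=0)
    grad_y = np.gradient(F, gy, axis=1)
    return {"grid_x": XX, "grid_y": YY, "value": F,
            "grad_x": grad_x, "grad_y": grad_y, "bandwidth": bandwidth}
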
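# chirobiophore

Coordinate-derived chirality descriptors for membrane protein structures.

Chirality in macromolecules is distributed: it lives in local atomic
geometry, in the torsional sense of the backbone, and in how a protein
embeds in its membrane — not only in R/S stereocenters.  This package
quantifies that distributed handedness.  It reads a PDB or mmCIF
structure, places it in a membrane reference frame (center of mass at the
origin, mean transmembrane-helix axis along +z), and computes six
descriptors that together form a chirality vector

```
C = [LTA, HPC, AES, DDP, LAI, OTS]
```

| slot | measures | definition |
|------|----------|------------|
| LTA  | atomic handedness | mean signed tetrahedron volume over atoms with ≥3 bonded neighbors, V = (1/6)(r_j−r_i)·((r_k−r_i)×(r_l−r_i)), normalized by mean \|V\|; in [−1, 1], exactly negated by mirroring |
| HPC  | backbone torsional coherence | mean sign of the Cα four-residue pseudo-torsion θ = atan2(‖b₂‖ b₁·n₂, n₁·n₂); +1 for a uniformly right-handed trace |
| AES  | packing asymmetry | mean Shannon entropy (nats) of each atom's (θ, φ) neighbor-direction histogram, 15° bins, 6 Å cutoff |
| DDP  | depth asymmetry | skewness of the atom-density distribution along the membrane normal |
| LAI  | leaflet bias | (N_upper − N_lower)/(N_upper + N_lower) about the midplane z = 0 |
| OTS  | signed helix tilt | (1/n) Σ s_i θ_i over annotated helices: tilt θ_i against the normal, sign s_i from backbone handedness (radians) |

On top of the per-structure vector the library provides the chirality-space
analytics: z-scoring, Euclidean and variance-whitened distances, PCA with
explained variance and loadings, hierarchical clustering, kernel-smoothed
descriptor gradient fields over the PC1–PC2 chart, eleven tissular-index
projections (T = W·C̃), and per-residue chirality fields with a residue
graph export.

Intended users: structural bioinformaticians comparing membrane-protein
architectures, and anyone needing frame-invariant handedness measures for
synthetic or designed structures.

## Worked example

Everything is testable without downloads via the synthetic generators.
Build a right-handed four-helix bundle (ideal α-geometry: 1.5 Å rise,
100°/residue, 2.3 Å radius) splayed 30° outward, with chiral
pseudo-side-chains so tetrahedra exist:

```
chirobiophore synth bundle --n-helices 4 --tilt 30 -n 20 \
    --decorations --noise-sd 0.03 --seed 5 --out bundle.pdb
chirobiophore compute bundle.pdb
```

prints (abridged):

```json
{
  "descriptors": {
    "AES": 3.081032998360759,
    "DDP": -0.0038530143200905297,
    "HPC": 1.0,
    "LAI": -0.0125,
    "LTA": -0.2767991010645015,
    "OTS": 0.523325131344395
  }
}
```

HPC = +1.0: every Cα pseudo-torsion of the right-handed trace is
positive.  OTS ≈ 0.523 rad ≈ 30°: four right-handed helices, each tilted
30° from the membrane normal, so the signed mean tilt is +π/6.  DDP and
LAI sit near zero because the bundle is symmetric about the midplane;
LTA reflects the fixed chirality of the decoration tetrahedra; AES is the
entropy of fairly uniform local environments.  Mirror the input and LTA,
HPC, OTS flip sign exactly while AES is unchanged — the package's central
invariance contract, enforced by the test suite.

A 9×6 reference descriptor matrix for nine membrane proteins
(1C3W, 1F88, 1J4N, 2RH1, 3ODU, 4DKL, 2A79, 1C17, 1OTS) ships with the
package:

```python
from chirobiophore import load_reference_matrix, standardize, pca
res = pca(standardize(load_reference_matrix()))
print(res.explained_variance_ratio[:2])   # [0.543 0.222]
```

PCA of the z-scored matrix puts 54.3% of the variance on PC1 and 22.2%
on PC2 (76.5% together), with the OTS loading dominating PC2 — membrane
twist orientation is the second axis of variation in this dataset.  See
`docs/methods.md` for conventions, parameter choices, and the known
inconsistencies in the reference values (they are documented inputs to
the analytics, not reproduction targets; `scripts/compare_reference.py`
prints recomputed vectors side by side with them for locally supplied
structure files).

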
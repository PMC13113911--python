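# Methods

This note records the model behind each descriptor, the conventions the
implementation fixes where the underlying definitions leave freedom, the
synthetic-data generators used as ground truth, and the known
limitations.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing and the membrane frame

Structures are reduced to protein heavy atoms: solvent and
hetero-compounds (HETATM records) are removed, hydrogens dropped (crystal
structures rarely resolve them, and including them where present would
bias comparisons), the first model of multi-model files is kept, and
alternate conformations resolve to the highest-occupancy location (ties
to the first in file — deterministic and the common convention).
Residues are indexed sequentially per chain in file order, ignoring
author-numbering gaps and insertion codes.  Helix boundaries come from
the deposited HELIX records (mmCIF `struct_conf`), clipped to resolved
residues; secondary-structure re-assignment (DSSP-style) is deliberately
out of scope so that helix definitions match the experimental curation.

Covalent bonds are inferred geometrically: two atoms bond iff their
distance is at most 1.15 × the sum of their covalent radii (built-in
table; C 0.76, N 0.71, O 0.66, S 1.05 Å, …).  This is label-agnostic —
no dependence on atom or residue names — and commutes with rigid motion.

The membrane frame puts the mass-weighted center of mass at the origin
and the membrane normal along +z.  The normal is the dominant principal
direction of the annotated helix-axis set, each axis weighted by helix
length so long transmembrane helices dominate short surface ones.  Two
sign conventions close the remaining gauge freedom, since deposited
structures carry no sidedness:

* **normal sign**: the first annotated helix points N→C "up"
  (non-negative z).  `--flip-normal` inverts it when biological
  sidedness is known.
* **in-plane rotation**: the largest in-plane gyration axis maps to +x,
  with the x sign chosen so the third moment of the x-coordinates is
  non-negative.  This matters only for the azimuthal bin registration of
  AES; all descriptors are insensitive to an x flip (AES exactly so, by
  bin symmetry).

The frame rotation always has det = +1 — a reflection here would invert
every chirality sign — and is validated on construction.  With the frame
recomputed from the moved coordinates, all six descriptors are invariant
under proper rigid motion to better than 1e-6 (enforced on twenty seeded
synthetic structures in the test suite).

## Descriptors

**LTA.**  For every atom with ≥3 bonded neighbors, each 3-combination of
neighbors forms a tetrahedron with signed volume
V = (1/6)(r_j−r_i)·((r_k−r_i)×(r_l−r_i));
LTA = mean(V)/mean(|V|) ∈ [−1, 1].  The scalar triple product is
antisymmetric under any neighbor swap, so the neighbor order must be
canonical for the sign to be well defined: neighbors are sorted by
distance from the center, ties broken lexicographically on
membrane-frame coordinates.  Distance sorting is rigid-invariant; the
lexicographic tie-break fires only on exact ties (measure zero in real
coordinates).  Mirror images yield exactly −LTA.

**HPC.**  Sliding four-residue windows over consecutive Cα atoms within
each chain; windows never span chain breaks (Cα–Cα gap > 4.5 Å, common
where loops are unresolved).  The pseudo-torsion uses the arctan2 form
θ = atan2(‖b₂‖(b₁·n₂), n₁·n₂) with n₁ = b₁×b₂, n₂ = b₂×b₃, which equals
the standard IUPAC dihedral (verified against an independent
projected-vector oracle to 1e-9 on 10³ random quadruples).  HPC is the
mean of sign(θ); |θ| < 1e-6 rad counts as sign 0 but stays in the
denominator, avoiding sign noise at machine precision.  Windows are
taken over the full chain — the restriction to annotated helices is
available as `--hpc-helices-only`.  Under this convention an ideal
right-handed α-helix (1.5 Å rise, 100°/residue, 2.3 Å radius) has
θ ≈ +0.873 rad in every window and HPC = +1.  Note that the reference
dataset reports negative HPC for α-helical proteins, which is
inconsistent with this (or the standard) sign convention; the
implementation follows the formula as defined and provides
`--flip-torsion-sign` for the opposite convention rather than silently
matching the reported signs.

**AES.**  Each atom's neighbors are all other heavy atoms within 6 Å —
spatial, not bonded: a bonded-only set would hold ≤4 atoms and give
degenerate entropies.  Neighbor directions are binned on the sphere
(polar θ against the frame's +z, azimuth φ; 15° bins in both → 12 × 24 =
288 bins; the azimuthal width mirrors the stated polar width and is
adjustable, with `--phi-bin 360` collapsing to 1-D polar binning).
S_i = −Σ p ln p over occupied bins (0·ln 0 := 0), natural log by default
(`--log-base 2` available); AES is the mean S_i over atoms with at least
one neighbor.  Entropy is bounded by ln(min(neighbors, 288)).

**DDP.**  Atoms are binned along z (50 uniform bins spanning the
z-extent by default; no bin count is prescribed by the underlying
definition, and the suite checks <5% sensitivity over 30–100 bins on
smooth clouds).  μ and σ are the count-weighted (population) mean and SD
of the atom z-values themselves, so closed-form cases are exact.  The
default `normalized` mode is the probability-weighted third moment of
the binned profile over σ³ — a dimensionless skewness, O(1).  The `raw`
mode evaluates the literal sum (1/(σ³N)) Σ_b (z_b−μ)³ n_b with raw
counts and bin count N; it scales with atom count and is retained
because the reference dataset's large DDP magnitudes (up to 40.33) are
reachable only on that scale.  The extended moment vector
[μ_z, skewness, kurtosis] uses non-excess kurtosis (Gaussian → 3) and
reports the Euclidean norm of the triple; μ_z is in Å while the other
two are dimensionless — the norm mixes units and is provided as defined.

**LAI.**  Count atoms strictly above and below z = 0 (the midplane after
COM centering).  Atoms exactly on the midplane join neither leaflet,
preserving exact antisymmetry under z-mirroring.  The weighted variant
accepts per-site magnitudes (e.g. per-residue |LTA_i|) in place of
counts.  Note a COM-centered structure can never reach |LAI| = 1 with
atoms on both sides; the reference value of 1.00 for one entry is
documented as-is and not targeted.

**OTS (twist score).**  For each annotated helix with ≥4 resolved Cα:
axis from a principal-direction fit (sign N→C), tilt θ_i = arccos(v_i·ẑ),
handedness s_i = sign of the mean Cα pseudo-torsion; OTS = mean(s_i θ_i),
in radians.  The vectorial form mean(s_i v_i) is reported alongside.  A
distinct quantity — the gyration-tensor eigenvalue skew
((λ₃−λ₂)−(λ₂−λ₁))/Σλ, −0.5 for a disc, +1 for a rod, 0 for a cube — is
exposed separately as `orientation_tensor_skew` and never conflated with
the twist score: the chirality vector's OTS slot is the twist score,
consistent with its radian-valued interpretation and the tilt-based
computation sequence.

## Chirality space, indices, fields

Standardization is per-column z-scoring with sample SD (ddof = 1);
constant columns map to zero with a warning (no finite z-score exists).
PCA is the eigendecomposition of the covariance of the z-scored matrix —
the correlation PCA of the raw data — so explained-variance ratios are
independent of the ddof choice.  Eigenvector signs are a convention;
results expose both a fixed orientation rule (largest-|loading| entry
positive) and the flipped alternative, and the reported PC2 OTS loading
uses the "LAI negative" orientation of the printed table.  Rows with
missing descriptors are excluded from PCA/clustering with a warning —
no imputation.  Clustering is average-linkage (default) on Euclidean
distances of the z-scored rows; the linkage choice is not prescribed, so
cluster-membership claims are treated qualitatively.  The whitened
distance divides per-descriptor differences by the descriptor SD and
equals the Euclidean distance on the z-scored matrix.  Gradient fields
interpolate one descriptor over the PC1–PC2 chart with a Gaussian
kernel (bandwidth: median pairwise score distance) and differentiate by
central differences.

The eleven tissular indices are fixed linear combinations of the
z-scored descriptors, applied as a single 11×6 projection matrix; the
matrix route is cross-checked against the individual formulas at run
time (1e-12).  The MCI and API rows are identical linear combinations as
defined; both are kept verbatim and the duplication documented rather
than repaired.  The coefficients are illustrative model definitions —
no regression fitting is performed; a custom weight CSV is accepted for
user-defined index sets.  No clamping is applied (TPI can exceed [−1,1]).

The per-residue field attaches [LTA_i, AES_i] to every residue (LTA_i
normalized by the structure-global mean |V|; residues without
tetrahedra carry NaN).  The residue graph connects residues within 8 Å
Cα distance (flag-settable) plus chain adjacency; it is an export
surface — spectral/topological analysis is out of scope.

## Synthetic generators and what they do (not) show

The generators provide exact ground truth: parametric helices with known
handedness (left = exact y-mirror of right), splayed bundles with
prescribed per-helix tilt and handedness (mean axis stays on z by
construction, so the recovered frame leaves each tilt equal to the set
value), z-clouds with known density laws (symmetric laws built from
exact mirror pairs, so skewness and leaflet asymmetry are analytically
zero), and chiral pseudo-methane clusters with four bonded neighbors at
distinct distances.  Because a bare Cα trace has no atoms at covalent
distances, helices can be decorated with three chiral
pseudo-side-chain atoms per residue (distinct bond lengths 1.40/1.50/
1.60 Å mixing the radial, along-chain and binormal directions), giving
bond inference real tetrahedra.

These structures exercise every stated symmetry and closed form, but
they are not proteins: no real side-chain chemistry, no β-sheets, no
missing loops or crystallographic disorder beyond seeded Gaussian noise.
Passing the suite demonstrates the geometric correctness and invariance
of the descriptors, not agreement with any particular deposited
structure's published values.

## Reference values and known inconsistencies

The packaged 9×6 matrix records the originally reported descriptor
values for nine membrane proteins.  It is the substrate for the
PCA/clustering/index analytics (whose headline numbers it reproduces
exactly), not a validation target for the descriptor pipeline, because
several entries are inconsistent with the printed definitions:

* reported LTA magnitudes (5.45–7.27) exceed the bound |LTA| ≤ 1 that
  follows from the normalization by mean |V| — the scale used there
  cannot be reconstructed, which is why `mean_abs_volume` is reported
  so users can recover unnormalized volumes;
* reported HPC values are negative for right-handed α-helical proteins
  (see the sign-convention note above);
* one LAI entry equals 1.00, impossible for a COM-centered structure
  with atoms on both sides of the midplane;
* one entry's LAI sign differs between the dataset's matrix form and its
  per-protein listing; the packaged matrix follows the per-protein
  listing (+0.97), the variant consistent with the dataset's own PCA
  summary, which the acceptance script reproduces to the printed
  precision.

`scripts/compare_reference.py` computes vectors for locally supplied
structure files and prints them next to the reference rows; it performs
no downloads.

## Numerical choices and degenerate inputs

Torsions with collinear triples are undefined and their windows skipped.
Structures with no tetrahedra, no torsion windows, no off-midplane
atoms, or no usable helices raise descriptor-specific errors (exit code
2 in the CLI); all-zero tetrahedral volumes define LTA = 0 with a
warning.  Zero z-extent makes the density profile degenerate (error).
Histogram binning uses floor indexing with the top edge clamped into the
last bin.  All computations are single-threaded and deterministic;
rerunning any command with the same inputs and configuration reproduces
outputs bit for bit, and every output embeds the full parameter record.

Problem sizes in the test and acceptance workloads (bundles of 3–5
helices × 14–20 residues, clouds of 10²–10⁵ points, 10³ random oracle
instances) were chosen to pin the invariants tightly while keeping the
whole suite fast to iterate on.

## Limitations

No lipid coordinates: LAI and DDP are protein-embedding proxies, not
bilayer compositional asymmetries.  No detection of transmembrane vs.
surface helices: all annotated helices enter the frame (length-weighted,
so short surface helices carry little weight) and the twist score; a
hydrophobicity- or tilt-based pre-filter is left to the caller.  No
assembly expansion or symmetry
mates; multi-chain entries are analyzed with all protein chains by
default (`--chains`-style restriction is left to preprocessing).  No
manifold mesh fitting, geodesics, t-SNE, persistent homology, or ML
classification — the graph and field exports exist precisely so such
analyses can be done downstream.
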
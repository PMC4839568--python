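# Methods

## The landscape model

`confland` treats an ensemble of structures of one protein as a metric
space whose metric is the superposed backbone RMSD over a curated residue
core, and embeds that space by classical multidimensional scaling (cMDS).

**Dissimilarity.** For each pair of structures the core atoms (default:
backbone N, CA, C, O of the selection's residues, in canonical
residue-then-atom order) are rigidly superposed by the least-squares
(Kabsch) fit restricted to proper rotations, and the RMSD after the fit is
the dissimilarity. The fit set equals the measure set and atoms are
unweighted. Scaling all coordinates by s scales every entry by s;
mirror-image conformers have strictly positive RMSD.

**Double centering and factorization.** With squared dissimilarities
Δ² and centering masses w (uniform by default), B = −½ J Δ² J where
J = I − 1wᵀ/Σw. RMSD is not a Euclidean metric, so B may be indefinite;
it is replaced by the nearest symmetric positive-semidefinite matrix in
Frobenius norm (eigenvalue clipping) before factorization, and the
Frobenius magnitude of that correction is stored on the model as a
diagnostic. Component k is the k-th eigenvector scaled to xₖᵀxₖ = λₖ;
explained-variance fractions divide by the sum of *positive* eigenvalues
of the uncorrected B. The strain ‖B − XXᵀ‖²_F is recorded. The default
dimension is p = 2; for kinase ensembles the first two components
typically separate active, Src-like inactive, DFG-out and open states,
and higher components rarely partition the data further.

**Out-of-sample extension.** A query with distance vector a to the n
training structures is projected by double-centering the bordered matrix
[Δ² a; aᵀ 0] with zero mass on the query. Because only the training
masses enter the centering, the border vector reduces to

    b_i = −½ (a_i² − rowmean_i(Δ²) − wmean(a²) + grandmean(Δ²)),

which is evaluated in O(n) from means cached at fit time (an identity the
test suite verifies against the explicit (n+1)×(n+1) construction). The
projection solves min_y Σ(b_i − x_iᵀy)², i.e. y = (XᵀX)⁻¹Xᵀb, dropping
the quadratic (β − yᵀy)² term of the exact objective; β is kept on the
projection object as a diagnostic of how far the query lies outside the
training span. Frames are projected independently, so the trajectory path
is embarrassingly parallel and never refits the embedding.

**Numerical conventions.** Eigenvalues below 1e-9 × λ_max are treated as
zero; requesting more components than positive eigenvalues truncates with
a warning. Each component's sign is fixed so its largest-magnitude
loading is positive, making serialized models byte-reproducible across
runs. A fully degenerate matrix (all structures identical) embeds at the
origin and refuses out-of-sample projection (singular XᵀX).

## Dataset curation

Structures are parsed from PDB files (Biopython). One chain per record
(first protein chain by default); altloc atoms keep the blank/"A"
conformer; residues with insertion codes never match plain-numbered
selections, which prevents silent misalignment. The dataset filter keeps
records whose resolution is known and ≤ 2.5 Å (inclusive) and in which
every atom of the fit selection is present. Whether the authors' backbone
definition of such analyses includes the carbonyl O is ambiguous in
general; it is included by default here (it adds peptide-plane
orientation) and is configurable.

## Clustering

Single, complete and average linkage operate directly on the RMSD matrix;
Ward linkage assumes squared-Euclidean geometry and therefore runs on a
cMDS embedding of the matrix (full-rank internally, or user-supplied
coordinates). k is user-chosen; no automatic selection is attempted, and
k-means is deliberately not offered — on kinase ensembles it fails to
isolate small non-Gaussian clusters such as a lone DFG-out structure.
Representatives are medoids (minimum summed dissimilarity to co-members,
ties to input order). Dendrograms export as Newick.

## Accelerated-MD reweighting

Dual-boost parameters follow the standard prescription: E_dihed = 1.3
V_dihed_avg, α_dihed = 0.06 V_dihed_avg, E_total = V_total_avg + 0.2
N_atoms, α_total = 0.2 N_atoms (energies kcal/mol). Reweighting bins
samples on 1-D or 2-D collective-variable grids (default 100×100 bins over
the sample range padded 2% per side) and computes per-bin exponential
averages in log space with the per-bin maximum subtracted, so large boosts
cannot overflow. The implemented normalization is

    P_i = Pb_i ⟨e^{ΔV/kT}⟩_i / Σ_j Pb_j ⟨e^{ΔV/kT}⟩_j,

the standard exponential-average estimator, which is exactly the
renormalized unbiased histogram; a variant that divides by Σ_j
⟨e^{ΔV/kT}⟩_j instead is sometimes written down but does not produce a
normalized distribution in general — it is available behind
`printed_normalization=True` for comparison only. kT defaults to 0.5961
kcal/mol (300 K). F = −kT ln P is shifted so the occupied-bin minimum is
zero; empty bins and values ≥ 30 kcal/mol (configurable cap) are reported
at the cap, matching the usual display convention.

## Order parameters

Salt bridges use minimum distances over charged-group atoms (Lys NZ; Glu
OE1/OE2; Arg NE/NH1/NH2) — the standard convention when a plot says
"donor-acceptor couple" without naming atoms. The reported difference is
d(Glu–Arg) − d(Lys–Glu) with CDK2 defaults Glu51/Lys33/Arg150. Segment
RMSDs superpose the frame on a reference over the core selection and then
measure the segment without refitting; defaults are activation loop
145–172 (DFG through APE) and αC-helix 46–55, both overridable — the
activation-loop span used in published figures of this kind is typically
not enumerated, so it is a config knob rather than a hard-coded truth.
Hydrogen bonds require explicit hydrogens (no inference): D–A ≤ 3.5 Å and
D-H···A > 120°. π-π contacts compute ring centroids and least-squares
plane normals (SVD); the inter-plane angle is folded to [0°, 90°], making
the edge-to-face 60–120° window equivalent to 60–90°; face-to-face
(< 30°, < 4.4 Å) is tested before edge-to-face (< 5.5 Å).

## Synthetic data: what it emulates and what it does not

The fixture generators define the study conditions for every test:

* **Euclidean configurations** (random points with exact distance
  matrices, plus the hand-checkable line {0, 3, 4}) are the cMDS oracle:
  a Euclidean matrix must embed with zero strain and exactly recoverable
  distances, and every training row must reproject onto itself.
* **Toy polymer ensembles** are gently helical 40-atom CA chains; each
  conformational state displaces the chain along a distinct low-frequency
  field orthogonal to the six rigid-body modes and to the other states'
  fields, so inter-state RMSD is a controlled knob (unit-RMS fields scaled
  by the displacement) rather than an accident, and cannot be absorbed by
  superposition. Frames add isotropic Gaussian noise. The separable preset
  (3 states × 30 frames, 3 Å displacement, 0.1 Å noise) mirrors, at desk
  scale, an ensemble whose states are far better separated than their
  internal spread — the regime in which all four linkages must agree.
* **Boosted double wells** draw 1-D samples from a two-Gaussian-mixture
  potential (wells at ±1, well free-energy offset dF, σ = 0.35) boosted by
  the aMD form ΔV = (E−U)²/(α+E−U) below the barrier energy, via
  inverse-CDF sampling on a fine grid. The recovery target dF_true is
  computed by quadrature of the unbiased law, so the reweighting test
  closes an exact loop: bias analytically, unbias numerically. At
  n = 200 000 the recovered ΔF agrees with the target to well under
  0.1 kcal/mol.

These fixtures establish the mathematics — embedding exactness,
normalization, estimator consistency, decision boundaries — but they do
not emulate real structural data: no side chains, no missing residues or
altlocs in generated ensembles, isotropic rather than correlated noise,
and boost statistics far tamer than a solvated-protein ΔV distribution
(where the exponential average converges slowly). Passing tests therefore
certify the machinery, not force-field-level realism.

## Problem sizes

The test suite and the acceptance script use ensembles of ≤ 90 frames of
40 atoms, 10-point embedding oracles and 2×10⁵ double-well samples; the
full suite runs in a few seconds on one core. The pipeline itself is
dense linear algebra at n of a few hundred (the realistic crystal-ensemble
size) and streams trajectory frames one at a time.

## External reproduction

Rebuilding a real CDK2 landscape requires downloading the current PDB
entries for UniProt P24941 at ≤ 2.5 Å, filtering for completeness of the
`cdk2_core` selection, and running `confland build`. On such an ensemble
the first two components are expected to carry > 80% of the
positive-eigenvalue variance. This path needs network access and an
evolving external database, so it is documented here rather than tested.

## Known limitations

* No mmCIF parsing, assembly expansion, hydrogen placement or missing-loop
  modeling; structures must arrive complete over the fit selection.
* No sequence alignment: all structures must share residue numbering.
* Out-of-sample projection is the least-squares approximation; queries far
  outside the training span are extrapolations (watch β and the distance
  residuals).
* No error bars on reweighted free energies, and no cumulant/Maclaurin
  reweighting variants.
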
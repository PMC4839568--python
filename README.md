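# confland

Conformational landscapes of proteins from structure ensembles and
molecular-dynamics trajectories.

Protein kinases (and many other proteins) crystallize in a handful of
distinct conformational states — active, Src-like inactive, DFG-out, open
allosteric states — and the natural way to compare hundreds of crystal
structures of the same protein is the pairwise backbone RMSD over a curated
conserved core. `confland` turns such an ensemble into a quantitative
landscape and places simulation frames onto it:

1. **Classical multidimensional scaling (cMDS).** Given the n×n RMSD
   matrix Δ, double centering maps squared dissimilarities to a centered
   Gram matrix,

       B = -1/2 J Δ² J,   J = I - 1wᵀ/Σw,

   which is replaced by its nearest symmetric positive-semidefinite matrix
   (RMSD is not Euclidean) and factorized: component k is the k-th
   eigenvector of B scaled so xₖᵀxₖ = λₖ, and λₖ/Σλ⁺ is the fraction of
   variance it explains. cMDS minimizes the *strain* ‖B − XXᵀ‖².
2. **Out-of-sample projection.** A trajectory frame with distance vector
   *a* to the n reference structures is embedded *without refitting*: the
   bordered matrix [Δ² a; aᵀ 0] is double-centered with zero weight on the
   new point, giving a border vector b, and the frame's coordinates are
   the least-squares solution y = (XᵀX)⁻¹Xᵀb. Cost per frame is linear in
   n, so microsecond trajectories (m ≫ n frames) project cheaply.
3. **Clustering.** Agglomerative clustering (single/complete/average on
   the raw RMSD matrix, Ward on embedded coordinates) partitions the
   ensemble; each cluster is summarized by its medoid.
4. **Accelerated-MD reweighting.** Dual-boost aMD samples carry a boost
   energy ΔV ≥ 0; the unbiased bin probability is recovered by exponential
   averaging, P_i ∝ Pb_i ⟨e^{ΔV/kT}⟩_i, and the free-energy surface is
   F = −kT ln P, min-shifted and display-capped (default 30 kcal/mol).
5. **Order parameters.** Salt-bridge minimum distances and their
   differences (e.g. Glu51–Arg150 vs Lys33–Glu51 in CDK2 numbering),
   activation-loop and αC-helix RMSDs against a reference, hydrogen bonds
   (D–A ≤ 3.5 Å, D-H···A > 120°) and π-π contacts (face-to-face: plane
   angle < 30°, centroids < 4.4 Å; edge-to-face: 60–120°, < 5.5 Å).

The CDK2 conserved-core residue selection (12 segments, 117 residues,
backbone N/CA/C/O) ships as the preset `cdk2_core`.

## Worked example

```python
import numpy as np
from confland import fit_cmds, pairwise_rmsd_matrix, hierarchical_cluster
from confland.fixtures import ToyEnsembleSpec, make_toy_ensemble, make_boosted_double_well
from confland.reweighting import KT_300K, reweight_histogram, free_energy

# a synthetic 3-state ensemble: 30 frames/state, 3 A state separation
spec = ToyEnsembleSpec(n_states=3, frames_per_state=30, n_atoms=40,
                       inter_state_displacement=3.0, noise_sd=0.1, seed=1)
frames, states = make_toy_ensemble(spec)
D = pairwise_rmsd_matrix(frames)

model = fit_cmds(D, p=2)
print("explained variance:", np.round(model.explained_variance, 4))
# explained variance: [0.7452 0.2481]

result = hierarchical_cluster(D, k=3, linkage="average")
print("cluster sizes:", np.bincount(result.labels)[1:])
# cluster sizes: [30 30 30]

# reweight boosted double-well samples back to the true free energies
x, dV, dF_true = make_boosted_double_well(n=200_000, kT=KT_300K, dF=1.0, seed=1)
surf = free_energy(reweight_histogram((x, dV), (np.linspace(-3, 3, 101),), kT=KT_300K))
c = surf.centers()[0]
dF = -KT_300K * np.log(surf.P[c > 0].sum() / surf.P[c < 0].sum())
print(f"true dF = {dF_true:.3f}, recovered dF = {dF:.3f} kcal/mol")
# true dF = 0.993, recovered dF = 0.996 kcal/mol
```

The two cMDS components carry ~99% of the positive-eigenvalue variance
(the three states span a plane), all three states are recovered as clusters
of 30, and exponential reweighting recovers the 1 kcal/mol well free-energy
difference to a few thousandths of a kcal/mol at this sample size.

## Command line

```sh
confland build ensemble.pdb --config config.yml --out model.npz --matrix-out D.csv
confland cluster D.csv --k 5 --linkage average --out clusters.tsv --tree-out tree.nwk
confland project model.npz trajectory.pdb --out projected.csv
confland orderparams trajectory.pdb --reference ref.pdb --out channels.csv
confland fes projected.csv --reweight --deltav deltaV --out fes.csv --plot fes.png
```

Exit codes: 0 success, 2 input/validation failure, 3 numerical failure.

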
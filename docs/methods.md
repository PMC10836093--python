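# Methods

## Scope and data model

The package analyses conformational ensembles of short peptides (the tau
repeat-domain fragments around the PGGG turn motif and the VQIVYK amyloid
motif are the motivating system) at four levels: geometry, kinetics, NMR
observables and cross-link contacts. The core container is a
`ConformerEnsemble`: an ordered stack of frames over a fixed atom table
(1-based residue numbering, PDB conventions). All internal geometry is in
Å; nm appears only at configuration boundaries (e.g. the clustering cutoff,
quoted in nm by convention) and is converted on entry. Physical time is
carried as `dt` (ns per frame) and enters only when timescales are reported.

## Synthetic ground truth

The generators in `synthetic_data` define the study conditions for every
test and analysis; they are first-class, tested code.

**Hairpin/extended ensembles.** The idealized hairpin is two antiparallel
straight strands (3.8 Å Cα virtual bonds, per-residue rise = 3.8 Å)
separated by `strand_sep` (default 4.8 Å, a typical cross-strand Cα–Cα
distance), with residue *i* paired to residue *2·apex+1−i*. The turn is
closed by pinching the two apex residues toward each other so that **every**
consecutive Cα–Cα distance, including the bond across the turn, is exactly
3.8 Å; consequently the apex pair itself is the single cross-strand pair
not at `strand_sep` (a geometric necessity whenever `strand_sep` ≠ 3.8 Å —
a rigid turn cannot satisfy both constraints at once). Isotropic Gaussian
noise (default 0; 0.3 Å for mixture fixtures, small enough to keep the
folded/unfolded separation unambiguous) produces frame-to-frame variation.
These Cα-only ensembles stand in for full-atom MD states; all distance
operations accept arbitrary atom selections so Cα serves as the
backbone/proton proxy. Whether Cα proxies shift the turn-ratio
classification boundaries relative to full-atom ensembles is untested; the
classification thresholds are validated only at the stated bounds
(< 0.75 left, > 1 right). Note that a rigid *centred* hairpin does not give
ρ ≈ 1 — that regime reflects floppier sampled turns — so no centred-turn
ρ = 1 behaviour is asserted anywhere.

**Markov trajectories.** A row-stochastic macrostate matrix `T_true` is
simulated from its stationary distribution; each state emits Gaussian
features with given means/covariances. This emulates a discretized MD
feature trajectory with metastable states while keeping every recovered
quantity checkable in closed form.

**Cross-link tables.** Replicate tables draw link positions from a lysine
list, with residue separation classes (local/intermediate/long) sampled at
known weights and per-record quality fields drawn uniformly over stated
ranges that straddle the filter thresholds. The generator records the true
class and the true filter verdict per record, so the filter chain can be
checked for exact agreement rather than statistically. What the synthetic
tables do not emulate: peptide detectability bias, positional ambiguity
from poor fragmentation, or correlated quality fields — passing tests show
the bookkeeping is right, not that real data would be this clean.

## Ensemble geometry

* **Distance maps** are the frame-mean of the minimum atom–atom distance
  between residue pairs over a selection (symmetric, zero diagonal).
* **Group distances** use unweighted selection centroids by default; a
  mass-weighted option exists for true centre-of-mass on heteroatom input
  (identical for Cα-only ensembles).
* **RMSD** is least-squares superposition (Kabsch, via
  `scipy.spatial.transform.Rotation.align_vectors`) with the same selection
  for fitting and measurement; the test suite cross-checks it against an
  independent quaternion (Horn) implementation to 1e-8.
* **GROMOS clustering**: repeatedly take the frame with the most neighbours
  within the RMSD cutoff as a centre and remove it with its neighbours.
  Ties on neighbour count break to the lowest frame index, making output
  deterministic. Clusters are reported in decreasing size; populations sum
  to 1. Equivalence to a brute-force implementation of the same greedy rule
  is asserted on ≤ 50-frame ensembles.
* **Turn register**: ρ = d(Cα₄, Cα₁₂)/d(Cα₇, Cα₁₂) per frame over
  configurable role residues; invariant under rigid motion and uniform
  scaling. Frames with a vanishing denominator are excluded from summaries
  with a degenerate-frame count.

## Markov-state-model kinetics

* **Featurization**: one column per residue pair (A×B) of per-frame minimum
  atom distances; the canonical 7×7 grouping yields 49 features.
* **tICA** solves the generalized eigenproblem of the symmetrized
  time-lagged covariance against the instantaneous covariance on mean-free
  data. Singular covariance is regularized with a ridge
  ε = 1e-10·trace/dim and a warning.
* **Discretization**: scikit-learn k-means (k-means++ init) with an
  explicit seed.
* **MSM estimation** counts sliding-window transitions at the lag and
  restricts to the largest strongly connected component (discarded count
  fraction is recorded). The reversible estimator symmetrizes counts,
  C̄ = (C+Cᵀ)/2, then row-normalizes — a closed form whose stationary
  distribution is the normalized row sums of C̄ and which satisfies
  detailed balance exactly. This was chosen over iterative reversible MLE
  for testability; the two agree in the data-rich regimes used here, and an
  MLE estimator would be a drop-in extension. Spectra of reversible models
  are computed via the π^{1/2} similarity transform (symmetric eigenproblem,
  real spectrum guaranteed).
* **Validation**: implied timescales t_i(τ) = −τ/ln λ_i(τ) (NaN marker for
  eigenvalues outside (0,1)); VAMP-2 as Σλ² of the top-k eigenvalues
  (the singular-value form of the variational score reduces to this for
  reversible models); Chapman–Kolmogorov on a fixed PCCA+ partition —
  predicted T(τ)^f coarse-grained with the base model's weights vs a model
  re-estimated at lag f·τ and coarse-grained on the same partition (no
  re-clustering at longer lags, the standard practice).
* **PCCA+** uses the Deuflhard–Weber inner-simplex construction on the top
  n right eigenvectors; memberships are the simplex coordinates, clipped to
  [0,1] and row-renormalized (the subsequent constrained optimization
  refinement matters only for strongly overlapping macrostates and is not
  implemented). Crisp labels by argmax; macro populations are stationary
  sums over crisp members.
* **MFPT** solves m = τ·1 + T m with m = 0 on the target, reported in ns,
  π-weighted over source states.
* **TPT**: forward committor by linear solve (0 on A, 1 on B), backward
  committor from the time-reversed chain (equals 1−q⁺ for reversible
  models, asserted to 1e-8); gross flux F_ij = π_i q⁻_i T_ij q⁺_j, net flux
  max(0, F−Fᵀ); total flux is the net flux out of A (equals net flux into
  B). Pathways by iterative widest-path (max-bottleneck Dijkstra)
  extraction: subtract each path's bottleneck flux and repeat until < 1e-8
  of the total remains. Fluxes and the channel split are validated against
  Monte-Carlo reactive-trajectory counting. TPT and MFPT accept either a
  microstate model or a PCCA+ coarse-graining (crisp-set, π-weighted
  macrostate matrix); both routes are exposed because either level of
  analysis is legitimate and they need not coincide.
* **Free-energy surfaces** are −ln histogram over two reduced coordinates,
  shifted to min 0, empty bins +inf.

Problem sizes in tests and drivers (10⁵–10⁶ steps for chain recovery,
5·10⁵ for the full-pipeline recovery at k = 15 microstates) were chosen as
the smallest sizes at which the statistical tolerances stated with each
check (e.g. populations ± 0.03, slowest timescale ± 15%) are comfortably
non-marginal for a well-mixed chain.

## NMR observables

* **Secondary shifts** Δδ = δ_obs − δ_rc per residue using a bundled
  standard random-coil Hα scale (per amino-acid type, glycine-specific row
  included).
* **ncSP** averages, over a ±window (default 3, truncated at termini),
  uniform-weight normalized deviations −Δδ/|ref|, with ref the full-helix
  deviation for negative Δδ and the full-sheet deviation otherwise. The
  bundled full-structure Hα deviations are the uniform −0.38/+0.38 ppm
  convention; per-type secondary-deviation tables and non-uniform window
  weights are known divergence knobs from the original neighbour-corrected
  propensity tool and can be swapped in via the reference-table arguments.
  Sign convention: positive = helical. Values are clamped to [−1.5, 1.5]
  and clamp counts reported. ncSP is linear in Δδ for a fixed window.
* **NOE effective distances**: r_eff = ⟨r⁻⁶⟩^(−1/6) over frames per atom
  pair, with min(r) ≤ r_eff ≤ mean(r) and exact linear scaling — both
  asserted as properties. Observability threshold defaults to 4 Å; for
  Cα-only fixtures Cα–Cα distances are proxies for proton pairs and the
  threshold is only a labelling convention.

## Cross-link contact analysis

Filters follow the strictness of the published thresholds exactly:
score strictly > 25, FDR strictly < 0.05, ppm window inclusive
[−2.2, +3.8], %TIC strictly > 10, peptide length ≥ 6. Per-criterion
rejection counts are returned because the filters, not the search, are the
analysis. Consensus keeps position pairs seen in ≥ n replicates (default
all). "Normalized frequency" divides each record's spectral count (nseen)
by its replicate's total — so values within a replicate sum to 1 — then
takes per-link mean ± SD across replicates; a raw-count mode is provided
since the alternative reading (per-construct maximum) cannot be excluded.
Contact order is the absolute residue separation of the linked positions
(loop-links and cross-links treated identically); repeat bins default to
tau 2N4R numbering and are configurable. Link-pattern clustering is
average-linkage/Euclidean over link columns (scipy), cut to n groups
(default 4), serialized as a nested dendrogram. Modification fractions are
peak areas normalized to their total.

## Known limitations

* Cα-only fixtures: no side chains, no protons, no solvent — generators
  produce geometry, not thermodynamics.
* The reversible MSM estimator is the symmetrization closed form, not the
  constrained MLE; for strongly non-equilibrium count matrices the two can
  differ.
* PCCA+ without the optimization refinement can mis-assign microstates when
  macrostates overlap heavily.
* No periodic-boundary imaging, and no binary trajectory formats; ensembles
  travel as multi-model PDB, tables as CSV, results as JSON.
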
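# ensemblekit

Analysis toolkit for distinguishing aggregation-prone from
aggregation-resistant peptide conformational ensembles, built around the tau
repeat domain and its amyloid-nucleating ⁳⁰⁶VQIVYK³¹¹ motif. The package
covers four layers of evidence that structural studies of tau combine:

1. **Ensemble geometry** — mean-minimum inter-residue distance maps,
   centroid distances between residue groups, pairwise fitted RMSD, GROMOS
   conformational clustering, and a *turn-register* statistic
   ρ = d(Cα₄, Cα₁₂)/d(Cα₇, Cα₁₂) that classifies a β-hairpin's strand
   register as left-shifted (ρ < 0.75), centred (ρ ≈ 1) or right-shifted
   (ρ > 1). The register controls whether the amyloid motif is sequestered
   against the upstream strand.
2. **Markov-state-model kinetics** — minimum-distance featurization, tICA,
   k-means microstates, reversible MSM estimation with implied-timescale and
   Chapman–Kolmogorov validation, PCCA+ macrostates, mean first-passage
   times, and transition-path-theory committors, gross/net fluxes and
   max-bottleneck pathway decomposition.
3. **NMR observables** — neighbour-corrected secondary-structure propensity
   (ncSP) from Hα secondary shifts (negative = β-extended, positive =
   α-helical) and ensemble NOE back-calculation,
   r_eff = ⟨r⁻⁶⟩^(−1/6), with an observability threshold (~4 Å).
4. **Cross-link mass spectrometry** — identification filters (score > 25,
   FDR < 0.05, −2.2 ≤ ppm ≤ +3.8, %TIC > 10, peptide length ≥ 6),
   replicate consensus (default 5-of-5), frequency normalization,
   contact-order classes (local ≤ 10, intermediate 11–39, long ≥ 40
   residues), tau repeat binning (R1 244–274 … R′ 369–380), hierarchical
   clustering of link patterns, and peptide modification fractions.

Everything is exercised on synthetic ensembles, trajectories and link tables
with known ground truth (`ensemblekit.synthetic_data`), so every estimator
in the package is validated by parameter recovery rather than by eye.

## Worked example

```python
import numpy as np
from ensemblekit import msm_kinetics as mk
from ensemblekit.ensemble_metrics import turn_register
from ensemblekit.synthetic_data import (
    HairpinSpec, MarkovEmissionSpec, make_hairpin_ensemble,
    simulate_markov_trajectory)

# a left-registered hairpin: the turn apex shifted toward the N-terminus
ens = make_hairpin_ensemble(HairpinSpec(n_res=18, apex=7, strand_sep=4.8))
print(turn_register(ens).ratio[0])        # 0.388 -> classified 'left'

# recover known 3-state kinetics from Gaussian feature emissions
T = np.array([[0.98, 0.01, 0.01], [0.02, 0.96, 0.02], [0.01, 0.01, 0.98]])
states, feats = simulate_markov_trajectory(MarkovEmissionSpec(
    T, means=[[0, 0], [4, 0], [0, 4]], covs=[0.25] * 3,
    n_steps=500_000, seed=2027))
Y = mk.tica_fit(feats, lag=5).transform(feats, 2)
disc = mk.kmeans_discretize(Y, k=15, seed=0)
model = mk.estimate_msm(disc.dtrajs[0], lag=5, dt=0.1)
print(np.sort(mk.pcca(model, 3).macro_populations))
# [0.197 0.400 0.403]  vs true stationary populations [0.2 0.4 0.4]
```

The register ratio 0.388 is below the 0.75 left-shift bound: residue 12 (the
amyloid-motif entry in the 18-residue frame) is paired back against the
residue-4 region, the contact pattern associated with reduced aggregation.
The recovered macrostate populations agree with the generator's stationary
distribution to < 0.01.

## Analysis scripts

`analysis/01_build_ensembles.py` … `05_xlms_contacts.py` are thin numbered
drivers that run each layer on its synthetic inputs and write tables under
`results/`. Each prints a short narrative of what it found; run them in
order (02 and 04 read the PDB ensembles written by 01).

## Command line

A `ensemblekit` console entry point exposes the same operations as
subcommands (`distmap`, `register`, `cluster`, `featurize`, `tica`, `msm`,
`its`, `ck`, `pcca`, `tpt`, `fes`, `ncsp`, `noedist`, `xl-filter`,
`xl-consensus`, `xl-classify`, `xl-cluster`, `pipeline`). Exit codes:
0 success, 2 validation error, 3 runtime failure.

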
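# loopmsm

Kinetic analysis of slow protein-loop conformational dynamics: unbiased
pairwise-distance featurization, iterative tICA feature selection,
Markov state modelling with hidden-Markov coarse-graining, two-system
landscape comparison, and Lipari–Szabo model-free analysis of backbone
¹⁵N relaxation data.

## The problem

Conformational ensembles of proteins often hide a handful of slow,
functionally relevant motions — typically loops interconverting between
discrete geometries on timescales far beyond ordinary fluctuations.
Identifying *which* residues carry those motions, building a kinetic
model of the interconversion, and comparing how a mutation reshapes the
landscape, is a multi-stage analysis that this package implements
end-to-end for anyone working with trajectory ensembles (plus an
independent NMR-relaxation branch for experimental cross-validation).

The core stages:

1. **Featurization** — all Cα–Cα pair distances D_ij over non-terminal
   residues (192 eligible residues → 18 336 features); pairs that stay
   < 3 Å or > 10 Å in every frame are pruned.
2. **Iterative tICA selection** — tICA solves C(τ)v = λC(0)v; features
   with low |Pearson correlation| to the leading tICs are eliminated and
   tICA is refit, until a compact set remains.  Residues recurring among
   the surviving pairs are reported as *anchor residues* of the slow
   motions.
3. **MSM + HMM** — k-means microstates in tIC space, reversible
   maximum-likelihood transition matrix, implied timescales
   t_k = −τ/ln λ_k, macrostate count from the timescale gap, and
   PCCA+-initialized hidden-Markov coarse-graining giving equilibrium
   populations π ± SD (trajectory bootstrap) and mean first passage
   times from a linear first-passage solve.
4. **Two-system comparison** — one joint tICA model places both systems
   in a shared coordinate space; macrostates are matched by tIC
   centroids, unmatched states are flagged *exclusive*, and population
   shifts and MFPT ratios are tabulated.
5. **NMR relaxation** — R1/R2/NOE forward model from the model-free
   spectral density J(ω) = (2/5)[S²τm/(1+(ωτm)²) + (1−S²)τ′/(1+(ωτ′)²)];
   τm estimation by inverting the rigid R2/R1 ratio, per-residue
   (S², τe, Rex) fits with nested model selection, and R2/R1
   classification against the ensemble mean ± 1 SD (above: μs–ms
   exchange; below: ps–ns flexibility).

A synthetic-data generator plants a bead-chain "protein" with two mobile
loop blocks switching between discrete conformations under known Markov
chains (one slow, one fast), so every stage can be validated against
exact ground truth — stationary distributions, MFPTs, anchor residues,
and relaxation parameters are all known by construction.

## Worked example

```bash
python examples/03_feature_selection_anchors.py
```

prints (seed 3):

```
start: 114 features, end: 10 (8 iterations, status=converged)
selected pairs: ['D_8_10', 'D_8_11', 'D_9_11', 'D_9_12', 'D_10_12',
                 'D_28_31', 'D_29_31', 'D_29_32', 'D_30_33', 'D_31_33']
anchor table (residue: pair count): {31: 3, 8: 2, 9: 2, 10: 2, 11: 2,
                                     12: 2, 29: 2, 33: 2, 28: 1, 30: 1, 32: 1}
planted loops: slow (28, 29, 30, 31, 32, 33) fast (8, 9, 10, 11, 12)
```

Starting from all 780 residue pairs with no prior knowledge, the
procedure converges onto 10 pairs, every one of which involves a planted
loop residue — the selection recovers both mobile loops purely from the
kinetic content of the distance time series.  `examples/04…` continues
into the MSM stage (implied timescales `[244.9, 53.1, 43.8, 2.0, …]`
frames: three slow processes → 4 macrostates, populations ≈ 0.25 ± 0.03
against a true value of 0.25), and `examples/05…` compares two systems
that differ in the slow loop's switch rate (MFPT ratios ≈ 2 for
slow-loop transitions).

The other examples cover ensemble generation and file output (01),
featurization/pruning/RMSF (02), and the NMR model-free branch (06).

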
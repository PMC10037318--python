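# Methods

This note records the models and procedures `pepsurf` implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer.

## System model and units

A trajectory is a shared topology (atoms with name, element, 1-based residue
index and residue name) plus ordered coordinate frames. The internal length
unit is Angstrom everywhere — contact cut-offs and RMSD values in this
problem domain are quoted in Å — with nanometre-based inputs converted on
read; energies are kJ/mol; the reaction coordinate of umbrella windows is in
nm because pull codes emit nm. Gold slab atoms are identified by element Au
(overridable by an explicit index set for exotic topologies); every non-gold
atom is treated as peptide, i.e. solvent is assumed stripped upstream. Box
vectors may vary between frames; they are used only for x/y periodicity in
the optional 3-D contact distance.

## Contact analysis

Per frame, the topmost gold layer is the mean z of slab atoms within
`layer_tolerance` (default 0.8 Å) of the maximum slab z. The default
tolerance sits between typical Au(111) interlayer spacing (~2.35 Å) and
thermal jitter, so the band captures exactly the top crystal layer of a
mildly disordered slab.

The residue–surface distance is the z-offset of the residue's reference site
(a named atom, or the centroid of a named set) from that layer plane. A
residue is in contact when distance ≤ cut-off — the boundary is inclusive,
and negative distances (site below the plane) count as contact. Because a
flat slab makes either convention defensible, a `min3d` mode instead takes
the minimum 3-D distance from any site atom to any top-layer atom under the
x/y minimum-image convention; the vertical mode is the default.

The shipped reference table uses the sulfur atom with a 4.5 Å cut-off for
Met, Cys and the modified residues MOX (oxidised Met), CTB
(tert-butyl-protected Cys) and COX (oxidised protected Cys), and the
side-chain terminal heavy atom(s) with the same 4.5 Å cut-off for standard
residues. The standard-residue entries are deliberately plain defaults:
published per-residue sites and cut-offs exist and should be supplied via
`load_reference_table` when available. Contact fractions over a
concatenation of trajectories equal the frame-weighted mean of the parts,
and are monotone non-decreasing in the cut-off; both properties are tested.

## Binding scores

The score combines the contact fraction with the amino acid's adsorption
free energy at the aqueous Au(111) interface. The combination operator is
not uniquely determined by the verbal definition, so the package adopts the
product `s_i = f_i · ΔG_i`: it is the only simple form that vanishes for
never-contacting residues, returns ΔG at permanent contact, and carries
kJ/mol units. The operator is a pluggable callable so `min`, a sum, or any
other convention can be swapped in without touching callers.

Cumulative scores are plain sums over inclusive 1-based position ranges;
the default report includes the N-terminal half (1–6) and C-terminal
"particle-binding" half (7–12) of the dodecapeptide layout, clipped to the
positions actually present. The position-9 classifier partitions the line at
−10 and −1 kJ/mol with the single-helix interval closed at both ends; the
source statement gives only the open phrase "−1 to −10", so inclusivity was
fixed by decision and is tested at the exact boundaries.

The shipped ΔG table is representative, not measured: magnitudes follow the
expected ordering (sulfur-bearing and aromatic side chains strongest,
small aliphatics weakest, blocked/oxidised sulfur anchors weak), every entry
is tagged `representative`, and any real analysis should load a published or
umbrella-sampling-derived table. Consequently the worked threonine example
is anchored only in its product: a planted 0.5 contact probability times the
representative ΔG(Thr) = −9 kJ/mol gives the −4.5 kJ/mol score the pipeline
reproduces; the factorisation into f₉ and ΔG is the package's assumption.

## Conformational clustering

Backbone RMSD is computed after removing centroids and applying the optimal
Kabsch rotation, with the determinant correction that forbids improper
(reflecting) solutions; superposition is on by default (`fit=False` gives raw
positional RMSD). The backbone selection defaults to N, CA, C — carbonyl O
excluded — and is configurable, since "all backbone atoms" is ambiguous about
O.

Clustering is the greedy max-neighbour rule: count neighbours within the
cut-off (inclusive) among unassigned frames, extract the frame with the most
neighbours as centroid together with its neighbours, repeat. Ties on
neighbour count break to the lowest frame index, making the partition
deterministic; clusters are reported by decreasing population, ties by
centroid index. The implementation works on a precomputed distance matrix
(`daura_cluster_from_matrix`) so tests can compare it against an exhaustive
re-derivation on random matrices; `daura_cluster` adds the O(n²) Kabsch-RMSD
matrix. n = 15001-frame production ensembles imply ~10⁸ pairwise fits; the
package targets the post-processing scale (hundreds to a few thousand
frames) and tests at n = 300.

Cross-variant matching compares centroid structures of the top-k (default 5)
most populated clusters of two ensembles: matched at RMSD ≤ 2.0 Å,
near-matched strictly between 2.0 and 2.5 Å, else unmatched; both thresholds
are configurable. When a result has fewer than k clusters the available ones
are compared and a warning is recorded rather than failing.

## WHAM

The estimator solves the standard self-consistency on a histogram grid:

    p(ξ_b) ∝ Σ_j n_j(b) / Σ_j N_j exp[(F_j − w_j(ξ_b))/kT]
    F_j = −kT ln Σ_b p(ξ_b) exp[−w_j(ξ_b)/kT]

iterated directly in log space (log-sum-exp throughout) until
`max_j |ΔF_j| < tolerance · kT`; the default tolerance 10⁻⁶ is interpreted
relative to kT, matching the dimensionless-tolerance convention of the
common reference tool, with an absolute kJ/mol mode behind a flag. One F_j
is pinned during iteration to remove the gauge drift; the final PMF
`−kT ln p` is shifted so its minimum over supported bins is zero. Bins with
zero total counts are reported as NaN — undefined, never zero — and excluded
from the gauge. k_B = 0.0083145 kJ mol⁻¹ K⁻¹; default temperature 300 K;
default 200 bins over the sampled range; iteration cap 2·10⁵ with a
convergence error (carrying the residual) beyond it. The converged result is
invariant to a constant shift of the initial F_j guess and to permuting
samples within a window; both are tested.

Error bars use a trajectory-style bootstrap: each window's series is
resampled with replacement in contiguous circular blocks whose length is the
series' integrated autocorrelation time (initial-positive-sequence estimate,
minimum 1), WHAM is re-run per replicate warm-started from the point
estimate, each replicate is gauge-aligned to the point estimate by its mean
offset, and the per-bin error is the standard deviation across replicates
(default 200; the acceptance checks use 50 to stay fast). The exact
resampling scheme of the reference tool is undocumented, so this block
bootstrap is a documented stand-in that preserves within-window correlation;
the `resampler` hook accepts any custom scheme. PMF comparisons anywhere in
the package first remove the arbitrary additive constant (`gauge_align`).

## Synthetic generators

All generators are pure functions of (spec, seed) and return their ground
truth, so recovery tests compare against what was planted.

*Contacts.* Each residue's contact state follows a stationary two-state
Markov chain with stationary probability p and lag-1 autocorrelation ρ
(transitions P(1|1) = p + ρ(1−p), P(1|0) = p(1−ρ)); ρ defaults to 0.5 so
variance tests face realistic temporal correlation (effective sample size
n(1−ρ)/(1+ρ)) rather than i.i.d. frames. Geometry: three square-grid
Au(111)-like layers 2.35 Å apart; in contact frames the reference site sits
0.5 Å inside the cut-off, otherwise 3 Å outside — only the placement relative
to the cut-off matters. Not emulated: side-chain flexibility, partial
contacts near the boundary, slab thermal motion, solvent.

*Ensembles.* Conformations are weight-chosen templates plus isotropic
Gaussian noise with the stated per-atom RMS (per-coordinate σ = RMS/√3),
optionally under random rigid motion, which fitted RMSD is blind to.
`random_templates` draws cumulative random walks until all pairs exceed a
minimum RMSD (default 6 Å = 3× the clustering cut-off), guaranteeing planted
clusters are recoverable exactly when noise ≪ cut-off. Not emulated: chain
connectivity constraints, basin anharmonicity, inter-cluster transitions.

*Umbrella windows.* Samples are drawn exactly from the biased Boltzmann
density via inverse-CDF interpolation on a 10⁴-point grid (trapezoidal CDF),
per-window child seeds; window layout defaults mirror the production setup
(0.05 nm spacing, k = 3000 kJ mol⁻¹ nm⁻²). Analytic truths: flat, harmonic,
and the double well a(ξ²−b²)² (tests use b = 0.2 nm with a ~5 kJ/mol
barrier). Exact i.i.d. sampling means these tests validate the estimator,
not time-correlation handling; the block bootstrap degenerates gracefully to
an ordinary bootstrap there (autocorrelation time ≈ 1).

Because the generators plant their statistics directly, passing tests show
the estimators are correct and well-calibrated on data obeying the stated
models; they say nothing about force-field accuracy, sampling convergence of
real REST-MD, or solvent-mediated effects.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: 10⁴-frame contact
trajectories (100 seeds), 300-member ensembles, 11–15 windows × 5·10⁴
samples with 50 bootstrap replicates — sizes at which every statistical bound
asserted is comfortably resolvable in a few minutes on one core. All
randomness flows from explicit integer seeds (numpy `default_rng` /
`SeedSequence.spawn`); reruns of any stage with the same config and seed are
byte-identical, which the pipeline tests assert on the JSON artifacts.

## Known limitations

- The O(n²) RMSD matrix makes clustering impractical beyond ~10⁴ frames
  without subsampling.
- Standard-residue reference sites/cut-offs and the ΔG table are
  representative defaults, to be overridden with published values.
- WHAM assumes a 1-D reaction coordinate and harmonic biases; no MBAR
  alternative is provided.
- The classifier encodes a fixed −10/−1 kJ/mol window; it is a correlation
  observed for one peptide family, not a transferable physical law.
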
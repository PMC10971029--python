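# Methods

## Model and procedure

The pipeline treats a two-chain complex as a constrained (catalytic) chain
plus a mobile (regulatory) chain whose conformational ensemble is compared
between a wild type and variants. All statistics are computed on Cα
coordinates. The stages, in order:

1. **Equilibration discard.** Each replicate keeps its last
   ⌈T·(1−f)⌉ frames (default f = 1/3, matching a design where the first
   5 ns of a 15 ns replicate are treated as equilibration). Implemented as
   T − ⌊T·f + 10⁻⁹⌋; the epsilon guards against binary-float artifacts for
   fractions like 1/3.
2. **Superposition.** Every frame is fitted independently onto the
   reference by a Kabsch (SVD) least-squares rigid fit on the fitting
   selection, defaulting to the constrained chain's Cα atoms; reporting
   statistics (RMSD, PCA) use the mobile chain. Reflections are excluded;
   collinear point sets are rejected because their rotation is not unique.
   Per-frame fitting (rather than one transform per replicate) is the
   standard trajectory-analysis convention and is what we implement.
3. **Cartesian PCA.** The covariance (ddof = 1) of the flattened
   mobile-chain coordinates over pooled frames is eigendecomposed via an
   economy SVD of the centered data matrix. By default the pool is wild
   type plus all variants, so one shared basis makes medians comparable
   across variants in a single report column; a wild-type-only basis is a
   config switch (`pooling: wt-only`). Eigenvector sign is fixed by making
   the largest-magnitude component positive (ties: lowest coordinate
   index). Sign conventions for "toward/away" motions are therefore a
   property of this rule, not of any biological direction; reports carry
   the signed shifts and this rule is the single place that fixes them.
4. **PC-shift calls.** A variant is called ±PCk when its pooled median
   score differs from the wild-type pooled median by at least one σ, where
   σ is the SD of the wild-type pooled scores on that PC (the natural
   reference spread when shifts are measured against the wild type). The
   boundary is inclusive (≥).
5. **Distance monitors.** Chain-qualified residue pairs, Cα–Cα Euclidean
   distance per frame. Because monitor pairs in the motivating use case are
   printed without complete chain qualifiers, the config requires explicit
   chain ids for both endpoints — nothing is guessed silently.
6. **Free-energy landscapes.** F = −ln(P/P_max) in kT over the 2-D
   histogram of a PC-score pair pooled over frames ("time-dependent joint
   probability" read as the empirical joint distribution over trajectory
   frames; no lag structure or smoothing). Empty bins are reported as
   undefined (NaN), never capped — capping is a rendering choice. Default
   grid: 50×50 bins over the data range padded by 1 %. Note the padding
   shrinks the data support of edge bins; for quantitative closed-form
   comparisons the tests use `pad_fraction=0` so bins match the sampled
   support exactly.
7. **Interaction energies.** Coulomb plus 12-6 Lennard-Jones between two
   disjoint selections, both terms multiplied by the CHARMM-style energy
   switching polynomial between r_on = 10 Å and r_off = 12 Å. Combining
   rules: geometric on ε, arithmetic on the rmin half-radii. The
   implementation is vectorized per frame and is verified against an
   all-pairs double loop to 10⁻¹⁰ kcal/mol (on systems without steric
   clashes; inside a clash the r⁻¹² term amplifies float rounding beyond
   any fixed absolute tolerance). This module is a coarse per-Cα surrogate
   for a full solvated force field: its contract is *relative* energies
   between variants under identical parameterization and the resulting
   stronger ("+") / weaker ("−") calls — absolute kcal/mol values are not
   comparable to all-atom energies, and no solvation term is included.
8. **Down-sampling significance test.** For two pooled frame series, each
   of 1000 repetitions draws 100 frames from each series without
   replacement and computes a Welch two-sample t (Welch chosen because
   variance equality between variant ensembles is not defensible). The
   statistic is the median t; the two-sided p is evaluated at the
   Welch–Satterthwaite df of the repetition whose t is closest to the
   median. Significance threshold α = 10⁻⁶. Replicates are pooled before
   drawing. An optional `stride` knob thins frames first as an
   autocorrelation mitigation.

### Conservatism of the down-sampling test

Because every draw subsamples the *same* finite series, the expected
subsample t is the full-data t scaled by √(m/n), and taking the median over
repetitions removes nearly all subsample noise. Under a true null the
median t is therefore approximately N(0, m/n) — far tighter than a t
distribution — and the test almost never rejects at conventional levels
(its measured null rejection rate at p < 0.05 is 0/200 in the acceptance
run). This is a feature, not a defect: the procedure exists to be a
conservative guard against the pseudo-replication of densely sampled,
autocorrelated trajectory frames, and the raw median t is always reported
alongside p so the effect size remains visible. Users wanting nominal
type-I calibration should not use this test.

## Synthetic-ensemble generator

The generator emulates the study design the pipeline targets: triplicate
ensembles per variant, frames nominally every 2 ps, two temperatures
(300 K, 360 K), with the pipeline discarding the first third of each
replicate.

* **Geometry.** Chain A (fixed, 80 residues) and chain B (mobile, 120
  residues) are parallel helical arcs with exactly 3.8 Å consecutive Cα
  spacing (radius solved from rise 1.5 Å and 100°/residue), axes 10 Å
  apart so the interface sits in the 4–12 Å band where the switched
  nonbonded energy is sensitive. Domains on the mobile chain default to
  "nSH2" = residues 1–40 and "iSH2" = residues 61–120.
* **Dynamics.** Frame t = template + Σ_k a_kt v_k + ε on the mobile chain,
  a_kt ~ N(shift_k·sd_k, sd_k²), ε isotropic with SD 0.1 Å; the fixed
  chain is exactly static, emulating harmonic constraints on the partner
  subunit. Planted modes are orthonormal half-sine displacement fields
  along x, y, z with SDs (3, 2, 1) Å; the single-signed lobes keep the
  eigenvector sign convention stable under estimation noise, and mode 1
  points across the interface so PC1 shifts couple to interface energies,
  as in the motivating system. Every frame then receives a random rigid
  transform (1 Å translation SD, 5° rotation SD) — large enough that
  skipping superposition visibly corrupts the PCA, which is the point.
* **Temperature.** 360 K widens only the residual noise by √(360/300);
  means are untouched. This tests two-temperature bookkeeping, not
  thermodynamics.
* **Energetic ground truth.** Mobile-chain atoms carry +0.2 e, fixed-chain
  atoms −0.2 e (ε = 0.1 kcal/mol, rmin/2 = 2.0 Å), so all cross-chain
  Coulomb terms are attractive and scaling a domain's charges by c scales
  that domain's cross-chain Coulomb energy by exactly c at fixed geometry.
  A "destabilizing" scenario (charge scale 0.5 on iSH2 plus a +2σ shift on
  mode 1) is the default planted variant; a null variant re-draws the
  wild-type settings under a different seed.
* **What it does not emulate.** No force-field dynamics, no frame
  autocorrelation (frames are i.i.d. draws), no solvent, no side chains,
  no anharmonicity. Passing tests therefore demonstrate that the
  *analysis* recovers planted effects of realistic magnitude — not that
  any particular biological system behaves this way, and not how the test
  behaves under the temporal correlation of real MD.

## Numerical choices

* Kabsch degeneracy: point sets whose second singular value is ≤ 10⁻⁸ of
  the first (collinear) are rejected.
* PCA eigenvalue/eigenvector agreement with an independent PCA
  implementation is asserted to 10⁻⁸; covariance trace equals the
  eigenvalue sum to 10⁻⁶.
* Welch t edge cases: two constant equal series give t = 0; zero combined
  variance with unequal means is a hard error (t undefined).
* p-values are clamped into (0, 1] after the t tail evaluation.
* FEL closed-form checks use 20×20 bins (Gaussian) and 10×10 (uniform) at
  n = 10⁵ — bin counts chosen so that bins in the checked region hold
  hundreds of samples, balancing histogram noise against discretization
  bias.
* Report determinism: artifacts contain no timestamps; the config hash and
  all seeds are recorded in the provenance block.

## Problem sizes

Default synthetic studies use 3 replicates × 500 frames per variant at one
temperature (the end-to-end acceptance run), with 120-frame studies for
unit-level pipeline checks and 2000-frame single ensembles for
mode-recovery checks. These sizes give comfortable margins on every
planted-recovery criterion (e.g. PC1-shift recovery 20/20 seeds) while
keeping the whole suite fast.

## Known limitations

* The R-cache converter's expected object layout (T × 3N numeric matrices,
  bio3d `xyz` convention) is an assumption validated only against
  synthetic fixtures; real deposited caches may need a mapping step, and
  the converter fails loudly rather than guessing.
* Interaction energies are qualitative by design (see surrogate note
  above); "ΔSH2"/"RMSD level" style qualitative binnings are not built in —
  the report emits numeric values and users may supply their own
  thresholds.
* Temperatures are analyzed separately (default 300 K); no cross-
  temperature pooling is offered because there is no principled way to
  pool medians across fluctuation scales without a model of the
  temperature dependence.
* The down-sampling test's conservatism (above) is intrinsic; it is not a
  calibrated hypothesis test.
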
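# varidyn

Trajectory-ensemble analysis of how protein variants alter the dynamics and
inter-subunit interactions of a two-chain complex — built around the
PI3K-style architecture of a mobile regulatory subunit (e.g. PIK3R1, with
its nSH2 and iSH2 domains) fluctuating against a constrained catalytic
partner (e.g. PIK3CA). The intended users are structural bioinformaticians
who have replicate coordinate ensembles for a wild type and a set of
variants and want reproducible, statistically guarded calls of the form
"this variant shifts collective motion PC1 upward and weakens the
iSH2:catalytic interface".

## What it computes

Given superposable Cα ensembles (multi-model PDB), the pipeline performs:

1. **Superposition** — every frame is least-squares fitted (Kabsch, SVD,
   proper rotations only) onto a reference using a fitting selection,
   conventionally the constrained chain's Cα atoms.
2. **Cartesian PCA** — the covariance **C** of the mobile-chain Cα
   coordinates over pooled frames is eigendecomposed, **C** v_k = λ_k v_k;
   frames project to PC scores s_k(t) = (x_t − ⟨x⟩)·v_k [Å].
3. **PC-shift classification** — a variant is called shifted on PC k
   (±PCk) when |median(s_k^var) − median(s_k^WT)| ≥ σ_k, with σ_k the SD of
   the pooled wild-type scores on that PC.
4. **Distance monitors** — Cα–Cα distances for chain-qualified residue
   pairs (e.g. across the two long iSH2 helices), summarized per variant.
5. **Free-energy landscapes** — F(s_i, s_j) = −ln(P/P_max) [kT] from the
   2-D histogram of a PC-score pair over pooled frames.
6. **Interaction energies** — per-frame switched-cutoff nonbonded energy
   between two disjoint selections (domain vs partner chain):
   E = S(r)·[332.0636·q_i q_j/(εr) + ε_ij((R_ij/r)¹² − 2(R_ij/r)⁶)], with
   the CHARMM-style switching polynomial S(r) tapering from r_on = 10 Å to
   zero at r_off = 12 Å.
7. **Down-sampling significance test** — repeatedly draw 100 frames from
   each of two series, compute a Welch t per draw, take the median t over
   1000 repetitions, and declare significance at p < 10⁻⁶. Deliberately
   conservative for dense, autocorrelated trajectory data.

A synthetic-ensemble generator (`varidyn.synthetic`) plants known
collective modes, mean shifts and interface-charge perturbations, so every
stage is verifiable against ground truth without any MD engine.

## Worked example

Generate a small synthetic study (wild type, a null variant drawn from the
wild-type settings, and a "destabilizing" variant with a planted +2σ shift
on mode 1 and iSH2 charges halved), then analyze it:

```sh
varidyn simulate --out study --seed 7 --frames 120
varidyn analyze --config study/config.yaml --out artifacts
```

The report (`artifacts/report.tsv`, one row per variant) comes out as:

```text
variant        delta_PCs  PC1_shift_A  PC1_wt_sd_A  iSH2:catalytic_call  iSH2:catalytic_dE_kcal_mol  iSH2:catalytic_p  rmsd_median_A
null           none       -0.1339      3.2205       n.s.                 -1.3837                     0.9457            0.3252
destabilizing  +PC1       5.6429       3.2205       -                    90.1489                     7.597e-74         0.5798
```

Reading the rows: the null variant shows no PC shift (−0.13 Å against a
3.22 Å wild-type σ on PC1) and its interface energy difference
(−1.4 kcal/mol) is not significant (`n.s.`) under the down-sampling test.
The destabilizing variant's PC1 median is shifted by +5.64 Å ≈ 1.8σ —
called `+PC1` — and its iSH2:catalytic energy is 90 kcal/mol less negative
than wild type (weaker binding, call `-`) at p ≈ 10⁻⁷⁴. That is exactly the
planted ground truth. Full per-frame projections, energy series and FEL
grids are written alongside the report.

## Data formats

Multi-model PDB is the canonical ensemble format (XYZ as a minimal
fallback); per-atom nonbonded parameters are a TSV of
`atom_index, charge_e, epsilon_kcal_mol, rmin_half_A`; the analysis config
is one YAML file (see `study/config.yaml` emitted by `simulate`).
`varidyn convert` imports R-serialized Cα coordinate caches (matrices of
T × 3N coordinates) into multi-model PDB via `Rscript`.
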
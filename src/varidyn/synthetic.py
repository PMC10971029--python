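"""Ground-truth synthetic ensembles emulating a constrained two-chain MD study.

The generator plants everything the analysis pipeline is supposed to
recover: a rigid "catalytic" chain A held fixed (emulating harmonic
constraints on the partner subunit), a mobile "regulatory" chain B whose
fluctuations live in a few orthonormal collective modes with known
amplitude SDs, variant-specific mean shifts along those modes (in units of
the mode SD), and variant-specific scaling of interface charges so that
domain interaction energies change by a known factor. Every frame
additionally receives a small random rigid-body transform, so superposition
is exercised rather than assumed.

Study design mirrored by the defaults: triplicate ensembles per variant,
frames every 2 ps with the first third discarded as equilibration by the
pipeline, and a second temperature (360 K) realized as residual noise
widened by sqrt(360/300) — fluctuation width only, never the means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .energetics import ParameterTable
from .structure_io import AtomRecord, Structure, TrajectoryEnsemble, write_ensemble, write_structure

__all__ = [
    "ComplexTemplate",
    "PlantedModes",
    "VariantScenario",
    "build_template",
    "default_planted_modes",
    "sample_ensemble",
    "make_parameter_table",
    "default_scenarios",
    "write_study",
]

_CA_SPACING = 3.8  # A, consecutive C-alpha distance
_HELIX_RISE = 1.5  # A per residue
_HELIX_TURN_DEG = 100.0  # degrees per residue
_JITTER_TRANSLATION_SD = 1.0  # A
_JITTER_ROTATION_SD_DEG = 5.0
_BASE_TEMPERATURE = 300.0


@dataclass
class ComplexTemplate:
    """Geometry spec for the synthetic two-chain complex.

    Chain "A" stands in for the constrained catalytic subunit, chain "B"
    for the mobile regulatory subunit. ``domain_partition`` names inclusive
    residue ranges on the mobile chain.
    """

    n_res_fixed_chain: int = 80
    n_res_mobile_chain: int = 120
    domain_partition: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"nSH2": (1, 40), "iSH2": (61, 120)}
    )
    axis_separation: float = 10.0  # A between the two helix axes

    def __post_init__(self) -> None:
        if self.n_res_fixed_chain < 1 or self.n_res_mobile_chain < 1:
            raise ValueError("both chains need at least one residue")
        ranges = sorted(self.domain_partition.values())
        for (lo, hi) in ranges:
            if not (1 <= lo <= hi <= self.n_res_mobile_chain):
                raise ValueError(f"domain range {lo}-{hi} outside mobile chain")
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi:
                raise ValueError("domain ranges must be disjoint")


@dataclass
class PlantedModes:
    """Orthonormal collective modes of the mobile chain with known SDs.

    ``mode_vectors`` is K x 3N_mobile (rows orthonormal to 1e-8);
    ``mode_sds`` [A] are the per-mode amplitude SDs, strictly descending;
    ``noise_sd`` [A] is the isotropic residual per coordinate.
    """

    mode_vectors: np.ndarray
    mode_sds: np.ndarray
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        self.mode_vectors = np.asarray(self.mode_vectors, dtype=float)
        self.mode_sds = np.asarray(self.mode_sds, dtype=float)
        if self.mode_vectors.ndim != 2 or self.mode_vectors.shape[0] != self.mode_sds.shape[0]:
            raise ValueError("need one SD per mode vector")
        gram = self.mode_vectors @ self.mode_vectors.T
        if not np.allclose(gram, np.eye(self.mode_vectors.shape[0]), atol=1e-8):
            raise ValueError("mode vectors must be mutually orthonormal")
        if np.any(self.mode_sds <= 0) or np.any(np.diff(self.mode_sds) >= 0):
            raise ValueError("mode SDs must be positive and strictly descending")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_modes(self) -> int:
        return self.mode_vectors.shape[0]


@dataclass
class VariantScenario:
    """One variant's generative condition.

    ``mode_shifts`` maps a 1-based mode index to a mean shift in units of
    that mode's SD; ``charge_scale`` maps a mobile-chain domain name to a
    multiplicative factor on that domain's charges.
    """

    name: str
    mode_shifts: dict[int, float] = field(default_factory=dict)
    charge_scale: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 3
    n_frames: int = 500
    temperatures: tuple[float, ...] = (300.0, 360.0)
    seed: int = 0
    is_wt: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


def _helix(n: int, x_offset: float, phase: float = 0.0) -> np.ndarray:
    """Ideal helical arc with exact consecutive C-alpha spacing."""
    turn = np.deg2rad(_HELIX_TURN_DEG)
    radius = np.sqrt(_CA_SPACING**2 - _HELIX_RISE**2) / (2.0 * np.sin(turn / 2.0))
    i = np.arange(n)
    return np.column_stack(
        [
            x_offset + radius * np.cos(phase + i * turn),
            radius * np.sin(phase + i * turn),
            i * _HELIX_RISE,
        ]
    )


def build_template(spec: ComplexTemplate | None = None) -> Structure:
    """Deterministic C-alpha-only two-chain template structure.

    Chain A (fixed) and chain B (mobile) are parallel helical arcs with
    exactly 3.8 A consecutive spacing, their axes ``axis_separation`` apart.
    """
    if spec is None:
        spec = ComplexTemplate()
    a = _helix(spec.n_res_fixed_chain, 0.0)
    b = _helix(spec.n_res_mobile_chain, spec.axis_separation, phase=np.pi)
    coords = np.vstack([a, b])
    atoms = [
        AtomRecord(atom_index=i, atom_name="CA", residue_number=i + 1, residue_name="ALA", chain_id="A")
        for i in range(spec.n_res_fixed_chain)
    ] + [
        AtomRecord(
            atom_index=spec.n_res_fixed_chain + i,
            atom_name="CA",
            residue_number=i + 1,
            residue_name="ALA",
            chain_id="B",
        )
        for i in range(spec.n_res_mobile_chain)
    ]
    return Structure(atoms=atoms, coordinates=coords)


def default_planted_modes(
    spec: ComplexTemplate | None = None,
    mode_sds: tuple[float, ...] = (3.0, 2.0, 1.0),
    noise_sd: float = 0.1,
) -> PlantedModes:
    """Smooth half-sine collective modes along x, y and z of the mobile chain.

    Mode 1 displaces the mobile chain toward/away from the fixed chain
    (x axis), so a planted mean shift on mode 1 also perturbs the interface
    geometry — the coupling the pipeline's PC-vs-energy story relies on.
    All lobes are single-signed, which keeps the deterministic eigenvector
    sign convention stable under estimation noise.
    """
    if spec is None:
        spec = ComplexTemplate()
    n = spec.n_res_mobile_chain
    profile = np.sin(np.pi * (np.arange(n) + 0.5) / n)
    vectors = []
    for k in range(len(mode_sds)):
        v = np.zeros((n, 3))
        v[:, k % 3] = profile * (1.0 if k < 3 else np.cos(np.pi * (k // 3) * np.arange(n) / n))
        v = v.ravel()
        vectors.append(v / np.linalg.norm(v))
    mat = np.array(vectors)
    # Gram-Schmidt guard for k > 3 harmonics
    q, _ = np.linalg.qr(mat.T)
    mat = (q.T * np.sign(np.sum(q.T * mat, axis=1))[:, None])[: len(mode_sds)]
    return PlantedModes(mode_vectors=mat, mode_sds=np.asarray(mode_sds, dtype=float), noise_sd=noise_sd)


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, _JITTER_ROTATION_SD_DEG))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    trans = rng.normal(0.0, _JITTER_TRANSLATION_SD, size=3)
    return rot, trans


def sample_ensemble(
    template: Structure,
    modes: PlantedModes,
    scenario: VariantScenario,
    replicate: int = 1,
    temperature: float = 300.0,
    apply_jitter: bool = True,
) -> TrajectoryEnsemble:
    """Draw one replicate's trajectory from the generative model.

    Frame t places the mobile chain at ``template + sum_k a_kt v_k + eps_t``
    with ``a_kt ~ N(shift_k * sd_k, sd_k^2)`` and isotropic residual noise
    (widened by sqrt(T/300) at elevated temperature); the fixed chain is
    exactly static. A small random rigid-body transform is then applied to
    the whole frame. Fully reproducible from (scenario.seed, replicate,
    temperature).
    """
    for k in scenario.mode_shifts:
        if not (1 <= k <= modes.n_modes):
            raise ValueError(f"mode shift references mode {k}, but only {modes.n_modes} modes planted")
    mobile_idx = np.array([a.atom_index for a in template.atoms if a.chain_id == "B"])
    if modes.mode_vectors.shape[1] != 3 * mobile_idx.size:
        raise ValueError("planted modes are not defined on the template's mobile chain")

    seq = np.random.SeedSequence([scenario.seed, int(replicate), int(round(temperature * 1000))])
    rng = np.random.default_rng(seq)
    t_frames = scenario.n_frames
    k_modes = modes.n_modes

    shift = np.zeros(k_modes)
    for k, s in scenario.mode_shifts.items():
        shift[k - 1] = s
    amp_mean = shift * modes.mode_sds
    amps = rng.normal(amp_mean, modes.mode_sds, size=(t_frames, k_modes))
    noise_sd = modes.noise_sd * np.sqrt(temperature / _BASE_TEMPERATURE)
    noise = rng.normal(0.0, noise_sd, size=(t_frames, mobile_idx.size * 3)) if noise_sd > 0 else 0.0

    frames = np.tile(template.coordinates, (t_frames, 1, 1))
    disp = amps @ modes.mode_vectors + noise
    frames[:, mobile_idx, :] += disp.reshape(t_frames, mobile_idx.size, 3)

    if apply_jitter:
        center = template.coordinates.mean(axis=0)
        for t in range(t_frames):
            rot, trans = _random_rigid(rng)
            frames[t] = (frames[t] - center) @ rot.T + center + trans

    return TrajectoryEnsemble(
        atoms=template.atoms,
        frames=frames,
        frame_interval=2.0,
        label=scenario.name,
        replicate=replicate,
        temperature=temperature,
    )


def make_parameter_table(
    template: Structure,
    scenario: VariantScenario | None = None,
    spec: ComplexTemplate | None = None,
    base_charge: float = 0.2,
    epsilon: float = 0.1,
    rmin_half: float = 2.0,
) -> ParameterTable:
    """Coarse per-C-alpha nonbonded parameters for a scenario.

    Mobile-chain atoms carry ``+base_charge``, fixed-chain atoms
    ``-base_charge`` (so every cross-chain Coulomb pair is attractive and
    domain interaction strength maps monotonically to charge magnitude).
    ``scenario.charge_scale`` multiplies the charges of the named
    mobile-chain domain, changing that domain's cross-chain Coulomb energy
    by exactly the same factor at fixed geometry.
    """
    if spec is None:
        spec = ComplexTemplate()
    n = template.n_atoms
    charge = np.array([base_charge if a.chain_id == "B" else -base_charge for a in template.atoms])
    if scenario is not None:
        for domain, factor in scenario.charge_scale.items():
            if domain not in spec.domain_partition:
                raise ValueError(f"charge_scale names unknown domain {domain!r}")
            lo, hi = spec.domain_partition[domain]
            for a in template.atoms:
                if a.chain_id == "B" and lo <= a.residue_number <= hi:
                    charge[a.atom_index] *= factor
    return ParameterTable(
        charge=charge,
        epsilon=np.full(n, epsilon),
        rmin_half=np.full(n, rmin_half),
    )


def default_scenarios(
    seed: int = 0,
    n_frames: int = 500,
    temperatures: tuple[float, ...] = (300.0,),
    n_replicates: int = 3,
) -> list[VariantScenario]:
    """The default synthetic study: WT, a null variant and a destabilizing one.

    The null variant shares the WT generative settings (different seed), so
    every comparison against it should come out not significant / no shift.
    The destabilizing variant plants a +2 sigma mean shift on mode 1 and
    halves the iSH2-domain charges (weaker interface).
    """
    common = dict(n_frames=n_frames, temperatures=temperatures, n_replicates=n_replicates)
    return [
        VariantScenario(name="WT", seed=seed, is_wt=True, **common),
        VariantScenario(name="null", seed=seed + 1, **common),
        VariantScenario(
            name="destabilizing",
            mode_shifts={1: 2.0},
            charge_scale={"iSH2": 0.5},
            seed=seed + 2,
            **common,
        ),
    ]


def write_study(
    out_dir: str | Path,
    scenarios: list[VariantScenario] | None = None,
    template_spec: ComplexTemplate | None = None,
    modes: PlantedModes | None = None,
    seed: int = 0,
    n_frames: int = 500,
    temperatures: tuple[float, ...] = (300.0,),
    stats_seed: int = 12345,
) -> Path:
    """Write a complete fixture study and a ready-to-run analysis config.

    Layout: ``{variant}/{temperature}K/rep{r}.pdb`` plus per-variant
    ``parameters.tsv``, a shared ``reference.pdb`` (the template),
    ``manifest.json`` with all generative settings, and ``config.yaml``
    consumable by the pipeline. Returns the config path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if template_spec is None:
        template_spec = ComplexTemplate()
    if modes is None:
        modes = default_planted_modes(template_spec)
    if scenarios is None:
        scenarios = default_scenarios(seed=seed, n_frames=n_frames, temperatures=temperatures)

    template = build_template(template_spec)
    write_structure(template, out_dir / "reference.pdb")

    manifest: dict = {"seed": seed, "variants": {}}
    variants_cfg = []
    for sc in scenarios:
        vdir = out_dir / sc.name
        vdir.mkdir(exist_ok=True)
        params = make_parameter_table(template, sc, template_spec)
        params.to_tsv(vdir / "parameters.tsv")
        trajs = []
        for temp in sc.temperatures:
            tdir = vdir / f"{temp:g}K"
            tdir.mkdir(exist_ok=True)
            for rep in range(1, sc.n_replicates + 1):
                ens = sample_ensemble(template, modes, sc, replicate=rep, temperature=temp)
                rel = f"{sc.name}/{temp:g}K/rep{rep}.pdb"
                write_ensemble(ens, out_dir / rel)
                trajs.append({"path": rel, "replicate": rep, "temperature": float(temp)})
        manifest["variants"][sc.name] = {
            "seed": sc.seed,
            "mode_shifts": {str(k): v for k, v in sc.mode_shifts.items()},
            "charge_scale": sc.charge_scale,
            "n_replicates": sc.n_replicates,
            "n_frames": sc.n_frames,
            "temperatures": list(sc.temperatures),
            "is_wt": sc.is_wt,
        }
        variants_cfg.append(
            {
                "name": sc.name,
                "wt": sc.is_wt,
                "parameters": f"{sc.name}/parameters.tsv",
                "trajectories": trajs,
            }
        )
    manifest["planted_mode_sds"] = modes.mode_sds.tolist()
    manifest["noise_sd"] = modes.noise_sd
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    nsh2 = template_spec.domain_partition.get("nSH2")
    ish2 = template_spec.domain_partition.get("iSH2")
    config = {
        "reference": "reference.pdb",
        "frame_interval_ps": 2.0,
        "fit_selection": "chain A and name CA",
        "pca_selection": "chain B and name CA",
        "equilibration_fraction": 1.0 / 3.0,
        "temperature": 300.0,
        "n_modes": 3,
        "pooling": "pooled",
        "fel": {"pair": [1, 2], "bins": 50},
        "stats": {"m_per_draw": 100, "repetitions": 1000, "alpha": 1e-6, "seed": stats_seed},
        "switching": {"r_on": 10.0, "r_off": 12.0, "dielectric": 1.0},
        "domains": {
            "nSH2": f"chain B and resid {nsh2[0]}-{nsh2[1]} and name CA" if nsh2 else None,
            "iSH2": f"chain B and resid {ish2[0]}-{ish2[1]} and name CA" if ish2 else None,
            "catalytic": "chain A and name CA",
        },
        "domain_pairs": [["iSH2", "catalytic"], ["nSH2", "catalytic"]],
        "monitors": [
            {"chain_a": "B", "residue_a": 65, "chain_b": "A", "residue_b": 65},
            {"chain_a": "B", "residue_a": 75, "chain_b": "A", "residue_b": 75},
            {"chain_a": "B", "residue_a": 61, "chain_b": "B", "residue_b": 110},
        ],
        "variants": variants_cfg,
    }
    config["domains"] = {k: v for k, v in config["domains"].items() if v}
    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
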
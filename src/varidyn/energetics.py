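"""Switched-cutoff nonbonded interaction energies between two selections.

The per-frame interaction energy between two disjoint atom selections is
the sum over all cross pairs of a Coulomb plus Lennard-Jones term, tapered
smoothly to zero between an inner switch radius (default 10 A) and an outer
cutoff (default 12 A) by the standard energy-switching polynomial

    S(r) = (r_off^2 - r^2)^2 (r_off^2 + 2 r^2 - 3 r_on^2) / (r_off^2 - r_on^2)^3

applied to both terms. Combining rules are geometric on epsilon and
arithmetic on the minimum-energy half-radii (R_ij = rmin_half_i +
rmin_half_j), with the LJ form eps_ij * ((R_ij/r)^12 - 2 (R_ij/r)^6).

This module is a coarse per-C-alpha surrogate for a full force field: its
contract is *relative* energies between variants on identical
parameterization (and the resulting stronger/weaker calls), never absolute
agreement with an all-atom, solvated energy function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import Selection, TrajectoryEnsemble

__all__ = [
    "ParameterTable",
    "SwitchingSpec",
    "EnergySeries",
    "pair_energy",
    "interaction_energy_series",
    "interaction_call",
]

COULOMB_CONSTANT = 332.0636  # kcal A mol^-1 e^-2


@dataclass
class ParameterTable:
    """Per-atom nonbonded parameters: charge [e], epsilon [kcal/mol], rmin_half [A]."""

    charge: np.ndarray
    epsilon: np.ndarray
    rmin_half: np.ndarray

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.rmin_half = np.asarray(self.rmin_half, dtype=float)
        n = self.charge.shape[0]
        if self.epsilon.shape != (n,) or self.rmin_half.shape != (n,):
            raise ValueError("charge, epsilon, rmin_half must have equal lengths")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")
        if np.any(self.rmin_half <= 0):
            raise ValueError("rmin_half must be positive")

    @property
    def n_atoms(self) -> int:
        return self.charge.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "atom_index": np.arange(self.n_atoms),
                "charge_e": self.charge,
                "epsilon_kcal_mol": self.epsilon,
                "rmin_half_A": self.rmin_half,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParameterTable":
        df = pd.read_csv(path, sep="\t").sort_values("atom_index")
        return cls(
            charge=df["charge_e"].to_numpy(),
            epsilon=df["epsilon_kcal_mol"].to_numpy(),
            rmin_half=df["rmin_half_A"].to_numpy(),
        )


@dataclass
class SwitchingSpec:
    """Switching / cutoff scheme: taper from ``r_on`` to zero at ``r_off`` [A]."""

    r_on: float = 10.0
    r_off: float = 12.0
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_CONSTANT
    distance_dependent_dielectric: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r_on < self.r_off):
            raise ValueError("require 0 < r_on < r_off")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")


@dataclass
class EnergySeries:
    """Per-frame interaction energy [kcal/mol] between two named selections."""

    values: np.ndarray
    coulomb: np.ndarray
    lennard_jones: np.ndarray
    selection_a_label: str = "A"
    selection_b_label: str = "B"
    label: str = ""
    replicate: int = 0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coulomb = np.asarray(self.coulomb, dtype=float)
        self.lennard_jones = np.asarray(self.lennard_jones, dtype=float)
        if not np.allclose(self.values, self.coulomb + self.lennard_jones, atol=1e-8):
            raise ValueError("values must equal coulomb + lennard_jones per frame")


def switching_factor(r: np.ndarray, spec: SwitchingSpec) -> np.ndarray:
    """S(r): 1 below r_on, the switching polynomial on (r_on, r_off], 0 beyond."""
    r = np.asarray(r, dtype=float)
    r2 = r * r
    on2, off2 = spec.r_on**2, spec.r_off**2
    s = np.ones_like(r)
    mid = (r > spec.r_on) & (r <= spec.r_off)
    s[mid] = ((off2 - r2[mid]) ** 2 * (off2 + 2.0 * r2[mid] - 3.0 * on2)) / (off2 - on2) ** 3
    s[r > spec.r_off] = 0.0
    return s


def _energy_terms(
    r: np.ndarray,
    qq: np.ndarray,
    eps_ij: np.ndarray,
    rmin_ij: np.ndarray,
    spec: SwitchingSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Switched (coulomb, lennard_jones) for arrays of pair distances."""
    s = switching_factor(r, spec)
    inv_r = 1.0 / r
    if spec.distance_dependent_dielectric:
        coul = spec.coulomb_constant * qq * inv_r * inv_r / spec.dielectric
    else:
        coul = spec.coulomb_constant * qq * inv_r / spec.dielectric
    ratio6 = (rmin_ij * inv_r) ** 6
    lj = eps_ij * (ratio6 * ratio6 - 2.0 * ratio6)
    return s * coul, s * lj


def pair_energy(
    r: float,
    q1: float,
    q2: float,
    eps1: float,
    eps2: float,
    rmin1: float,
    rmin2: float,
    spec: SwitchingSpec | None = None,
) -> float:
    """Switched nonbonded energy [kcal/mol] of one atom pair at distance r [A].

    ``rmin1``/``rmin2`` are half-radii; the pair minimum-energy distance is
    their sum. r must be positive.
    """
    if spec is None:
        spec = SwitchingSpec()
    if not r > 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    coul, lj = _energy_terms(
        np.array([r]), np.array([q1 * q2]), np.array([np.sqrt(eps1 * eps2)]),
        np.array([rmin1 + rmin2]), spec,
    )
    return float(coul[0] + lj[0])


def interaction_energy_series(
    ensemble: TrajectoryEnsemble,
    sel_a: Selection,
    sel_b: Selection,
    params: ParameterTable,
    spec: SwitchingSpec | None = None,
    label_a: str | None = None,
    label_b: str | None = None,
) -> EnergySeries:
    """Per-frame cross-selection interaction energy, decomposed.

    Sums ``pair_energy`` over all cross pairs within the cutoff, per frame.
    Selections must be disjoint and covered by the parameter table. The
    vectorized evaluation equals the all-pairs double loop.
    """
    if spec is None:
        spec = SwitchingSpec()
    ia = sel_a.resolved_indices
    ib = sel_b.resolved_indices
    if ia.size == 0 or ib.size == 0:
        raise ValueError("energy selections must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("energy selections overlap; interaction energy requires disjoint sets")
    if max(ia.max(), ib.max()) >= params.n_atoms:
        raise ValueError("parameter table does not cover all selected atoms")

    qq = np.outer(params.charge[ia], params.charge[ib])
    eps_ij = np.sqrt(np.outer(params.epsilon[ia], params.epsilon[ib]))
    rmin_ij = params.rmin_half[ia][:, None] + params.rmin_half[ib][None, :]

    t = ensemble.n_frames
    coul_out = np.empty(t)
    lj_out = np.empty(t)
    for i in range(t):
        delta = ensemble.frames[i][ia][:, None, :] - ensemble.frames[i][ib][None, :, :]
        r = np.sqrt(np.sum(delta * delta, axis=2))
        if np.any(r <= 0):
            raise ValueError(f"coincident atoms across selections in frame {i}")
        coul, lj = _energy_terms(r, qq, eps_ij, rmin_ij, spec)
        coul_out[i] = coul.sum()
        lj_out[i] = lj.sum()
    return EnergySeries(
        values=coul_out + lj_out,
        coulomb=coul_out,
        lennard_jones=lj_out,
        selection_a_label=label_a or sel_a.expression,
        selection_b_label=label_b or sel_b.expression,
        label=ensemble.label,
        replicate=ensemble.replicate,
        temperature=ensemble.temperature,
    )


def interaction_call(variant: np.ndarray | EnergySeries, wt: np.ndarray | EnergySeries, test) -> str:
    """Stronger/weaker/not-significant call for a variant's interaction energy.

    ``test`` is the resampling test result computed on these two series.
    More negative energy means stronger binding: a significant decrease in
    the variant median is called ``"+"`` (stronger), a significant increase
    ``"-"`` (weaker), otherwise ``"n.s."``.
    """
    v = variant.values if isinstance(variant, EnergySeries) else np.asarray(variant)
    w = wt.values if isinstance(wt, EnergySeries) else np.asarray(wt)
    if not test.significant:
        return "n.s."
    return "+" if float(np.median(v)) < float(np.median(w)) else "-"
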
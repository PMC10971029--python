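"""Cartesian principal component analysis of superposed coordinates.

The covariance of the selected C-alpha coordinates, pooled over all frames
of one or more (already superposed) ensembles, is eigendecomposed. The
leading eigenvectors are collective motions ("modes"); projecting frames on
them yields per-frame PC scores in Angstrom. A variant is called shifted
along a PC when its pooled median score differs from the wild-type median
by at least one wild-type standard deviation on that PC.

Eigenvector sign is fixed deterministically: the largest-magnitude
component is made positive, ties broken by the lowest coordinate index.
PC indices are 1-based in all public interfaces and reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Selection, TrajectoryEnsemble

__all__ = [
    "ModeBasis",
    "ProjectionSeries",
    "PcShiftCall",
    "fit_modes",
    "project",
    "call_pc_shift",
    "displacement_field",
]


@dataclass
class ModeBasis:
    """Mean conformation, orthonormal modes and their variances.

    ``mean_conformation`` is the flattened (3M,) pooled mean of the selected
    coordinates; ``eigenvectors`` is K x 3M (rows orthonormal); eigenvalues
    are in A^2, descending. ``variance_fraction`` is each mode's share of the
    *total* coordinate variance (all 3M modes), so it sums to <= 1 over the
    K retained modes.
    """

    mean_conformation: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    total_variance: float
    selection_expression: str = ""

    def __post_init__(self) -> None:
        self.mean_conformation = np.asarray(self.mean_conformation, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        if self.eigenvectors.ndim != 2:
            raise ValueError("eigenvectors must be K x 3M")
        k, dim = self.eigenvectors.shape
        if self.mean_conformation.shape != (dim,):
            raise ValueError("mean_conformation length must match eigenvector length")
        if self.eigenvalues.shape != (k,) or self.variance_fraction.shape != (k,):
            raise ValueError("eigenvalues/variance_fraction must have one entry per mode")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class ProjectionSeries:
    """Per-frame PC scores [A]: T x K, exact inner products with the modes."""

    scores: np.ndarray
    label: str = ""
    replicate: int = 0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be T x K")


@dataclass
class PcShiftCall:
    """A Table-style PC-shift call for one variant on one PC.

    ``call`` is ``"+PCk"`` / ``"-PCk"`` when the variant median differs from
    the wild-type median by at least one wild-type SD (the >= boundary is
    inclusive), else ``"none"``.
    """

    pc_index: int
    variant_median: float
    wt_median: float
    wt_sd: float
    call: str

    @property
    def shift(self) -> float:
        return self.variant_median - self.wt_median

    @property
    def shift_in_sigma(self) -> float:
        return self.shift / self.wt_sd if self.wt_sd > 0 else np.inf * np.sign(self.shift)


def _pooled_coords(ensembles: list[TrajectoryEnsemble], selection: Selection) -> np.ndarray:
    idx = selection.resolved_indices
    blocks = [e.frames[:, idx, :].reshape(e.n_frames, -1) for e in ensembles]
    return np.concatenate(blocks, axis=0)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # Largest-|component| made positive; np.argmax takes the lowest index on ties.
    out = vectors.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def fit_modes(
    ensembles: list[TrajectoryEnsemble] | TrajectoryEnsemble,
    selection: Selection,
    n_modes: int = 3,
) -> ModeBasis:
    """Fit a PCA mode basis on the pooled frames of superposed ensembles.

    The covariance (ddof=1) of the flattened selected coordinates over all
    pooled frames is eigendecomposed; the top ``n_modes`` modes are kept
    with a deterministic sign convention. At least two pooled frames are
    required.
    """
    if isinstance(ensembles, TrajectoryEnsemble):
        ensembles = [ensembles]
    if not ensembles:
        raise ValueError("no ensembles given")
    x = _pooled_coords(ensembles, selection)
    t_total, dim = x.shape
    if t_total < 2:
        raise ValueError(f"PCA requires at least 2 pooled frames, got {t_total}")
    mean = x.mean(axis=0)
    xc = x - mean
    # economy SVD: eigenvalues of the covariance are s^2 / (T - 1)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / (t_total - 1)
    total = float(eigvals.sum())
    k = min(n_modes, vt.shape[0])
    vectors = _fix_signs(vt[:k])
    frac = eigvals[:k] / total if total > 0 else np.zeros(k)
    return ModeBasis(
        mean_conformation=mean,
        eigenvectors=vectors,
        eigenvalues=eigvals[:k],
        variance_fraction=frac,
        total_variance=total,
        selection_expression=selection.expression,
    )


def project(
    ensemble: TrajectoryEnsemble,
    basis: ModeBasis,
    selection: Selection,
) -> ProjectionSeries:
    """Project an ensemble's selected coordinates on a mode basis.

    Scores are exact inner products ``(frame - mean) . v_k``; no
    re-centering beyond the basis mean.
    """
    idx = selection.resolved_indices
    x = ensemble.frames[:, idx, :].reshape(ensemble.n_frames, -1)
    if x.shape[1] != basis.mean_conformation.shape[0]:
        raise ValueError(
            f"selection dimension {x.shape[1]} does not match basis dimension "
            f"{basis.mean_conformation.shape[0]}"
        )
    scores = (x - basis.mean_conformation) @ basis.eigenvectors.T
    return ProjectionSeries(
        scores=scores,
        label=ensemble.label,
        replicate=ensemble.replicate,
        temperature=ensemble.temperature,
    )


def pooled_scores(projections: list[ProjectionSeries], pc_index: int) -> np.ndarray:
    """Concatenate one PC's scores over replicates (``pc_index`` 1-based)."""
    if pc_index < 1:
        raise ValueError("pc_index is 1-based")
    return np.concatenate([p.scores[:, pc_index - 1] for p in projections])


def call_pc_shift(
    variant_proj: list[ProjectionSeries],
    wt_proj: list[ProjectionSeries],
    pc_index: int,
) -> PcShiftCall:
    """Call a variant's PC shift against the wild type at the >=1 sigma rule.

    Replicates are pooled within each condition; sigma is the SD (ddof=1) of
    the pooled wild-type scores on that PC.
    """
    if not variant_proj or not wt_proj:
        raise ValueError("both projection sets must be non-empty")
    v = pooled_scores(variant_proj, pc_index)
    w = pooled_scores(wt_proj, pc_index)
    v_med = float(np.median(v))
    w_med = float(np.median(w))
    sd = float(np.std(w, ddof=1)) if w.size > 1 else 0.0
    shift = v_med - w_med
    if sd > 0 and abs(shift) >= sd:
        call = f"{'+' if shift > 0 else '-'}PC{pc_index}"
    else:
        call = "none"
    return PcShiftCall(pc_index=pc_index, variant_median=v_med, wt_median=w_med, wt_sd=sd, call=call)


def displacement_field(basis: ModeBasis, pc_index: int) -> np.ndarray:
    """Per-atom displacement vectors [A] of one mode, scaled by sqrt(eigenvalue).

    Reshapes the (sign-fixed) eigenvector to M x 3; the squared norms sum to
    the mode's eigenvalue. Intended for report/visualization export.
    """
    if not (1 <= pc_index <= basis.n_modes):
        raise ValueError(f"pc_index {pc_index} outside 1..{basis.n_modes}")
    v = basis.eigenvectors[pc_index - 1]
    lam = basis.eigenvalues[pc_index - 1]
    return (v * np.sqrt(max(lam, 0.0))).reshape(-1, 3)
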
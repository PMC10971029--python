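"""Free-energy landscapes over pairs of principal-component scores.

The landscape is the empirical joint distribution of two PC scores over
pooled trajectory frames, expressed in thermal units: bins receive
F = -ln(P / P_max) [kT], so the most populated bin has F = 0 and empty bins
are undefined (NaN) rather than capped. Temperature enters only through the
kT unit label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modes import ProjectionSeries

__all__ = ["FelGrid", "compute_fel"]


@dataclass
class FelGrid:
    """2-D free-energy grid over a PC pair.

    ``probability`` sums to 1; ``free_energy`` [kT] is 0 at the most
    populated bin, non-negative where defined and NaN on empty bins.
    """

    pc_pair: tuple[int, int]
    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if not np.isclose(self.probability.sum(), 1.0, atol=1e-8):
            raise ValueError("probability must sum to 1")
        occupied = self.probability > 0
        if occupied.any():
            fmin = np.nanmin(self.free_energy[occupied])
            if not np.isclose(fmin, 0.0, atol=1e-10):
                raise ValueError("minimum free energy over occupied bins must be 0")
        if np.any(self.free_energy[occupied] < -1e-10):
            raise ValueError("free energy must be non-negative where defined")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame(
            {
                "x_center": xc.ravel(),
                "y_center": yc.ravel(),
                "probability": self.probability.ravel(),
                "free_energy_kT": self.free_energy.ravel(),
            }
        )

    def to_tsv(self, path, meta_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if meta_path is not None:
            meta = {
                "pc_pair": list(self.pc_pair),
                "x_edges": self.x_edges.tolist(),
                "y_edges": self.y_edges.tolist(),
                "units": "kT",
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def compute_fel(
    proj: list[ProjectionSeries] | ProjectionSeries,
    pc_pair: tuple[int, int] = (1, 2),
    bins: int = 50,
    pad_fraction: float = 0.01,
) -> FelGrid:
    """Free-energy landscape from the joint histogram of two PC scores.

    ``pc_pair`` is 1-based and must name two distinct PCs. The grid spans
    the pooled data range on each axis, padded by ``pad_fraction``; a
    warning is issued when there are fewer pooled frames than bins.
    """
    if isinstance(proj, ProjectionSeries):
        proj = [proj]
    i, j = pc_pair
    if i == j:
        raise ValueError("pc_pair must name two distinct PCs")
    if i < 1 or j < 1:
        raise ValueError("pc_pair indices are 1-based")
    x = np.concatenate([p.scores[:, i - 1] for p in proj])
    y = np.concatenate([p.scores[:, j - 1] for p in proj])
    n = x.size
    if n < bins:
        warnings.warn(f"only {n} pooled frames for {bins} bins per axis", stacklevel=2)

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = pad_fraction * span if span > 0 else max(abs(hi), 1.0) * 1e-6
        return np.linspace(lo - pad, hi + pad, bins + 1)

    x_edges = _edges(x)
    y_edges = _edges(y)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    prob = counts / counts.sum()
    with np.errstate(divide="ignore"):
        free = -np.log(prob / prob.max())
    free[prob == 0] = np.nan
    return FelGrid(pc_pair=(i, j), x_edges=x_edges, y_edges=y_edges, probability=prob, free_energy=free)
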
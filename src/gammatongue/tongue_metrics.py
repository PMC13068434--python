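"""Arnold-tongue construction, normalization, comparison, and sizing.

An Arnold tongue here is a gridded map over (contrast heterogeneity zeta,
grid coarseness rho) of either model synchrony or behavioral accuracy. The
module provides the comparison toolkit: min-max normalization, Pearson
correlation, weighted Jaccard similarity (the more conservative of the two),
Simpson-rule tongue volume, a chance-floored 2D psychometric surface with its
75%-accuracy contour, and the fold-based noise ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import simpson


@dataclass
class ArnoldTongue:
    """Gridded (zeta x rho) map of synchrony, accuracy, or probability."""

    values: np.ndarray  # shape (n_zeta, n_rho)
    zeta_axis: np.ndarray
    rho_axis: np.ndarray
    kind: str = "synchrony"  # {"synchrony", "accuracy", "probability"}
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.zeta_axis = np.asarray(self.zeta_axis, dtype=float)
        self.rho_axis = np.asarray(self.rho_axis, dtype=float)
        if self.values.shape != (len(self.zeta_axis), len(self.rho_axis)):
            raise ValueError("values shape must be (n_zeta, n_rho)")
        if np.any(np.diff(self.zeta_axis) <= 0) or np.any(np.diff(self.rho_axis) <= 0):
            raise ValueError("axes must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.zeta_axis, columns=self.rho_axis)
        df.index.name = "zeta"
        df.columns.name = "rho"
        df.to_csv(Path(path))

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "synchrony") -> "ArnoldTongue":
        df = pd.read_csv(Path(path), index_col=0)
        return cls(
            values=df.to_numpy(),
            zeta_axis=df.index.to_numpy(dtype=float),
            rho_axis=df.columns.to_numpy(dtype=float),
            kind=kind,
        )


def _same_shape(A: ArnoldTongue, B: ArnoldTongue) -> None:
    if A.values.shape != B.values.shape:
        raise ValueError("tongues must share the same grid shape")


def minmax_normalize(tongue: ArnoldTongue) -> ArnoldTongue:
    """Rescale values to [0, 1] via (v - min) / (max - min)."""
    v = tongue.values
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        raise ValueError("cannot min-max normalize a constant map")
    return replace(tongue, values=(v - lo) / (hi - lo), normalized=True)


def pearson_similarity(A: ArnoldTongue, B: ArnoldTongue) -> float:
    """Product-moment correlation between the two maps, cellwise."""
    _same_shape(A, B)
    a, b = A.values.ravel(), B.values.ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(stats.pearsonr(a, b).statistic)


def weighted_jaccard(A: ArnoldTongue, B: ArnoldTongue) -> float:
    """Weighted Jaccard similarity: sum min(a, b) / sum max(a, b).

    Both maps must be nonnegative (min-max normalize first when comparing
    accuracy to synchrony so they share the [0, 1] range). Two all-zero maps
    are defined as identical (similarity 1).
    """
    _same_shape(A, B)
    a, b = A.values.ravel(), B.values.ravel()
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("weighted Jaccard requires nonnegative values")
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 1.0
    return float(np.minimum(a, b).sum() / denom)


def tongue_size(tongue: ArnoldTongue) -> float:
    """Volume under the tongue surface by 2D composite Simpson integration."""
    if len(tongue.zeta_axis) < 3 or len(tongue.rho_axis) < 3:
        raise ValueError("Simpson integration needs at least 3 points per axis")
    inner = simpson(tongue.values, x=tongue.rho_axis, axis=1)
    return float(simpson(inner, x=tongue.zeta_axis))


@dataclass
class TongueSurfaceFit:
    """Chance-floored logistic accuracy surface over (zeta, rho).

    accuracy = 0.5 + 0.5 / (1 + exp(-(b0 + b1*zeta + b2*rho + b3*zeta*rho)))
    """

    beta: np.ndarray  # (4,)
    converged: bool

    def predict(self, zeta, rho) -> np.ndarray:
        z = np.asarray(zeta, dtype=float)
        r = np.asarray(rho, dtype=float)
        eta = self.beta[0] + self.beta[1] * z + self.beta[2] * r + self.beta[3] * z * r
        return 0.5 + 0.5 / (1.0 + np.exp(-eta))

    def contour_75(
        self, zeta_range: tuple[float, float], rho_range: tuple[float, float], n: int = 201
    ) -> np.ndarray | None:
        """Points (zeta, rho) of the 75%-accuracy level set, or None if absent.

        Accuracy 0.75 corresponds to eta = 0, i.e. the line
        b0 + b1*zeta + b2*rho + b3*zeta*rho = 0; solved for rho on a zeta grid.
        """
        zg = np.linspace(*zeta_range, n)
        denom = self.beta[2] + self.beta[3] * zg
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = -(self.beta[0] + self.beta[1] * zg) / denom
        ok = np.isfinite(rho) & (rho >= rho_range[0]) & (rho <= rho_range[1])
        if not ok.any():
            return None
        return np.column_stack([zg[ok], rho[ok]])


def fit_tongue_surface(
    accuracy_tongue: ArnoldTongue, trial_counts: np.ndarray | int
) -> TongueSurfaceFit:
    """Fit the 2AFC surface to per-condition accuracies by binomial likelihood."""
    acc = accuracy_tongue.values
    counts = np.broadcast_to(np.asarray(trial_counts, dtype=float), acc.shape)
    k = np.round(acc * counts)
    zz, rr = np.meshgrid(accuracy_tongue.zeta_axis, accuracy_tongue.rho_axis, indexing="ij")

    def nll(beta):
        eta = beta[0] + beta[1] * zz + beta[2] * rr + beta[3] * zz * rr
        p = 0.5 + 0.5 / (1.0 + np.exp(-eta))
        p = np.clip(p, 0.5 + 1e-9, 1.0 - 1e-9)
        return -(k * np.log(p) + (counts - k) * np.log(1.0 - p)).sum()

    res = optimize.minimize(nll, x0=np.zeros(4), method="Nelder-Mead",
                            options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"tongue surface fit failed: {res.message}")
    return TongueSurfaceFit(beta=res.x, converged=bool(res.success))


def noise_ceiling(
    fold_mean_tongues: list[ArnoldTongue],
    leftout_tongues: list[ArnoldTongue],
    metric=weighted_jaccard,
) -> tuple[float, float]:
    """25th-75th percentile band of metric(fold mean, left-out participant).

    Each fold pairs the mean tongue of the held-in group with the left-out
    participant's tongue; the band bounds the attainable model-behavior fit.
    """
    if len(fold_mean_tongues) < 2 or len(fold_mean_tongues) != len(leftout_tongues):
        raise ValueError("need >= 2 aligned folds")
    vals = [metric(m, l) for m, l in zip(fold_mean_tongues, leftout_tongues)]
    lo, hi = np.percentile(vals, [25, 75])
    return float(lo), float(hi)


def mean_tongue(tongues: list[ArnoldTongue]) -> ArnoldTongue:
    """Cellwise mean of tongues sharing one grid."""
    if not tongues:
        raise ValueError("empty tongue list")
    for t in tongues[1:]:
        _same_shape(tongues[0], t)
    return replace(tongues[0], values=np.mean([t.values for t in tongues], axis=0))
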
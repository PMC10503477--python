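"""Single-limb GRF curve analysis: stance resampling and permutation SPM.

Force curves recorded at high rate are resampled onto a fixed grid of 50
intervals per stance.  Group ensembles of curves are compared over the
whole stance domain with a nonparametric one-dimensional statistical
parametric mapping (SPM) procedure: a pointwise two-sample t-field,
thresholded at the (1 - alpha) quantile of the permutation distribution of
the field maximum of |t| under group-label exchange.  The max-statistic
threshold controls the family-wise (cluster-level) error across the curve
while respecting the dependence of neighboring stance nodes; suprathreshold
clusters receive p-values from the same permutation distribution evaluated
at the cluster's peak |t|.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import DomainError, IntegrityError

__all__ = [
    "resample_stance",
    "split_stance_halves",
    "spm_two_sample",
    "summarize_grf",
    "SPMResult",
    "SPMCluster",
]

N_INTERVALS_DEFAULT = 50


@dataclass
class SPMCluster:
    start: float   # stance fraction of first suprathreshold node
    end: float     # stance fraction of last suprathreshold node
    p_value: float
    peak_t: float


@dataclass
class SPMResult:
    node_t: np.ndarray            # t statistic per stance node
    stance_fraction: np.ndarray
    critical_threshold: float
    clusters: list                # list[SPMCluster]
    alpha: float
    n_permutations: int

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


# ------------------------------------------------------------------ resample

def resample_stance(forces, times=None, n_intervals: int = N_INTERVALS_DEFAULT):
    """Linear interpolation of a stance-phase curve onto ``n_intervals + 1`` nodes.

    ``times`` are stance fractions (or raw times; they are rescaled to
    [0, 1]).  Defaults to an evenly spaced source grid when omitted.
    Returns ``(stance_fraction, force)`` arrays.
    """
    forces = np.asarray(forces, dtype=float)
    if forces.size < 2:
        raise DomainError("need at least 2 samples to resample a stance")
    if times is None:
        times = np.linspace(0.0, 1.0, forces.size)
    else:
        times = np.asarray(times, dtype=float)
        if times.shape != forces.shape:
            raise IntegrityError("times and forces lengths differ")
        if np.any(np.diff(times) <= 0):
            raise IntegrityError("sample times must be strictly increasing")
        times = (times - times[0]) / (times[-1] - times[0])
    grid = np.linspace(0.0, 1.0, n_intervals + 1)
    return grid, np.interp(grid, times, forces)


def split_stance_halves(grid: np.ndarray, forces: np.ndarray):
    """First and last half of a stance curve; the midpoint node belongs to both."""
    grid = np.asarray(grid)
    forces = np.asarray(forces)
    mid = np.searchsorted(grid, 0.5, side="left")
    first = (grid[: mid + 1], forces[: mid + 1])
    second = (grid[mid:], forces[mid:])
    return first, second


# ----------------------------------------------------------------------- SPM

def _t_field(curves: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistic per node; 0 where variance is 0."""
    a = curves[~group_b]
    b = curves[group_b]
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / denom, 0.0)
    return t


def _permutation_masks(n: int, nb: int, n_permutations: int, rng) -> np.ndarray:
    """Boolean masks (rows) assigning ``nb`` of ``n`` curves to group B."""
    from math import comb

    total = comb(n, nb)
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), nb)):
            masks[i, list(idx)] = True
        return masks
    masks = np.zeros((n_permutations, n), dtype=bool)
    for i in range(n_permutations):
        masks[i, rng.choice(n, size=nb, replace=False)] = True
    return masks


def spm_two_sample(
    curves_a,
    curves_b,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    rng=None,
    stance_fraction=None,
) -> SPMResult:
    """Permutation SPM comparison of two ensembles of stance curves.

    ``curves_a`` and ``curves_b`` are (n_curves, n_nodes) arrays on a
    common grid.  Deterministic given ``rng``; when the number of distinct
    group relabelings is at most ``n_permutations`` the permutation
    distribution is enumerated exactly.
    """
    A = np.atleast_2d(np.asarray(curves_a, dtype=float))
    B = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DomainError("curve ensembles must share a common grid")
    if len(A) < 3 or len(B) < 3:
        raise DomainError("need at least 3 curves per group")
    if n_permutations < 1.0 / alpha:
        warnings.warn(
            f"{n_permutations} permutations cannot resolve alpha={alpha}",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng()
    n_nodes = A.shape[1]
    if stance_fraction is None:
        stance_fraction = np.linspace(0.0, 1.0, n_nodes)
    else:
        stance_fraction = np.asarray(stance_fraction, dtype=float)

    curves = np.vstack([A, B])
    n, nb = len(curves), len(B)
    observed_mask = np.zeros(n, dtype=bool)
    observed_mask[len(A):] = True
    t_obs = _t_field(curves, observed_mask)

    masks = _permutation_masks(n, nb, n_permutations, rng)
    max_abs = np.empty(len(masks))
    for i, mask in enumerate(masks):
        max_abs[i] = np.max(np.abs(_t_field(curves, mask)))
    threshold = float(np.quantile(max_abs, 1.0 - alpha))

    clusters = []
    supra = np.abs(t_obs) > threshold
    if supra.any():
        edges = np.flatnonzero(np.diff(np.concatenate([[0], supra.view(np.int8), [0]])))
        for start, stop in zip(edges[0::2], edges[1::2]):
            peak = float(np.max(np.abs(t_obs[start:stop])))
            p = float((1 + np.sum(max_abs >= peak)) / (1 + len(max_abs)))
            clusters.append(
                SPMCluster(
                    start=float(stance_fraction[start]),
                    end=float(stance_fraction[stop - 1]),
                    p_value=p,
                    peak_t=peak,
                )
            )
    return SPMResult(
        node_t=t_obs,
        stance_fraction=stance_fraction,
        critical_threshold=threshold,
        clusters=clusters,
        alpha=alpha,
        n_permutations=len(masks),
    )


# ------------------------------------------------------------------- summary

def summarize_grf(curves) -> dict:
    """Pointwise mean and min/max envelope of a curve ensemble."""
    C = np.atleast_2d(np.asarray(curves, dtype=float))
    if C.size == 0:
        raise DomainError("need at least one curve")
    return {
        "mean": C.mean(axis=0),
        "min": C.min(axis=0),
        "max": C.max(axis=0),
    }
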
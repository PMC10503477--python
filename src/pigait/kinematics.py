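"""Fourier decomposition of cyclic joint-angle traces.

A walking cycle's joint angle theta(t), t in [0, 1) cycle fractions anchored
at limb touchdown, is decomposed in exponential form

    c_n = (1/N) * sum_k theta(t_k) exp(-i 2 pi n k / N),    n = 0..H

with H = 8 harmonics retained.  ``c0`` is the mean joint angle; the
oscillation amplitude is defined as the RMS amplitude

    A = sqrt(2 * sum_{n=1..H} |c_n|^2)

and the amplitude-normalized harmonics ``c_n / A`` form the "shape"
vector (so 2 sum |shape_n|^2 = 1).  Mean angle and amplitude are postural descriptors; the
6 joints x 8 harmonics x 2 (re/im) = 96 pooled shape values, reduced to
12 principal components, are coordination descriptors.

Angle convention: interior joint angle in radians, pi = fully extended,
0 = fully flexed; traces start at touchdown of the limb.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .bayes import ConjugateLinearModel
from .errors import DomainError, IntegrityError

__all__ = [
    "JOINTS",
    "N_HARMONICS",
    "JointTrace",
    "FourierDescriptor",
    "resample_cycle",
    "fourier_decompose",
    "fourier_reconstruct",
    "affine_split",
    "descriptor_to_coeffs",
    "range_of_motion",
    "coordination_pca",
    "shape_matrix_from_descriptors",
    "compare_posture",
]

JOINTS = ("shoulder", "elbow", "carpal", "hip", "knee", "tarsal")
N_HARMONICS = 8


@dataclass
class JointTrace:
    """A joint's angle-vs-cycle-fraction curve (radians)."""

    joint: str
    cycle_fraction: np.ndarray  # in [0, 1), strictly increasing, first sample 0
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.cycle_fraction = np.asarray(self.cycle_fraction, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.cycle_fraction.shape != self.angle.shape:
            raise IntegrityError("cycle_fraction and angle lengths differ")

    def __len__(self) -> int:
        return len(self.angle)


@dataclass
class FourierDescriptor:
    """Mean angle, RMS amplitude, and amplitude-normalized harmonic shape.

    The shape vector is ``c_n / A`` with ``A = sqrt(2 sum |c_n|^2)``, so it
    satisfies ``2 sum |shape_n|^2 = 1`` when the amplitude is positive (a
    pure first-harmonic cosine has ``shape_1 = 1/sqrt(2)``) and is all-zero
    for a constant trace.
    """

    joint: str
    mean_angle: float
    amplitude: float
    shape: np.ndarray  # complex, length N_HARMONICS

    @property
    def shape_real(self) -> np.ndarray:
        """Interleaved (re, im) representation, length 2 * N_HARMONICS."""
        out = np.empty(2 * len(self.shape))
        out[0::2] = self.shape.real
        out[1::2] = self.shape.imag
        return out


# ------------------------------------------------------------------ sampling

def resample_cycle(trace: JointTrace, n_samples: int) -> JointTrace:
    """Periodic linear interpolation onto ``n_samples`` uniform cycle fractions."""
    x, y = trace.cycle_fraction, trace.angle
    if len(x) < 3:
        raise IntegrityError("need at least 3 samples to resample a cycle")
    if np.any(np.diff(x) <= 0):
        raise IntegrityError("cycle fractions must be strictly increasing")
    if x[0] < 0 or x[-1] >= 1:
        raise IntegrityError("cycle fractions must lie in [0, 1)")
    grid = np.arange(n_samples) / n_samples
    # wrap one sample on each side so interpolation is periodic
    xe = np.concatenate([[x[-1] - 1.0], x, [x[0] + 1.0]])
    ye = np.concatenate([[y[-1]], y, [y[0]]])
    return JointTrace(trace.joint, grid, np.interp(grid, xe, ye))


# ------------------------------------------------------------------- Fourier

def fourier_decompose(trace: JointTrace, n_harmonics: int = N_HARMONICS) -> np.ndarray:
    """Complex coefficients ``c_0 .. c_H`` of a uniformly sampled cycle."""
    theta = trace.angle
    n = len(theta)
    if n < 2 * n_harmonics + 1:
        raise DomainError(
            f"{n} samples alias {n_harmonics} harmonics; need >= {2 * n_harmonics + 1}"
        )
    grid = np.arange(n) / n
    if not np.allclose(trace.cycle_fraction, grid, atol=1e-9):
        raise IntegrityError("fourier_decompose requires a uniform grid starting at 0")
    coeffs = np.fft.fft(theta) / n
    out = coeffs[: n_harmonics + 1].copy()
    out[0] = out[0].real  # mean angle is real by construction
    return out


def fourier_reconstruct(coeffs: np.ndarray, n_samples: int, joint: str = "") -> JointTrace:
    """Evaluate ``theta(t) = c0 + 2 sum_n Re(c_n exp(i 2 pi n t))`` on a uniform grid."""
    coeffs = np.asarray(coeffs, dtype=complex)
    t = np.arange(n_samples) / n_samples
    harmonics = np.arange(1, len(coeffs))
    phase = np.exp(2j * np.pi * np.outer(t, harmonics))
    theta = coeffs[0].real + 2.0 * (phase @ coeffs[1:]).real
    return JointTrace(joint, t, theta)


def affine_split(coeffs: np.ndarray, joint: str = "") -> FourierDescriptor:
    """Split coefficients into mean angle, RMS amplitude, and normalized shape."""
    coeffs = np.asarray(coeffs, dtype=complex)
    mean = float(coeffs[0].real)
    osc = coeffs[1:]
    amplitude = float(np.sqrt(2.0 * np.sum(np.abs(osc) ** 2)))
    if amplitude > 0:
        shape = osc / amplitude
    else:
        shape = np.zeros_like(osc)
    return FourierDescriptor(joint, mean, amplitude, shape)


def descriptor_to_coeffs(desc: FourierDescriptor) -> np.ndarray:
    """Inverse of :func:`affine_split`."""
    return np.concatenate([[desc.mean_angle + 0j], desc.amplitude * desc.shape])


def range_of_motion(trace: JointTrace) -> float:
    """Max minus min joint angle over the cycle (radians)."""
    if len(trace) == 0:
        raise DomainError("empty trace")
    return float(np.max(trace.angle) - np.min(trace.angle))


# ----------------------------------------------------------------- PCA block

def shape_matrix_from_descriptors(per_stride: list) -> np.ndarray:
    """Stack per-stride shape descriptors into an (n_strides x 96) matrix.

    ``per_stride`` is a list of mappings joint -> FourierDescriptor covering
    all six joints.
    """
    rows = []
    for stride in per_stride:
        parts = [stride[j].shape_real for j in JOINTS]
        rows.append(np.concatenate(parts))
    return np.asarray(rows)


def coordination_pca(shape_matrix: np.ndarray, n_pcs: int = 12):
    """Column-centered PCA of the pooled shape matrix.

    Returns ``(scores, loadings, explained_variance_ratio)`` with loadings of
    shape (n_features, n_pcs), orthonormal columns, and a fixed sign
    convention (largest-magnitude loading element positive).
    """
    X = np.asarray(shape_matrix, dtype=float)
    n, p = X.shape
    if n <= n_pcs:
        raise DomainError(f"need more than {n_pcs} strides for {n_pcs} PCs, got {n}")
    if not np.any(X.var(axis=0) > 0):  # identical rows: no variance to decompose
        return np.zeros((n, n_pcs)), np.eye(p)[:, :n_pcs], np.zeros(n_pcs)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    return scores, loadings, pca.explained_variance_ratio_.copy()


def project_shapes(shape_matrix: np.ndarray, loadings: np.ndarray, center: np.ndarray):
    """Project shape rows onto frozen loadings (centering with frozen means)."""
    return (np.asarray(shape_matrix) - center) @ loadings


# --------------------------------------------------------- group comparison

def _posture_table(per_stride: list, scores: np.ndarray) -> pd.DataFrame:
    cols = {}
    for j in JOINTS:
        cols[f"mean_{j}"] = [s[j].mean_angle for s in per_stride]
    for j in JOINTS:
        roms = []
        for s in per_stride:
            trace = fourier_reconstruct(descriptor_to_coeffs(s[j]), 200, j)
            roms.append(range_of_motion(trace))
        cols[f"rom_{j}"] = roms
    for k in range(scores.shape[1]):
        cols[f"pc{k + 1}"] = scores[:, k]
    return pd.DataFrame(cols)


def compare_posture(
    descriptors_a: list,
    descriptors_b: list,
    rng=None,
    level: float = 0.95,
    n_pcs: int = 12,
) -> pd.DataFrame:
    """Bayesian group comparison of postural and coordination variables.

    ``descriptors_a``/``descriptors_b`` are lists (one entry per stride) of
    mappings joint -> :class:`FourierDescriptor`.  For each of the 6 mean
    angles, 6 ranges of motion, and ``n_pcs`` coordination components a
    conjugate Bayesian linear model ``value ~ group`` is fitted; the group
    coefficient posterior gives the B-minus-A difference.  The posterior is
    closed form, so ``rng`` is accepted for interface stability but unused.

    Returns a DataFrame with columns ``variable, mean_diff, ci_lo, ci_hi,
    excludes_zero, residual_sd``.
    """
    if len(descriptors_a) < 2 or len(descriptors_b) < 2:
        raise DomainError("need at least 2 strides per group")
    pooled = list(descriptors_a) + list(descriptors_b)
    shapes = shape_matrix_from_descriptors(pooled)
    scores, _, _ = coordination_pca(shapes, n_pcs=n_pcs)
    table = _posture_table(pooled, scores)
    group = np.concatenate([np.zeros(len(descriptors_a)), np.ones(len(descriptors_b))])

    rows = []
    for var in table.columns:
        y = table[var].to_numpy()
        if np.std(y) == 0:
            rows.append(
                dict(variable=var, mean_diff=0.0, ci_lo=0.0, ci_hi=0.0,
                     excludes_zero=False, residual_sd=0.0, degenerate=True)
            )
            continue
        model = ConjugateLinearModel().fit(group[:, None], y, feature_names=["group"])
        summ = model.coefficient_summary()
        lo, hi = model.coefficient_interval(0, level=level)
        rows.append(
            dict(
                variable=var,
                mean_diff=float(summ.mean[0]),
                ci_lo=float(lo),
                ci_hi=float(hi),
                excludes_zero=bool(lo > 0 or hi < 0),
                residual_sd=model.residual_scale,
                degenerate=False,
            )
        )
    return pd.DataFrame(rows)
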
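"""Covariance features on the SPD manifold.

Multi-band covariance matrices of anesthetic EEG are symmetric positive
definite (SPD) and live on a curved Riemannian manifold.  This module
provides everything the pipeline needs on that manifold:

* exact Oracle Approximating Shrinkage (OAS) covariance estimation,
  guaranteeing positive definiteness for short segments,
* the affine-invariant Riemannian metric (AIRM)
  ``d(A, B) = ||log(A^{-1/2} B A^{-1/2})||_F``,
* the Karcher (geometric) mean and the class-balanced reference point,
* an adaptive "Riemannian potato" outlier rejector for covariance frames,
* tangent-space projection at a reference point, producing Euclidean
  vectors whose norm equals the manifold distance to the reference.

All matrix functions go through symmetric eigendecompositions with an
eigenvalue floor for numerical safety.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .config import DEFAULT_BANDS
from .errors import ContractError, DegenerateInputError, NumericalError

EIG_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# symmetric matrix functions
# ---------------------------------------------------------------------------

def _eigh_fun(mat: np.ndarray, fun, floor: float = EIG_FLOOR) -> np.ndarray:
    """Apply ``fun`` to the eigenvalues of a symmetric matrix."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    w = np.maximum(w, floor)
    return (v * fun(w)) @ v.T


def logm_spd(mat: np.ndarray) -> np.ndarray:
    return _eigh_fun(mat, np.log)


def expm_sym(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    return (v * np.exp(w)) @ v.T


def sqrtm_spd(mat: np.ndarray) -> np.ndarray:
    return _eigh_fun(mat, np.sqrt)


def invsqrtm_spd(mat: np.ndarray) -> np.ndarray:
    return _eigh_fun(mat, lambda w: 1.0 / np.sqrt(w))


def powm_spd(mat: np.ndarray, p: float) -> np.ndarray:
    return _eigh_fun(mat, lambda w: w**p)


def is_spd(mat: np.ndarray, sym_tol: float = 1e-9) -> bool:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        return False
    if not np.allclose(mat, mat.T, atol=sym_tol):
        return False
    return bool(np.linalg.eigvalsh((mat + mat.T) / 2.0).min() > 0)


def _check_spd(mat: np.ndarray, name: str = "matrix") -> None:
    if not is_spd(mat):
        raise ContractError(f"{name} is not symmetric positive definite")


# ---------------------------------------------------------------------------
# OAS covariance
# ---------------------------------------------------------------------------

def oas_covariance(block: np.ndarray) -> np.ndarray:
    """Shrunk covariance of a (features x samples) block.

    Implements the closed-form oracle-approximating shrinkage of Chen,
    Wiesel, Eldar & Hero (2010): the empirical covariance S is shrunk
    toward the scaled identity ``mu I`` with ``mu = tr(S)/p`` and

        rho = min(1, [(1 - 2/p) tr(S^2) + tr(S)^2]
                     / [(n + 1 - 2/p) (tr(S^2) - tr(S)^2 / p)]).

    The convex combination ``(1 - rho) S + rho mu I`` is positive definite
    whenever the block is not identically constant, which makes every
    per-segment covariance a valid point on the SPD manifold.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ContractError("covariance block must be 2-D (features x samples)")
    p, n = block.shape
    if n < 2:
        raise ContractError(f"need >= 2 samples for a covariance, got {n}")
    centered = block - block.mean(axis=1, keepdims=True)
    emp = centered @ centered.T / n
    tr_s = np.trace(emp)
    tr_s2 = float(np.sum(emp * emp))  # tr(S @ S) for symmetric S
    mu = tr_s / p
    if mu <= 0:
        raise DegenerateInputError("constant block has no covariance structure")
    num = (1.0 - 2.0 / p) * tr_s2 + tr_s**2
    den = (n + 1.0 - 2.0 / p) * (tr_s2 - tr_s**2 / p)
    rho = 1.0 if den <= 0 else min(1.0, num / den)
    shrunk = (1.0 - rho) * emp
    shrunk[np.diag_indices(p)] += rho * mu
    return shrunk


# ---------------------------------------------------------------------------
# metric, mean, tangent space
# ---------------------------------------------------------------------------

def airm_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices."""
    _check_spd(a, "A")
    _check_spd(b, "B")
    if a.shape != b.shape:
        raise ContractError("dimension mismatch")
    w = invsqrtm_spd(a)
    log_ab = logm_spd(w @ b @ w)
    return float(np.linalg.norm(log_ab, "fro"))


def riemannian_mean(
    mats,
    weights=None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> np.ndarray:
    """Karcher (Frechet) mean of SPD matrices under the AIRM.

    Fixed-point iteration ``M <- M^{1/2} exp(sum_i w_i log(M^{-1/2} C_i
    M^{-1/2})) M^{1/2}`` starting from the log-Euclidean mean; converged
    when the Frobenius norm of the weighted tangent mean drops below
    ``tol``.
    """
    mats = [np.asarray(m, dtype=float) for m in mats]
    if not mats:
        raise ContractError("empty list of matrices")
    if weights is None:
        weights = np.full(len(mats), 1.0 / len(mats))
    else:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    if len(mats) == 1:
        return mats[0].copy()
    logs = np.stack([logm_spd(m) for m in mats])
    mean = expm_sym(np.tensordot(weights, logs, axes=1))
    step, prev_norm = 1.0, np.inf
    for _ in range(max_iter):
        w_half = sqrtm_spd(mean)
        w_ihalf = invsqrtm_spd(mean)
        tangent = np.zeros_like(mean)
        for wi, c in zip(weights, mats):
            tangent += wi * logm_spd(w_ihalf @ c @ w_ihalf)
        norm = np.linalg.norm(tangent, "fro")
        if norm < tol:
            return mean
        if norm >= prev_norm:   # not contracting: damp the fixed point
            step = max(step / 2.0, 0.05)
        prev_norm = norm
        mean = w_half @ expm_sym(step * tangent) @ w_half
        mean = (mean + mean.T) / 2.0
    raise NumericalError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(last tangent norm {norm:.3e}, n={len(mats)}, p={mean.shape[0]})"
    )


def geodesic_step(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Point at fraction ``t`` along the AIRM geodesic from ``a`` to ``b``."""
    w_half = sqrtm_spd(a)
    w_ihalf = invsqrtm_spd(a)
    mid = powm_spd(w_ihalf @ b @ w_ihalf, t)
    out = w_half @ mid @ w_half
    return (out + out.T) / 2.0


def balanced_reference(mats, labels, tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    """Class-balanced Riemannian reference point.

    The Karcher mean is taken over the frames of each class first, then
    over the two class means with equal weights, so the reference is
    invariant to class-size imbalance.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ContractError(f"need exactly two classes, got {list(classes)}")
    mats = list(mats)
    class_means = [
        riemannian_mean([m for m, l in zip(mats, labels) if l == c],
                        tol=tol, max_iter=max_iter)
        for c in classes
    ]
    return riemannian_mean(class_means, tol=tol, max_iter=max_iter)


def tangent_project(mats, reference: np.ndarray) -> np.ndarray:
    """Project SPD matrices to the tangent space at ``reference``.

    Each matrix C maps to the vectorized upper triangle (off-diagonal
    entries scaled by sqrt(2)) of ``log(R^{-1/2} C R^{-1/2})``, so the
    Euclidean norm of the vector equals the AIRM distance d(R, C).
    """
    _check_spd(reference, "reference")
    w = invsqrtm_spd(reference)
    single = isinstance(mats, np.ndarray) and mats.ndim == 2
    if single:
        mats = [mats]
    p = reference.shape[0]
    iu = np.triu_indices(p)
    scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    out = np.empty((len(mats), p * (p + 1) // 2))
    for i, c in enumerate(mats):
        log_c = logm_spd(w @ np.asarray(c, dtype=float) @ w)
        out[i] = log_c[iu] * scale
    return out[0] if single else out


def tangent_unproject(vec: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_project` (exponential map at the reference)."""
    p = reference.shape[0]
    iu = np.triu_indices(p)
    scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    sym = np.zeros((p, p))
    sym[iu] = np.asarray(vec, dtype=float) / scale
    sym = sym + sym.T - np.diag(np.diag(sym))
    w_half = sqrtm_spd(reference)
    out = w_half @ expm_sym(sym) @ w_half
    return (out + out.T) / 2.0


# ---------------------------------------------------------------------------
# Riemannian potato
# ---------------------------------------------------------------------------

def riemannian_potato(
    mats,
    z_threshold: float = 2.5,
    adapt_rate: float = 0.1,
    burn_in: int = 10,
    history: int = 50,
) -> np.ndarray:
    """Adaptive outlier rejection for a sequence of covariance frames.

    A running geometric mean tracks the frame stream; each frame's
    distance to the mean is z-scored against the mean and standard
    deviation of recent inlier distances and the frame is flagged when
    the z-score exceeds ``z_threshold``.  The mean moves
    a geodesic step of size ``adapt_rate`` toward inlier frames only, so a
    flagged frame never contaminates the reference.  The first ``burn_in``
    frames seed the mean and the distance statistics and are then scored
    like every other frame.

    Returns a boolean inlier mask (True = keep).  Because the AIRM is
    affine invariant, the mask is unchanged under a common rescaling or
    congruence transform of all frames.
    """
    mats = [np.asarray(m, dtype=float) for m in mats]
    n = len(mats)
    if n < 2:
        raise ContractError("potato needs at least 2 frames")
    burn_in = min(burn_in, n)
    # the burn-in mean only seeds the adaptive reference; a loose
    # tolerance is ample (distances involved are O(1))
    mean = riemannian_mean(mats[:burn_in], tol=1e-4, max_iter=100)
    dists = deque(maxlen=history)
    for m in mats[:burn_in]:
        dists.append(airm_distance(mean, m))
    mask = np.ones(n, dtype=bool)
    for i, m in enumerate(mats):
        d = airm_distance(mean, m)
        arr = np.fromiter(dists, dtype=float)
        z = (d - arr.mean()) / max(arr.std(), 1e-12)
        if i >= burn_in and z > z_threshold:
            mask[i] = False
            continue
        if i >= burn_in:
            dists.append(d)
            mean = geodesic_step(mean, m, adapt_rate)
    if not mask.any():
        raise DegenerateInputError("every frame was flagged by the potato")
    return mask


# ---------------------------------------------------------------------------
# multi-band stacking
# ---------------------------------------------------------------------------

@dataclass
class MultibandSignal:
    """Band-filtered copies of the 4 channels stacked with the
    burst-suppression timeline: (channels x bands + 1) rows x samples.

    Row order is channel-major within band, bands low to high, timeline
    last; the order is fixed and serialized with any trained model.
    """

    data: np.ndarray
    band_edges: tuple = DEFAULT_BANDS

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


def _band_sos(low: float, high: float, fs: float, order: int = 4):
    return butter(order, [low, high], btype="band", fs=fs, output="sos")


def multiband_stack(
    segments,
    timelines,
    fs: float,
    bands=DEFAULT_BANDS,
    order: int = 4,
) -> list[MultibandSignal]:
    """Build one multi-band block per segment.

    ``segments`` is a list of (channels x samples) z-scored blocks and
    ``timelines`` the per-segment suppression timelines at the same rate.
    Each output block has ``4 * len(bands) + 1`` rows.
    """
    if len(segments) != len(timelines):
        raise ContractError("timeline list not aligned with segments")
    sos_list = [_band_sos(lo, hi, fs, order) for lo, hi in bands]
    out = []
    for block, tl in zip(segments, timelines):
        block = np.asarray(block, dtype=float)
        if tl.shape[-1] != block.shape[-1]:
            raise ContractError("timeline length does not match segment length")
        rows = [sosfiltfilt(sos, block, axis=-1) for sos in sos_list]
        stacked = np.vstack(rows + [np.asarray(tl, dtype=float)[None, :]])
        out.append(MultibandSignal(stacked, tuple(bands)))
    return out
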
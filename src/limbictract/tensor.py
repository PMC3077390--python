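"""Diffusion tensor estimation and FA/RD/AD scalar maps.

The tensor is fitted per voxel by ordinary log-linear least squares on
``ln(S_i / S0) = -b_i g_i^T D g_i`` — the classical closed-form estimator.
Eigenvalues are sorted descending and clamped to zero (with a flag) before
computing the scalar metrics, so noisy background voxels cannot produce
FA > 1:

* ``FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||``
* ``RD = (lambda2 + lambda3) / 2``
* ``AD = lambda1``
"""

from __future__ import annotations

import numpy as np

from .core import ImageGrid, ScalarMap, TensorVolume, tensor_coeffs_to_matrices
from .synthetic import GradientScheme, design_matrix

__all__ = [
    "fit_tensor",
    "eigendecompose",
    "fa_value",
    "rd_value",
    "ad_value",
    "scalar_maps",
    "principal_directions",
]


def fit_tensor(dwi: np.ndarray, scheme: GradientScheme,
               grid: ImageGrid | None = None) -> TensorVolume:
    """Log-linear least-squares tensor fit of a 4D (x, y, z, volume) DWI.

    Multiple b=0 volumes are averaged into the baseline S0 before taking the
    log ratio.  Voxels with S0 <= 0 get a zero tensor and are flagged in
    ``TensorVolume.invalid``.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, volume)")
    if dwi.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"dwi has {dwi.shape[3]} volumes but the gradient scheme has {scheme.n_volumes}"
        )
    if grid is None:
        grid = ImageGrid(shape=dwi.shape[:3], voxel_size=(1.0, 1.0, 1.0))

    b0 = scheme.b0_mask
    dw = ~b0
    B = design_matrix(scheme.directions[dw], scheme.bvalues[dw])  # (m, 6)
    if np.linalg.matrix_rank(B) < 6:
        raise ValueError("gradient directions are collinear; design is rank-deficient")
    pinv = np.linalg.pinv(B)  # (6, m)

    s0 = dwi[..., b0].mean(axis=-1)
    invalid = ~(s0 > 0) | ~np.isfinite(s0)
    s0_safe = np.where(invalid, 1.0, s0)
    sig = np.clip(dwi[..., dw], 1e-12, None)
    logratio = -np.log(sig / s0_safe[..., None])  # (x, y, z, m) = B d
    coeffs = np.einsum("cm,...m->...c", pinv, logratio)
    coeffs[invalid] = 0.0
    return TensorVolume(coeffs=coeffs, grid=grid, invalid=invalid)


def eigendecompose(tensor: np.ndarray):
    """Eigendecomposition of symmetric tensors, eigenvalues sorted descending.

    Accepts a (3, 3) matrix, a 6-coefficient vector, or arrays thereof.
    Returns ``(eigenvalues, eigenvectors)`` where ``eigenvectors[..., :, k]``
    is the unit eigenvector of ``eigenvalues[..., k]``.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape[-1] == 6 and (t.ndim == 1 or t.shape[-2:] != (3, 3)):
        t = tensor_coeffs_to_matrices(t)
    if t.shape[-2:] != (3, 3):
        raise ValueError("tensor must be (..., 3, 3) or (..., 6)")
    if not np.all(np.isfinite(t)):
        raise ValueError("tensor contains non-finite values")
    evals, evecs = np.linalg.eigh(t)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., :, ::-1]
    return evals, evecs


def _clamped(evals: np.ndarray):
    clamped = np.clip(evals, 0.0, None)
    flag = np.any(evals < 0, axis=-1)
    return clamped, flag


def fa_value(l1, l2, l3):
    """Fractional anisotropy from (nonnegative) eigenvalues; 0 for all-zero."""
    lam = np.stack(np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)), axis=-1)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return fa if fa.ndim else float(fa)


def rd_value(l2, l3):
    """Radial diffusivity: mean of the two minor eigenvalues."""
    out = (np.asarray(l2, float) + np.asarray(l3, float)) / 2.0
    return out if out.ndim else float(out)


def ad_value(l1):
    """Axial diffusivity: the major eigenvalue."""
    out = np.asarray(l1, float) + 0.0
    return out if out.ndim else float(out)


def scalar_maps(tensors: TensorVolume):
    """FA, RD and AD maps from a tensor volume.

    Negative eigenvalues are clamped to zero for the metric computation; the
    affected voxels are flagged in the returned dict under ``"clamped"``.
    Returns ``{"fa": ScalarMap, "rd": ScalarMap, "ad": ScalarMap,
    "clamped": bool array}``.
    """
    evals, _ = eigendecompose(tensors.coeffs)
    lam, clamped_flag = _clamped(evals)
    fa = fa_value(lam[..., 0], lam[..., 1], lam[..., 2])
    rd = rd_value(lam[..., 1], lam[..., 2])
    ad = ad_value(lam[..., 0])
    g = tensors.grid
    return {
        "fa": ScalarMap(data=np.asarray(fa), grid=g, name="fa"),
        "rd": ScalarMap(data=np.asarray(rd), grid=g, name="rd"),
        "ad": ScalarMap(data=np.asarray(ad), grid=g, name="ad"),
        "clamped": clamped_flag,
    }


def principal_directions(tensors: TensorVolume) -> np.ndarray:
    """(x, y, z, 3) field of unit principal eigenvectors (tracking input)."""
    _, evecs = eigendecompose(tensors.coeffs)
    return np.ascontiguousarray(evecs[..., :, 0])
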
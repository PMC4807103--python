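"""Spherical-spline interpolation of scalp potentials (Perrin-style).

Bad channels are reconstructed from good ones by fitting a spherical thin-
plate spline on the unit sphere: the kernel is the Legendre series

    g(cos t) = 1/(4*pi) * sum_{n>=1} (2n+1) / (n^m (n+1)^m) * P_n(cos t)

with stiffness order ``m`` (4 by default) and a small smoothing term added to
the diagonal of the good-channel kernel matrix.  The fit solves the bordered
system enforcing the zero-sum side condition, and interpolated values are the
kernel expansion plus the fitted constant.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import legendre

from .montage import Montage

__all__ = ["spline_kernel", "interpolation_matrix", "spherical_spline_interpolate"]


def spline_kernel(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Evaluate the spherical-spline kernel g(cos angle)."""
    n = np.arange(1, n_terms + 1)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n**m * (n + 1.0) ** m)
    return legendre.legval(np.asarray(cosang, dtype=float), coef) / (4.0 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    *,
    m: int = 4,
    n_terms: int = 50,
    smoothing: float = 1e-5,
) -> np.ndarray:
    """Matrix mapping good-channel values to interpolated bad-channel values.

    Positions are projected onto the unit sphere; only their directions
    matter.  Returns an array of shape (n_bad, n_good).
    """
    gu = good_pos / np.linalg.norm(good_pos, axis=1, keepdims=True)
    bu = bad_pos / np.linalg.norm(bad_pos, axis=1, keepdims=True)
    G = spline_kernel(np.clip(gu @ gu.T, -1.0, 1.0), m=m, n_terms=n_terms)
    Gb = spline_kernel(np.clip(bu @ gu.T, -1.0, 1.0), m=m, n_terms=n_terms)
    ng = len(gu)
    # bordered system: [G + sI, 1; 1^T, 0] [c; c0] = [v; 0]
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + smoothing * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    # columns of the solve map each good channel's unit value to (c, c0)
    rhs = np.vstack([np.eye(ng), np.zeros((1, ng))])
    sol = np.linalg.solve(A, rhs)  # (ng+1, ng)
    return Gb @ sol[:ng] + sol[ng]


def spherical_spline_interpolate(
    data: np.ndarray,
    bad_channels,
    montage: Montage,
    *,
    m: int = 4,
    n_terms: int = 50,
    smoothing: float = 1e-5,
    min_good: int = 8,
) -> np.ndarray:
    """Replace bad-channel rows of ``data`` by spherical-spline estimates.

    Parameters
    ----------
    data : ndarray, shape (n_channels, ...) — ERP or epoch array.
    bad_channels : sequence of int or of str
        Channel indices or montage labels to reconstruct.
    montage : Montage
    min_good : int
        Minimum number of remaining good channels.

    Returns
    -------
    ndarray
        A copy of ``data`` with bad rows replaced; good rows are untouched.
    """
    bad_idx = sorted(
        montage.labels.index(b) if isinstance(b, str) else int(b)
        for b in bad_channels
    )
    out = np.array(data, dtype=float, copy=True)
    if not bad_idx:
        return out
    n_ch = montage.n_channels
    if out.shape[0] != n_ch:
        raise ValueError("data first axis must match the montage channel count")
    good_idx = [i for i in range(n_ch) if i not in set(bad_idx)]
    if len(good_idx) < min_good:
        raise ValueError(
            f"only {len(good_idx)} good channels remain; >= {min_good} required"
        )
    W = interpolation_matrix(
        montage.positions[good_idx],
        montage.positions[bad_idx],
        m=m,
        n_terms=n_terms,
        smoothing=smoothing,
    )
    flat = out.reshape(n_ch, -1)
    flat[bad_idx] = W @ flat[good_idx]
    return out
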
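"""Distance distribution functions P(r).

Two routes are provided: a direct pair-distance histogram of a sphere model,
and a regularized indirect transform of a measured curve, minimizing

    chi^2(P) + alpha * || d2 P / dr2 ||^2     subject to  P >= 0,

with P pinned to zero at r = 0 and r = dmax.  The maximum length L is read
off where P(r) falls below a small threshold of its peak, which makes the
"P(r) = 0" rule operational on noisy solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear
from scipy.signal import find_peaks
from scipy.spatial.distance import pdist

from .scattering import ScatteringCurve
from .spheres import SphereModel

ZERO_THRESHOLD = 1e-3     # of max P, for reading off L
PEAK_PROMINENCE = 0.02    # of max P, for M / M1 / M2 calling
SMOOTH_SPAN = 0.7         # nm covered by the moving average (min 3 bins);
                          # wide enough to wipe cube-grid aliasing combs


@dataclass
class DistanceDistribution:
    r: np.ndarray            # bin centers / grid, nm
    p: np.ndarray            # P(r), area-normalized when `normalized`
    dmax: float              # assumed or realized maximum dimension, nm
    length: float            # derived L, nm
    rg: float                # derived from second moment, nm
    peaks: np.ndarray        # peak positions, nm, ascending r
    normalized: bool = True
    truncated: bool = False  # P still large at dmax (dmax too small)


def _call_peaks(r: np.ndarray, p: np.ndarray) -> np.ndarray:
    if len(p) < 3:
        return r[np.argmax(p)][None] if len(p) else np.array([])
    dr = r[1] - r[0]
    nbin = max(3, int(round(SMOOTH_SPAN / dr)) | 1)
    kern = np.ones(nbin) / nbin
    ps = np.convolve(p, kern, mode="same")
    idx, _ = find_peaks(ps, prominence=PEAK_PROMINENCE * ps.max())
    if len(idx) == 0:
        idx = np.array([int(np.argmax(ps))])
    return r[idx]


def _moments(r: np.ndarray, p: np.ndarray) -> float:
    """R_g from P(r): R_g^2 = int r^2 P dr / (2 int P dr)."""
    tot = np.trapezoid(p, r)
    if tot <= 0:
        return np.nan
    return float(np.sqrt(np.trapezoid(r**2 * p, r) / (2.0 * tot)))


def pr_from_model(spheres: SphereModel, bin_width: float = 0.1,
                  normalize: bool = True,
                  smear_sigma: float | None = None) -> DistanceDistribution:
    """P(r) as the histogram of all sphere-pair distances.

    ``smear_sigma`` (default: the common sphere radius) Gaussian-smears the
    center-distance histogram, representing the intra-sphere spread of
    scattering mass; it also suppresses the aliasing comb that the cubic
    sphere grid would otherwise imprint on the histogram.  Pass 0 for the raw
    center-distance histogram.
    """
    if spheres.n_spheres < 2:
        raise ValueError("need at least two spheres")
    if smear_sigma is None:
        smear_sigma = spheres.radius
    d = pdist(spheres.centers)
    pad = 4.0 * smear_sigma
    nbins = int(np.ceil((d.max() + pad) / bin_width)) + 1
    counts, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts.astype(float)
    if smear_sigma > 0:
        from scipy.ndimage import gaussian_filter1d

        p = gaussian_filter1d(p, smear_sigma / bin_width, mode="constant")
    occupied = np.flatnonzero(p > ZERO_THRESHOLD * p.max())
    length = float(edges[occupied[-1] + 1])
    if normalize:
        area = np.trapezoid(p, centers)
        if area > 0:
            p = p / area
    return DistanceDistribution(
        r=centers, p=p, dmax=length, length=length,
        rg=_moments(centers, p), peaks=_call_peaks(centers, p),
        normalized=normalize,
    )


def pr_from_curve(curve: ScatteringCurve, dmax: float, n_points: int = 101,
                  alpha: float = 1e-4) -> DistanceDistribution:
    """Regularized indirect transform of I(Q) to P(r) on [0, dmax].

    The forward model is I(Q) = sum_j P(r_j) sinc(Q r_j) dr over an interior
    grid (endpoints fixed at zero); the smoothness weight ``alpha`` multiplies
    the squared second differences of P.  Errors weight the data rows when
    present.  Raises on a numerically singular system (alpha too small).
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive (ill-conditioned otherwise)")
    q, i = curve.q, curve.i
    r_full = np.linspace(0.0, dmax, n_points)
    r = r_full[1:-1]
    dr = r_full[1] - r_full[0]
    qr = np.outer(q, r)
    A = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0) * dr
    w = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(i)
    scale = np.abs(i * w).max()
    Aw = A * w[:, None] / scale
    yw = i * w / scale
    # second differences over the full grid incl. the pinned endpoints
    m = len(r)
    D = np.zeros((m, m))
    for j in range(m):
        D[j, j] = -2.0
        if j > 0:
            D[j, j - 1] = 1.0
        if j + 1 < m:
            D[j, j + 1] = 1.0
    lam = np.sqrt(alpha) * np.abs(Aw).max()
    M = np.vstack([Aw, lam * D / dr**2 * dr**2])
    b = np.concatenate([yw, np.zeros(m)])
    sol = lsq_linear(M, b, bounds=(0.0, np.inf), max_iter=500)
    if not np.all(np.isfinite(sol.x)):
        raise RuntimeError("indirect transform failed: system ill-conditioned")
    p = np.zeros(n_points)
    p[1:-1] = sol.x
    pmax = p.max()
    truncated = bool(p[-2] > 0.05 * pmax)
    # L: first r past the global maximum where P drops below threshold
    imax = int(np.argmax(p))
    below = np.flatnonzero(p[imax:] < ZERO_THRESHOLD * pmax)
    length = float(r_full[imax + below[0]]) if len(below) else float(dmax)
    area = np.trapezoid(p, r_full)
    if area > 0:
        p_n = p / area
    else:
        p_n = p
    return DistanceDistribution(
        r=r_full, p=p_n, dmax=float(dmax), length=length,
        rg=_moments(r_full, p_n), peaks=_call_peaks(r_full, p_n),
        normalized=True, truncated=truncated,
    )


def chi_square(curve: ScatteringCurve, dist: DistanceDistribution) -> float:
    """Misfit of the forward-simulated P(r) against the curve (free scale)."""
    qr = np.outer(curve.q, dist.r)
    A = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    icalc = np.trapezoid(A * dist.p[None, :], dist.r, axis=1)
    w = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(curve.i)
    num = np.sum(w**2 * curve.i * icalc)
    den = np.sum(w**2 * icalc**2)
    eta = num / den if den > 0 else 0.0
    return float(np.sum((w * (curve.i - eta * icalc)) ** 2))
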
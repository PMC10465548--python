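"""Low-energy tail modeling of the insertion-energy histogram.

At low temperatures the Boltzmann sum is dominated by the sparsely
sampled low-energy tail of H(U), making raw chemical potentials noisy.
The (unnormalised) cumulative distribution C(U) = sum_{U' <= U} H(U') is
empirically exponential, C(U) = A e^{alpha U}, over many orders of
magnitude; equivalently, x = e^{-beta U} follows a power law with an
upper bound b = e^{-beta U_min}.  The correction procedure:

1. fit ln C(U) by local linear (loess-style) regression over a window
   bounded below by a count threshold (10^4 at production scale) and
   above by U = -4 kcal/mol;
2. estimate the lower endpoint U_min, either from the sample-size
   dependence of block minima (U_hat = U_min + E/(1+(M/D)^delta)) or
   from the clash-free-fraction anchor CDF(U_min) = B * f_CF^gamma
   (B = 1, gamma = 0.25, the default rule);
3. replace H(U) below the window by the derivative of the extrapolated
   CDF, truncated at U_min, and redo the Boltzmann sum.

An outlying lowest energy is flagged when it falls more than
1 kcal/mol below the CDF = 1 extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .energy_model import KB
from .widom_mu import EnergyHistogram, MuPoint

__all__ = [
    "CdfModel",
    "UminFit",
    "cdf_from_hist",
    "fit_log_cdf",
    "estimate_umin_blocks",
    "umin_from_fcf",
    "corrected_mu_ex",
    "detect_outlier",
    "block_minima",
]

CDF_BOUNDARY_DEFAULT = 1.0e4
WINDOW_UPPER_DEFAULT = -4.0  # kcal/mol


def cdf_from_hist(hist: EnergyHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative counts C(U) at occupied bin centers, ascending in U."""
    nz = np.nonzero(hist.counts)[0]
    if len(nz) == 0:
        raise ValueError("empty histogram")
    u = (hist.origin + nz) * hist.bin_width
    c = np.cumsum(hist.counts[nz]).astype(float)
    return u, c


def _tricube(t: np.ndarray) -> np.ndarray:
    a = np.clip(np.abs(t), 0.0, 1.0)
    return (1 - a**3) ** 3


def _local_linear(xs: np.ndarray, ys: np.ndarray, x0: float, span: float) -> tuple[float, float]:
    """Tricube-weighted degree-1 fit around x0; returns (value, slope) at x0."""
    n = len(xs)
    q = max(int(math.ceil(span * n)), 3)
    d = np.abs(xs - x0)
    order = np.argsort(d, kind="stable")[:q]
    dmax = d[order].max()
    if dmax == 0:
        dmax = 1.0
    w = _tricube(d[order] / dmax)
    X = xs[order] - x0
    Y = ys[order]
    sw = w.sum()
    swx = (w * X).sum()
    swxx = (w * X * X).sum()
    swy = (w * Y).sum()
    swxy = (w * X * Y).sum()
    det = sw * swxx - swx * swx
    if abs(det) < 1e-300:
        return float(swy / sw), 0.0
    a = (swxx * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    return float(a), float(b)


@dataclass
class CdfModel:
    """Loess-style model of ln C(U) over a fit window, with tail extrapolation.

    Below the window, predictions follow the tangent line at the window's
    lower edge (value and slope continuous); ``alpha`` is that slope.
    """

    xs: np.ndarray  # U values inside the window
    ys: np.ndarray  # ln C(U)
    span: float
    window: tuple[float, float]
    alpha: float = field(init=False)
    _edge_value: float = field(init=False)
    u_min: float | None = None
    endpoint_rule: str = "fcf_rule"

    def __post_init__(self) -> None:
        v, s = _local_linear(self.xs, self.ys, float(self.xs[0]), self.span)
        self._edge_value = v
        self.alpha = s
        if self.alpha <= 0:
            raise ValueError("fitted CDF slope alpha must be positive")

    def predict_log_cdf(self, u) -> np.ndarray:
        """ln C(U); loess inside the window, tangent extrapolation below."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        out = np.empty_like(u)
        lo = float(self.xs[0])
        for i, ui in enumerate(u):
            if ui < lo:
                out[i] = self._edge_value + self.alpha * (ui - lo)
            else:
                out[i] = _local_linear(self.xs, self.ys, ui, self.span)[0]
        return out

    def u_at_log_cdf(self, target_log_c: float) -> float:
        """U where the extrapolated ln C(U) reaches a target (below window)."""
        lo = float(self.xs[0])
        return lo + (target_log_c - self._edge_value) / self.alpha


def fit_log_cdf(
    cdf: tuple[np.ndarray, np.ndarray],
    window: tuple[float, float] | None = None,
    span: float = 0.75,
    cdf_boundary: float = CDF_BOUNDARY_DEFAULT,
    u_upper: float = WINDOW_UPPER_DEFAULT,
    min_points: int = 10,
) -> CdfModel:
    """Fit ln C(U) by tricube local linear regression over the fit window.

    The default window runs from the first U with C >= ``cdf_boundary``
    up to ``u_upper``; pass ``window`` to override both (needed for toy
    histograms much smaller than production scale).
    """
    u, c = cdf
    if window is None:
        above = c >= cdf_boundary
        if not np.any(above):
            raise ValueError("histogram too sparse: CDF never reaches the boundary")
        lo = float(u[np.argmax(above)])
        window = (lo, u_upper)
    sel = (u >= window[0] - 1e-12) & (u <= window[1] + 1e-12)
    if int(sel.sum()) < min_points:
        raise ValueError(
            f"only {int(sel.sum())} CDF points in window {window}; need >= {min_points}"
        )
    return CdfModel(xs=u[sel], ys=np.log(c[sel]), span=span, window=window)


def block_minima(hist: EnergyHistogram, block_sizes: list[int] | None = None) -> dict[int, float]:
    """Mean lowest insertion energy as a function of block size M_ori.

    The per-orientation records are grouped into consecutive blocks of
    M_ori orientations each; each block's minimum energy is found and the
    minima are averaged.  M_ori values must divide the orientation count.
    """
    n_ori = len(hist.per_orientation)
    if block_sizes is None:
        block_sizes = [m for m in range(1, n_ori + 1) if n_ori % m == 0]
    mins = np.empty(n_ori)
    for i, rec in enumerate(hist.per_orientation):
        nz = np.nonzero(rec["counts"])[0]
        mins[i] = (rec["origin"] + nz[0]) * hist.bin_width if len(nz) else np.inf
    out: dict[int, float] = {}
    for m in block_sizes:
        if n_ori % m != 0:
            raise ValueError(f"block size {m} does not divide {n_ori} orientations")
        blocks = mins.reshape(n_ori // m, m).min(axis=1)
        out[m] = float(blocks.mean())
    return out


@dataclass
class UminFit:
    """Joint block-minimum fit: U_hat = U_min + E/(1 + (M_ori/D)^delta).

    D is shared across concentrations; U_min, E and delta (bounded to
    [0.6, 1]) are per concentration.
    """

    u_min: dict  # key -> U_min
    E: dict
    delta: dict
    D: float
    residual_norm: float

    def __post_init__(self) -> None:
        for k, d in self.delta.items():
            if not (0.6 - 1e-9 <= d <= 1.0 + 1e-9):
                raise ValueError(f"delta[{k}]={d} outside [0.6, 1]")


def estimate_umin_blocks(
    data: dict,
    max_nfev: int = 20000,
) -> UminFit:
    """Fit the block-minimum model jointly across concentrations.

    ``data`` maps a key (e.g. concentration) to (M_ori array, U_hat
    array); at least 4 distinct block sizes per key are required.
    Trust-region-reflective least squares with delta in [0.6, 1] and a
    single shared D.
    """
    keys = list(data)
    if not keys:
        raise ValueError("no block-minimum data")
    m_arrs, u_arrs = {}, {}
    for k in keys:
        m, u = data[k]
        m = np.asarray(m, dtype=float)
        u = np.asarray(u, dtype=float)
        if len(np.unique(m)) < 4:
            raise ValueError(f"{k}: need >= 4 distinct block sizes")
        m_arrs[k], u_arrs[k] = m, u

    # parameter vector: [log D, then per key (U_min, E, delta)]
    p0 = [math.log(float(np.median(np.concatenate([m_arrs[k] for k in keys]))))]
    lo, hi = [-10.0], [30.0]
    for k in keys:
        u = u_arrs[k]
        p0 += [float(u.min()), float(max(u.max() - u.min(), 1e-3)), 0.8]
        lo += [-np.inf, 0.0, 0.6]
        hi += [np.inf, np.inf, 1.0]

    def unpack(p):
        D = math.exp(p[0])
        rest = {}
        for i, k in enumerate(keys):
            um, e, dl = p[1 + 3 * i : 4 + 3 * i]
            rest[k] = (um, e, dl)
        return D, rest

    def resid(p):
        D, rest = unpack(p)
        out = []
        for k in keys:
            um, e, dl = rest[k]
            model = um + e / (1.0 + (m_arrs[k] / D) ** dl)
            out.append(model - u_arrs[k])
        return np.concatenate(out)

    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", max_nfev=max_nfev)
    if not sol.success:
        raise RuntimeError(f"block-minimum fit did not converge: {sol.message}; residuals {sol.fun}")
    D, rest = unpack(sol.x)
    return UminFit(
        u_min={k: rest[k][0] for k in keys},
        E={k: rest[k][1] for k in keys},
        delta={k: rest[k][2] for k in keys},
        D=D,
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def umin_from_fcf(f_cf: float, cdf_model: CdfModel, B: float = 1.0, gamma: float = 0.25) -> float:
    """U_min from the clash-free-fraction anchor CDF(U_min) = B * f_CF^gamma."""
    if not (0.0 < f_cf <= 1.0):
        raise ValueError("f_CF must lie in (0, 1]")
    target = math.log(B) + gamma * math.log(f_cf)
    u_min = cdf_model.u_at_log_cdf(target)
    lo = float(cdf_model.xs[0])
    if u_min > lo + 1e-9:
        raise ValueError(
            f"anchor CDF target lies inside the fit window (U_min={u_min:.3f} > {lo:.3f})"
        )
    return u_min


def corrected_mu_ex(
    hist: EnergyHistogram,
    cdf_model: CdfModel,
    u_min: float,
    temperature: float,
) -> MuPoint:
    """beta*mu_ex with the histogram tail replaced by the fitted CDF.

    Below the fit window's lower edge, bin masses come from differencing
    the extrapolated CDF, truncated at ``u_min``; the replaced mass is
    rescaled to match the observed count below the edge, so the total
    stays at M_CF.  Above the edge the original histogram is used.
    """
    lo_edge = float(cdf_model.xs[0])
    if u_min > lo_edge:
        raise ValueError("U_min must lie at or below the fit window's lower edge")
    beta = 1.0 / (KB * temperature)
    dw = hist.bin_width
    centers = hist.bin_centers
    counts = hist.counts.astype(float)
    below = centers < lo_edge
    observed_below = counts[below].sum()

    u_vals: list[float] = []
    w_vals: list[float] = []
    keep = (~below) & (counts > 0)
    u_vals.extend(centers[keep])
    w_vals.extend(counts[keep])

    if observed_below > 0:
        # model bin centers from just below the edge down to u_min
        n_bins = int(math.ceil((lo_edge - u_min) / dw)) + 1
        model_centers = lo_edge - dw * np.arange(1, n_bins + 1)
        model_centers = model_centers[model_centers >= u_min - dw]
        hi_edges = model_centers + dw / 2.0
        lo_edges = np.maximum(model_centers - dw / 2.0, u_min)
        mass = np.exp(cdf_model.predict_log_cdf(hi_edges)) - np.exp(
            cdf_model.predict_log_cdf(lo_edges)
        )
        mass = np.clip(mass, 0.0, None)
        total = mass.sum()
        if total <= 0:
            raise ValueError("extrapolated tail carries no mass")
        mass *= observed_below / total
        sel = mass > 0
        u_vals.extend(model_centers[sel])
        w_vals.extend(mass[sel])

    u_arr = np.asarray(u_vals)
    w_arr = np.asarray(w_vals)
    log_sum = logsumexp(-beta * u_arr, b=w_arr)
    val = -(math.log(hist.f_cf) - math.log(hist.m_cf) + log_sum)
    return MuPoint(
        concentration=math.nan, temperature=temperature, beta_mu_ex=val, corrected=True
    )


def detect_outlier(cdf_model: CdfModel, observed_lowest_u: float, threshold: float = 1.0) -> bool:
    """True if the observed lowest energy sits > threshold below the CDF=1 point."""
    expected = cdf_model.u_at_log_cdf(0.0)
    return observed_lowest_u < expected - threshold
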
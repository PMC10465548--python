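"""Binodal, spinodal and critical temperature from beta*mu_ex(rho).

At each temperature the excess chemical potential over a concentration
series is fit to a fifth-order polynomial through the origin,

    beta*mu_ex = sum_{l=1..5} b_l rho^l ,

whose first coefficient b_1 is twice the second virial coefficient.
Adding the ideal term ln(rho/rho0) gives the full beta*mu(rho); below
the critical temperature this curve carries a van der Waals loop, and a
horizontal line bisecting the loop with equal areas (equal-area
construction) yields the coexisting dilute/dense concentrations
(binodal) while the loop's extrema bound the unstable range (spinodal).
T_c is reported as the midpoint of the bracket between the warmest
loop-bearing and the coolest loop-free temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "MuPolynomial",
    "PhasePoint",
    "NoLoop",
    "PhaseDiagram",
    "VLResult",
    "fit_mu_polynomial",
    "total_mu",
    "equal_area",
    "build_phase_diagram",
    "vliegenthart_lekkerkerker_tc",
]


@dataclass
class MuPolynomial:
    """Fifth-order polynomial fit of beta*mu_ex(rho), no constant term."""

    coefficients: np.ndarray  # b_1 .. b_5
    temperature: float  # degrees C
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != 5:
            raise ValueError("exactly five coefficients b_1..b_5 expected")

    @property
    def b1(self) -> float:
        """First-order coefficient; b1/2 is the second virial coefficient."""
        return float(self.coefficients[0])

    def __call__(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        # sum b_l rho^l with zero constant term, highest power first for polyval
        full = np.concatenate([self.coefficients[::-1], [0.0]])
        return np.polyval(full, rho)

    def antiderivative(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        out = np.zeros_like(rho)
        for l in range(1, 6):
            out = out + self.coefficients[l - 1] * rho ** (l + 1) / (l + 1)
        return out


@dataclass
class PhasePoint:
    """Coexistence and stability bounds at one temperature."""

    temperature: float  # degrees C
    rho_dilute: float
    rho_dense: float
    rho_spin_lo: float
    rho_spin_hi: float
    mu_star: float

    def __post_init__(self) -> None:
        if not (self.rho_dilute < self.rho_spin_lo < self.rho_spin_hi < self.rho_dense):
            raise ValueError(
                "phase point must satisfy rho_dilute < rho_spin_lo < rho_spin_hi < rho_dense"
            )


@dataclass
class NoLoop:
    """Marker result: the chemical potential curve is monotone (supercritical)."""

    temperature: float = math.nan


@dataclass
class PhaseDiagram:
    points: list  # PhasePoint, ordered by temperature
    tc_estimate: float  # degrees C (upper-bound midpoint); nan if undetermined
    tc_bracket: tuple = (math.nan, math.nan)


def fit_mu_polynomial(points, temperature: float) -> MuPolynomial:
    """Least-squares fifth-order fit through the origin.

    ``points`` is a sequence of (rho, beta_mu_ex) pairs; at least six
    concentrations are required to determine the five coefficients with
    a residual degree of freedom.
    """
    pts = [(float(r), float(m)) for r, m in points]
    if len(pts) < 6:
        raise ValueError("need at least 6 concentrations for a fifth-order fit")
    rho = np.array([p[0] for p in pts])
    mu = np.array([p[1] for p in pts])
    X = np.stack([rho**l for l in range(1, 6)], axis=1)
    coef, *_ = np.linalg.lstsq(X, mu, rcond=None)
    resid = mu - X @ coef
    return MuPolynomial(coefficients=coef, temperature=temperature, residuals=resid)


def total_mu(poly: MuPolynomial, rho, rho0: float = 1.0) -> np.ndarray:
    """Full dimensionless chemical potential ln(rho/rho0) + beta*mu_ex(rho)."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    return np.log(rho / rho0) + poly(rho)


def _find_extrema(f, rho_lo: float, rho_hi: float, n_samples: int = 4001):
    """Interior extrema of f on (rho_lo, rho_hi) by sign changes of the slope."""
    xs = np.linspace(rho_lo, rho_hi, n_samples)
    ys = f(xs)
    dy = np.diff(ys)
    sign = np.sign(dy)
    extrema = []
    for i in range(1, len(sign)):
        if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
            # slope changes sign between xs[i-1] and xs[i+1]
            a, b = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
            kind = "max" if sign[i - 1] > 0 else "min"
            # refine by golden-section on +-f
            from scipy.optimize import minimize_scalar

            g = (lambda x: -f(np.array([x]))[0]) if kind == "max" else (
                lambda x: f(np.array([x]))[0]
            )
            res = minimize_scalar(g, bounds=(a, b), method="bounded",
                                  options={"xatol": 1e-12 * (rho_hi - rho_lo)})
            extrema.append((float(res.x), kind))
    return extrema


def equal_area(
    mu_curve,
    rho_lo: float,
    rho_hi: float,
    temperature: float = math.nan,
    antiderivative=None,
    tol: float = 1e-10,
):
    """Equal-area (Maxwell) construction on a chemical-potential curve.

    ``mu_curve`` maps rho (array) to beta*mu.  If the curve has exactly
    one interior maximum followed by one minimum (a van der Waals loop),
    returns the :class:`PhasePoint` whose horizontal line mu* bisects
    the loop with equal areas; otherwise returns :class:`NoLoop`.
    ``antiderivative`` (optional) is an exact integral of mu_curve; by
    default adaptive quadrature is used.
    """
    f = lambda x: np.asarray(mu_curve(np.asarray(x, dtype=float)))
    extrema = _find_extrema(f, rho_lo, rho_hi)
    kinds = [k for _, k in extrema]
    if kinds != ["max", "min"]:
        return NoLoop(temperature=temperature)
    rho_max, rho_min = extrema[0][0], extrema[1][0]
    mu_at_max = float(f(np.array([rho_max]))[0])
    mu_at_min = float(f(np.array([rho_min]))[0])

    def outer_roots(mu_star):
        g = lambda x: float(f(np.array([x]))[0]) - mu_star
        r1 = brentq(g, rho_lo, rho_max, xtol=1e-13, rtol=8.9e-16)
        r3 = brentq(g, rho_min, rho_hi, xtol=1e-13, rtol=8.9e-16)
        return r1, r3

    def area(mu_star):
        r1, r3 = outer_roots(mu_star)
        if antiderivative is not None:
            integral = antiderivative(r3) - antiderivative(r1)
        else:
            integral, _ = quad(lambda x: float(f(np.array([x]))[0]), r1, r3, limit=200)
        return integral - mu_star * (r3 - r1), r1, r3

    lo = max(mu_at_min, float(f(np.array([rho_lo]))[0])) + 1e-12
    hi = min(mu_at_max, float(f(np.array([rho_hi]))[0])) - 1e-12
    if not lo < hi:
        return NoLoop(temperature=temperature)
    mu_star = brentq(lambda m: area(m)[0], lo, hi, xtol=tol, rtol=8.9e-16)
    _, r1, r3 = area(mu_star)
    return PhasePoint(
        temperature=temperature, rho_dilute=r1, rho_dense=r3,
        rho_spin_lo=rho_max, rho_spin_hi=rho_min, mu_star=float(mu_star),
    )


def build_phase_diagram(
    polys: list,
    rho_lo: float,
    rho_hi: float,
    rho0: float = 1.0,
) -> PhaseDiagram:
    """Equal-area construction at every temperature; bracket T_c.

    ``polys`` is a list of :class:`MuPolynomial` (their ``temperature``
    fields order the diagram).  T_c is the midpoint between the warmest
    temperature with a loop and the coolest without one; if every
    temperature has a loop the bracket is open above.
    """
    polys = sorted(polys, key=lambda p: p.temperature)
    points, no_loop_temps, loop_temps = [], [], []
    for poly in polys:
        curve = lambda rho, p=poly: total_mu(p, rho, rho0)
        anti = lambda rho, p=poly: (rho * math.log(rho / rho0) - rho) + float(p.antiderivative(rho))
        res = equal_area(curve, rho_lo, rho_hi, temperature=poly.temperature, antiderivative=anti)
        if isinstance(res, PhasePoint):
            points.append(res)
            loop_temps.append(poly.temperature)
        else:
            no_loop_temps.append(poly.temperature)
    if not loop_temps:
        tc = math.nan
        bracket = (-math.inf, min(no_loop_temps)) if no_loop_temps else (math.nan, math.nan)
        return PhaseDiagram(points=[], tc_estimate=tc, tc_bracket=bracket)
    t_warm = max(loop_temps)
    cooler_no_loop = [t for t in no_loop_temps if t > t_warm]
    if cooler_no_loop:
        t_upper = min(cooler_no_loop)
        tc = 0.5 * (t_warm + t_upper)
        bracket = (t_warm, t_upper)
    else:
        tc = math.nan
        bracket = (t_warm, math.inf)
    return PhaseDiagram(points=points, tc_estimate=tc, tc_bracket=bracket)


@dataclass
class VLResult:
    """Vliegenthart-Lekkerkerker critical-temperature estimate."""

    tc: float  # same units as the input temperature axis; nan when out of range
    status: str  # "crossed", "below_range", "above_range"


def vliegenthart_lekkerkerker_tc(temperatures, b2_over_vst, threshold: float = -6.0) -> VLResult:
    """Temperature where B2(T)/V_st crosses the empirical threshold (-6).

    ``temperatures`` ascending; ``b2_over_vst`` the ratio at each.  B2
    increases with T, so the curve crosses from below; bisection on the
    linear interpolant locates the root.
    """
    t = np.asarray(temperatures, dtype=float)
    r = np.asarray(b2_over_vst, dtype=float)
    if len(t) != len(r) or len(t) < 2:
        raise ValueError("need matching temperature and ratio arrays, length >= 2")
    diff = r - threshold
    if np.all(diff > 0):
        return VLResult(tc=math.nan, status="below_range")
    if np.all(diff < 0):
        return VLResult(tc=math.nan, status="above_range")
    idx = int(np.argmax(diff > 0)) if diff[0] < 0 else int(np.argmax(diff < 0))
    root = brentq(lambda x: float(np.interp(x, t, diff)), t[0], t[-1], xtol=1e-10)
    return VLResult(tc=float(root), status="crossed")
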
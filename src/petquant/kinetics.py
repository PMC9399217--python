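"""Two-tissue compartment (2TC) kinetic modeling with an image-derived
arterial input function.

Model
-----
Tracer exchanges between whole blood ``C_b`` (which, absent arterial
sampling and metabolite correction, also serves as the input ``C_p``), a
free tissue compartment ``C1`` and a bound compartment ``C2``::

    dC1/dt = K1*Cp - (k2 + k3)*C1 + k4*C2
    dC2/dt = k3*C1 - k4*C2
    C_T(t) = (1 - vB)*(C1 + C2) + vB*C_b(t)

The impulse response of ``C1 + C2`` is a sum of two exponentials with
eigen-rates::

    alpha_{1,2} = [(k2 + k3 + k4) -/+ sqrt((k2 + k3 + k4)^2 - 4 k2 k4)] / 2

and the forward solution is the convolution of that response with the
input.  The input is taken piecewise-linear between its samples (zero
before the first), so every convolution integral is evaluated in closed
form per segment — no quadrature error enters the forward model.

Macro-parameters for the reversible model: total distribution volume
``VT = K1/k2 * (1 + k3/k4)`` and binding potential ``BP = k3/k4``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidInputError, UnderDeterminedError
from .tac import TimeActivityCurve

__all__ = [
    "TwoTissueParams",
    "MacroParams",
    "FitResult",
    "forward_2tc",
    "macro_parameters",
    "fit_2tc",
    "load_reference_rate_constants",
]

#: Fitted k4 below this is reported as "< 0.001" (irreversible in practice).
K4_REPORT_THRESHOLD = 1e-3

#: Upper bound (1/min) applied to each rate constant during fitting.
RATE_UPPER_BOUND = 10.0


@dataclass(frozen=True)
class TwoTissueParams:
    """Rate constants of the 2TC model.

    K1 in mL·cm⁻³·min⁻¹; k2, k3, k4 in min⁻¹; vB dimensionless blood
    volume fraction in [0, 1].
    """

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.05

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be a finite non-negative number, got {v}")
        if not 0.0 <= self.vB <= 1.0:
            raise InvalidInputError(f"vB must lie in [0, 1], got {self.vB}")

    @property
    def irreversible(self) -> bool:
        """True when k4 == 0: the bound compartment is a trap."""
        return self.k4 == 0.0

    def rates(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4])


@dataclass(frozen=True)
class MacroParams:
    """Macro-parameters derived from the rate constants.

    vt
        Total distribution volume VT = K1/k2 * (1 + k3/k4), mL/cm³.
        ``inf`` in the irreversible limit (k4 = 0 with k3 > 0).
    bp
        Binding potential BP = k3/k4 (NaN when undefined, i.e. k4 = 0
        with k3 > 0).
    irreversible
        Flag set when k4 = 0 and k3 > 0: the tracer is trapped and the
        reversible macro-parameters do not exist.
    """

    vt: float
    bp: float
    irreversible: bool = False

    @property
    def bp_display(self) -> str:
        """BP formatted the way kinetic tables print it: values below
        0.001 are rendered as '< 0.001'."""
        if self.irreversible or not np.isfinite(self.bp):
            return "n/a (irreversible)"
        if self.bp < K4_REPORT_THRESHOLD:
            return "< 0.001"
        return f"{self.bp:.3f}"


def macro_parameters(params: TwoTissueParams) -> MacroParams:
    """Distribution volume and binding potential from rate constants.

    Raises
    ------
    InvalidInputError
        If k2 == 0 (VT undefined: no tissue-to-blood return path).
    """
    if params.k2 == 0.0:
        raise InvalidInputError(
            "k2 = 0: distribution volume K1/k2*(1 + k3/k4) is undefined "
            "(no efflux from the free compartment)")
    if params.k4 == 0.0:
        if params.k3 == 0.0:
            # no second compartment at all: one-tissue limit
            return MacroParams(vt=params.K1 / params.k2, bp=0.0, irreversible=False)
        return MacroParams(vt=math.inf, bp=math.nan, irreversible=True)
    bp = params.k3 / params.k4
    vt = params.K1 / params.k2 * (1.0 + bp)
    return MacroParams(vt=vt, bp=bp, irreversible=False)


# --------------------------------------------------------------------------
# Exact convolution of exponential kernels with a piecewise-linear input.
# --------------------------------------------------------------------------

def _segment_integrals(alpha: float, h: np.ndarray, c0: np.ndarray, c1: np.ndarray):
    """Closed-form integrals over one linear input segment of length h.

    With the input c(s) = c0 + (c1 - c0) * s/h on s in [0, h], returns

        J0 = ∫_0^h e^{-alpha (h - s)} c(s) ds
        J1 = ∫_0^h (h - s) e^{-alpha (h - s)} c(s) ds

    (J1 is needed only for the confluent repeated-eigenvalue case.)
    Substituting u = h - s turns both into moments of e^{-alpha u}
    against a linear function of u; ``expm1`` keeps the small-alpha*h
    regime accurate.
    """
    b = (c1 - c0) / h          # slope w.r.t. s;  c(h - u) = c1 - b*u
    if alpha == 0.0:
        J0 = 0.5 * (c0 + c1) * h
        J1 = (c0 / 3.0 + c1 / 6.0) * h * h
        return J0, J1
    a = alpha
    x = a * h
    e = np.exp(-x)
    # m_k = ∫_0^h u^k e^{-a u} du, k = 0, 1, 2.  The recurrences cancel
    # catastrophically for small a*h, so switch to 4-term series there
    # (truncation ~ (a h)^4 relative, below double precision at 1e-4).
    with np.errstate(invalid="ignore", divide="ignore"):
        m0_r = -np.expm1(-x) / a
        m1_r = (m0_r - h * e) / a
        m2_r = (2.0 * m1_r - h * h * e) / a
    m0_s = h * (1.0 - x / 2.0 + x * x / 6.0 - x ** 3 / 24.0)
    m1_s = h * h * (0.5 - x / 3.0 + x * x / 8.0 - x ** 3 / 30.0)
    m2_s = h ** 3 * (1.0 / 3.0 - x / 4.0 + x * x / 10.0 - x ** 3 / 36.0)
    small = x < 1e-4
    m0 = np.where(small, m0_s, m0_r)
    m1 = np.where(small, m1_s, m1_r)
    m2 = np.where(small, m2_s, m2_r)
    J0 = c1 * m0 - b * m1
    J1 = c1 * m1 - b * m2
    return J0, J1


def _eigenrates(k2: float, k3: float, k4: float) -> tuple[float, float]:
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    root = math.sqrt(max(disc, 0.0))
    return 0.5 * (s - root), 0.5 * (s + root)


def forward_2tc(params: TwoTissueParams, aif: TimeActivityCurve,
                times: Sequence[float]) -> TimeActivityCurve:
    """Forward-simulate the 2TC tissue curve for a given whole-blood input.

    The input drives the tissue compartments as ``C_p`` and contributes
    the fractional blood signal ``vB * C_b``; both roles use the same
    whole-blood curve (no plasma separation or metabolite correction).

    Parameters
    ----------
    params
        Rate constants and blood volume fraction.
    aif
        Whole-blood input curve; at least two samples.  It is treated as
        piecewise-linear between samples and zero before the first.
    times
        Evaluation times (min), strictly increasing, non-negative.

    Returns
    -------
    TimeActivityCurve
        Tissue concentration at ``times`` in the input's units.
    """
    t_eval = np.asarray(times, dtype=float)
    if t_eval.ndim != 1 or t_eval.size == 0:
        raise InvalidInputError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t_eval) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(t_eval < 0):
        raise InvalidInputError("times must be non-negative")
    if len(aif) < 2:
        raise InvalidInputError("aif must have at least 2 samples to interpolate")

    grid = _ForwardGrid(aif, t_eval)
    values = grid.tissue(params.K1, params.k2, params.k3, params.k4, params.vB)
    return TimeActivityCurve(times=t_eval, values=values,
                             decay_corrected=aif.decay_corrected)


class _ForwardGrid:
    """Precomputed knot grid for repeated forward evaluations (fitting).

    The knot grid is the union of the input samples and the evaluation
    times (from t=0), so every segment of the piecewise-linear input is
    integrated exactly regardless of the rate constants tried.
    """

    def __init__(self, aif: TimeActivityCurve, t_eval: np.ndarray):
        knots = np.union1d(np.union1d(aif.times, t_eval), [0.0])
        # merge near-duplicate knots (e.g. 1.5 vs 1.5+2eps from a float
        # grid) so segment lengths never collapse to rounding noise
        tol = 1e-9 * max(1.0, float(knots[-1]))
        keep = np.concatenate([[True], np.diff(knots) > tol])
        knots = knots[keep]
        self.knots = knots
        self.c_in = aif.interp(knots)
        self.cb_eval = aif.interp(t_eval)
        idx = np.clip(np.searchsorted(knots, t_eval), 0, knots.size - 1)
        left = np.clip(idx - 1, 0, knots.size - 1)
        use_left = np.abs(knots[left] - t_eval) < np.abs(knots[idx] - t_eval)
        self.idx = np.where(use_left, left, idx)
        self.h = np.diff(knots)
        self.c0 = self.c_in[:-1]
        self.c1 = self.c_in[1:]
        # a uniform knot grid admits a constant-coefficient recurrence
        self.uniform = bool(self.h.size > 0
                            and np.allclose(self.h, self.h[0], rtol=1e-9, atol=0.0))

    def _conv(self, alpha: float, confluent: bool = False):
        n = self.knots.size
        I0 = np.zeros(n)
        J0, J1 = _segment_integrals(alpha, self.h, self.c0, self.c1)
        if self.uniform:
            from scipy.signal import lfilter

            d = float(np.exp(-alpha * self.h[0]))
            I0[1:] = lfilter([1.0], [1.0, -d], J0)
            if not confluent:
                return I0
            u = d * self.h[0] * I0[:-1] + J1
            I1 = np.zeros(n)
            I1[1:] = lfilter([1.0], [1.0, -d], u)
            return I0, I1
        decay = np.exp(-alpha * self.h)
        if not confluent:
            for i in range(n - 1):
                I0[i + 1] = decay[i] * I0[i] + J0[i]
            return I0
        I1 = np.zeros(n)
        for i in range(n - 1):
            I1[i + 1] = decay[i] * (I1[i] + self.h[i] * I0[i]) + J1[i]
            I0[i + 1] = decay[i] * I0[i] + J0[i]
        return I0, I1

    def tissue(self, K1: float, k2: float, k3: float, k4: float, vB: float) -> np.ndarray:
        if K1 == 0.0:
            free = np.zeros_like(self.knots)
        else:
            a1, a2 = _eigenrates(k2, k3, k4)
            scale = max(a2, 1.0)
            if (a2 - a1) <= 1e-10 * scale:
                # repeated eigenvalue: confluent limit with impulse
                # response K1 * [1 + (k3 + k4 - a) t] e^{-a t}
                a = 0.5 * (a1 + a2)
                I0, I1 = self._conv(a, confluent=True)
                free = K1 * (I0 + (k3 + k4 - a) * I1)
            else:
                B1 = K1 * (k3 + k4 - a1) / (a2 - a1)
                B2 = K1 * (a2 - (k3 + k4)) / (a2 - a1)
                free = B1 * self._conv(a1) + B2 * self._conv(a2)
        return (1.0 - vB) * free[self.idx] + vB * self.cb_eval


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a 2TC least-squares fit."""

    params: TwoTissueParams
    macro: MacroParams
    rss: float
    stderr: dict[str, float]
    converged: bool
    n_iter: int
    k4_below_threshold: bool = False

    @property
    def k4_display(self) -> str:
        """k4 formatted the way kinetic tables print it."""
        if self.k4_below_threshold:
            return "< 0.001"
        return f"{self.params.k4:.3f}"

    def to_json(self, path: str | Path) -> None:
        doc = {
            "params": asdict(self.params),
            "macro": {"vt": self.macro.vt, "bp": self.macro.bp,
                      "bp_display": self.macro.bp_display,
                      "irreversible": self.macro.irreversible},
            "rss": self.rss,
            "stderr": self.stderr,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "k4_below_threshold": self.k4_below_threshold,
        }
        Path(path).write_text(json.dumps(doc, indent=2, default=float))


# Deterministic multi-start lattice over (K1, k2, k3, k4); spans fast and
# slow kinetics as well as near-irreversible corners.
_START_POINTS = np.array([
    [0.10, 0.10, 0.01, 0.01],
    [0.50, 0.50, 0.10, 0.10],
    [0.10, 1.00, 0.50, 0.50],
    [1.00, 0.10, 0.10, 0.50],
    [0.50, 1.00, 1.00, 0.50],
    [0.05, 0.05, 0.005, 1.00],
    [0.30, 0.30, 0.30, 0.05],
    [1.00, 1.00, 0.10, 0.005],
])


def fit_2tc(tissue: TimeActivityCurve, aif: TimeActivityCurve,
            vb_fixed: float = 0.05,
            weights_mode: Literal["uniform", "frame-duration"] = "uniform") -> FitResult:
    """Fit (K1, k2, k3, k4) by bounded nonlinear least squares.

    vB is held fixed at ``vb_fixed``.  Eight deterministic starting
    points are tried; the solution with the lowest residual sum of
    squares wins (ties broken toward the lower k4).  Standard errors are
    the usual Gauss-Newton approximation from the Jacobian at the
    optimum.

    Parameters
    ----------
    tissue, aif
        Measured tissue curve and whole-blood input on overlapping time
        support.
    vb_fixed
        Fractional blood volume, fixed (typically 0.05).
    weights_mode
        "uniform" (default) or "frame-duration", which weights each
        residual by the square root of its frame duration.
    """
    if not 0.0 <= vb_fixed <= 1.0:
        raise InvalidInputError(f"vb_fixed must lie in [0, 1], got {vb_fixed}")
    n = len(tissue)
    if n < 4:
        raise UnderDeterminedError(
            f"need at least 4 tissue samples to fit 4 rate constants, got {n}")

    if weights_mode == "frame-duration":
        if tissue.frame_durations_s is None:
            raise InvalidInputError("frame-duration weighting requires frame_durations_s")
        w = np.sqrt(tissue.frame_durations_s / tissue.frame_durations_s.mean())
    elif weights_mode == "uniform":
        w = np.ones(n)
    else:
        raise InvalidInputError(f"unknown weights_mode {weights_mode!r}")

    y = tissue.values
    t_eval = tissue.times
    if len(aif) < 2:
        raise InvalidInputError("aif must have at least 2 samples to interpolate")
    grid = _ForwardGrid(aif, t_eval)

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = grid.tissue(*theta, vB=vb_fixed)
        return w * (model - y)

    best = None
    bounds = (np.zeros(4), np.full(4, RATE_UPPER_BOUND))
    for x0 in _START_POINTS:
        try:
            sol = least_squares(residuals, x0, bounds=bounds,
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        if best is None:
            best = sol
        else:
            # prefer lower cost; among near-ties, the lower k4 (more
            # parsimonious: closer to the irreversible special case)
            if sol.cost < best.cost * (1.0 - 1e-9):
                best = sol
            elif abs(sol.cost - best.cost) <= 1e-9 * max(best.cost, 1e-300) \
                    and sol.x[3] < best.x[3]:
                best = sol

    if best is None:
        params = TwoTissueParams(0.0, 0.0, 0.0, 0.0, vB=vb_fixed)
        return FitResult(params=params, macro=MacroParams(vt=0.0, bp=0.0),
                         rss=math.inf, stderr={}, converged=False, n_iter=0)

    theta = best.x
    params = TwoTissueParams(*theta, vB=vb_fixed)
    rss = float(2.0 * best.cost)

    # Gauss-Newton covariance; degenerate Jacobians give NaN errors.
    stderr = {}
    dof = n - 4
    if dof > 0:
        J = best.jac
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cov = rss / dof * np.linalg.pinv(J.T @ J)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                se = np.full(4, np.nan)
        stderr = dict(zip(("K1", "k2", "k3", "k4"), map(float, se)))

    if params.k2 > 0:
        macro = macro_parameters(params)
    else:
        macro = MacroParams(vt=math.nan, bp=math.nan, irreversible=params.k4 == 0.0)

    return FitResult(params=params, macro=macro, rss=rss, stderr=stderr,
                     converged=bool(best.success and np.isfinite(rss)),
                     n_iter=int(best.nfev),
                     k4_below_threshold=params.k4 < K4_REPORT_THRESHOLD)


def load_reference_rate_constants():
    """Bundled published rate-constant table for the two bilateral-hip
    patients (suspected vs contralateral joints).

    Returns a DataFrame with columns subject, region, K1, k2, k3, k4,
    vt, bp; cells printed as "< 0.001" are parsed to NaN with a matching
    ``*_censored`` boolean column.
    """
    import pandas as pd
    from importlib import resources

    path = resources.files("petquant.data").joinpath("joint_rate_constants.csv")
    df = pd.read_csv(path, dtype=str)
    for col in ("K1", "k2", "k3", "k4", "vt", "bp"):
        censored = df[col].str.contains("<", na=False)
        df[col + "_censored"] = censored
        df[col] = pd.to_numeric(df[col].where(~censored), errors="coerce")
    df["subject"] = df["subject"].astype(int)
    return df
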
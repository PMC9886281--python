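"""1:1 Langmuir binding kinetics: sensorgram model and global fitting.

The association phase follows R(t) = Req (1 - exp(-k_obs t)) with
k_obs = kon*C + koff and Req = Rmax*C/(C + KD); the dissociation phase
continues from the association endpoint with rate koff. A single
(kon, koff, Rmax) is fitted jointly across a concentration series in
log-parameter space with multi-start initialisation.

With koff * t_dissoc << 1 the off-rate is weakly identified; the fit
reports a curvature-based confidence interval and a warning instead of
hiding the problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BliTrace",
    "KineticsFit",
    "IdentifiabilityError",
    "model_sensorgram",
    "reference_subtract",
    "global_fit",
]


class IdentifiabilityError(ValueError):
    """Raised when the sensorgram series cannot pin down the global parameters."""


@dataclass(frozen=True)
class BliTrace:
    """One sensorgram: time (s), signal (nm), analyte concentration (M)."""

    time: np.ndarray
    signal: np.ndarray
    concentration: float
    t_assoc: float
    reference_subtracted: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.size != s.size:
            raise ValueError("time and signal lengths differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class KineticsFit:
    kon: float  # M^-1 s^-1
    koff: float  # s^-1
    rmax: float  # nm
    per_trace_rms: tuple
    converged: bool
    ambiguous: bool = False
    koff_ci: tuple = (math.nan, math.nan)
    warnings: tuple = ()

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant, always koff/kon."""
        return self.koff / self.kon


def model_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    concentration: float,
    time: np.ndarray,
    t_assoc: float,
) -> np.ndarray:
    """Closed-form 1:1 sensorgram on an arbitrary time grid.

    ``time`` runs through both phases; samples after ``t_assoc`` follow the
    dissociation exponential from the exact association endpoint.
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise ValueError("kon, koff and rmax must be > 0")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    t = np.asarray(time, dtype=float)
    if concentration == 0.0:
        return np.zeros_like(t)
    kd = koff / kon
    req = rmax * concentration / (concentration + kd)
    kobs = kon * concentration + koff
    assoc = req * (1.0 - np.exp(-kobs * np.clip(t, None, t_assoc)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-koff * (np.clip(t, t_assoc, None) - t_assoc))
    return np.where(t <= t_assoc, assoc, dissoc)


def reference_subtract(
    traces: Sequence[BliTrace], reference: BliTrace
) -> list[BliTrace]:
    """Pointwise subtraction of a zero-concentration reference trace.

    The reference is linearly interpolated onto each trace's grid; time
    points outside the reference range raise.
    """
    out = []
    for tr in traces:
        if tr.time[0] < reference.time[0] - 1e-9 or tr.time[-1] > reference.time[-1] + 1e-9:
            raise ValueError("trace time grid extends beyond the reference trace")
        ref = np.interp(tr.time, reference.time, reference.signal)
        out.append(
            BliTrace(tr.time, tr.signal - ref, tr.concentration, tr.t_assoc, True)
        )
    return out


def _residuals(theta: np.ndarray, traces: Sequence[BliTrace]) -> np.ndarray:
    # clip to keep wild multi-start excursions finite
    kon, koff, rmax = np.exp(np.clip(theta, -60.0, 60.0))
    with np.errstate(over="ignore", invalid="ignore", under="ignore"):
        parts = [
            tr.signal
            - model_sensorgram(kon, koff, rmax, tr.concentration, tr.time, tr.t_assoc)
            for tr in traces
        ]
        out = np.concatenate(parts)
    return np.nan_to_num(out, nan=1e6, posinf=1e6, neginf=-1e6)


def global_fit(
    traces: Sequence[BliTrace],
    kon_starts: Optional[Sequence[float]] = None,
    koff_starts: Optional[Sequence[float]] = None,
) -> KineticsFit:
    """Fit a shared (kon, koff, Rmax) to a sensorgram concentration series.

    Multi-start local least squares over a log-spaced (kon, koff) grid;
    Rmax is initialised from the maximum observed signal. The best optimum
    is returned; the fit is flagged ambiguous if a near-equal optimum
    (cost within 5%) disagrees on KD by more than 2x.
    """
    traces = [tr for tr in traces if tr.concentration > 0]
    concentrations = {tr.concentration for tr in traces}
    if len(concentrations) < 2:
        raise IdentifiabilityError(
            "global fit needs >= 2 traces at distinct non-zero concentrations "
            "(kon and Rmax are not separable from a single concentration)"
        )
    if kon_starts is None:
        kon_starts = np.logspace(4, 7, 4)
    if koff_starts is None:
        koff_starts = np.logspace(-5, -2, 4)
    rmax0 = max(float(np.max(tr.signal)) for tr in traces)
    rmax0 = max(rmax0, 1e-6)

    optima = []
    for kon0 in kon_starts:
        for koff0 in koff_starts:
            theta0 = np.log([kon0, koff0, rmax0])
            try:
                res = least_squares(
                    _residuals, theta0, args=(traces,), method="lm",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
                )
            except Exception:
                continue
            if np.all(np.isfinite(res.x)):
                optima.append(res)
    if not optima:
        return KineticsFit(math.nan, math.nan, math.nan, (), False)

    optima.sort(key=lambda r: r.cost)
    best = optima[0]
    kon, koff, rmax = np.exp(best.x)
    kd = koff / kon
    ambiguous = False
    for other in optima[1:]:
        if other.cost <= 1.05 * best.cost + 1e-30:
            kd_other = math.exp(other.x[1] - other.x[0])
            ratio = kd_other / kd
            if ratio > 2.0 or ratio < 0.5:
                ambiguous = True
                break

    per_trace_rms = []
    for tr in traces:
        r = tr.signal - model_sensorgram(kon, koff, rmax, tr.concentration, tr.time, tr.t_assoc)
        per_trace_rms.append(float(np.sqrt(np.mean(r**2))))

    koff_ci = _koff_interval(best, traces)
    warnings = []
    t_dissoc = max(tr.time[-1] - tr.t_assoc for tr in traces)
    if koff * t_dissoc < 0.1:
        warnings.append(
            "off-rate is near the measurement limit: koff * t_dissoc = "
            f"{koff * t_dissoc:.3g} < 0.1; koff and KD are weakly identified"
        )
    return KineticsFit(
        float(kon), float(koff), float(rmax), tuple(per_trace_rms), True,
        ambiguous, koff_ci, tuple(warnings),
    )


def _koff_interval(res, traces) -> tuple:
    """95% multiplicative CI for koff from the residual curvature at the optimum."""
    n = sum(tr.time.size for tr in traces)
    dof = n - res.x.size
    if dof <= 0:
        return (math.nan, math.nan)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return (0.0, math.inf)
    sd_log = math.sqrt(max(cov[1, 1], 0.0))
    koff = math.exp(res.x[1])
    factor = math.exp(1.96 * sd_log)
    return (koff / factor, koff * factor)
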
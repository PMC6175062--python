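"""Individual-level structural models for RIF, CPI and RSV.

The perpetrator (rifampicin) follows a one-compartment disposition with a
continuous transit-compartment absorption delay.  The endogenous biomarker
CPI follows a turnover model: zero-order synthesis into a single volume,
first-order biliary and renal loss, with the biliary route inhibited
competitively by the perpetrator plasma concentration,

    dC/dt = [ksyn/(1 + rho*x) - CLb*C/(1 + r*x) - CLR*C] / V,   x = C_rif/Ki
    dU/dt = CLR * C,

where r is the I/Ki multiplier of a DDI scenario (r=1: rifampicin itself)
and rho scales a hypothetical inhibition of the synthesis rate (rho=0: the
transporter-only model).  Rosuvastatin follows a two-compartment model with
first-order absorption, with the same competitive inhibition acting on its
biliary clearance.

Everything here is deterministic, single-subject, and solved with an
adaptive stiff-capable integrator (LSODA, rtol 1e-8 / atol 1e-10).  The
vectorized fixed-grid equivalents live in :mod:`copropk.gridsim`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .gridsim import transit_input_rate
from .params import CpiParams, RifParams, RsvParams

_RTOL = 1e-8
_ATOL = 1e-10

DEFAULT_URINE_INTERVALS = ((-7.0, 0.0), (0.0, 7.0), (7.0, 24.0))


@dataclass
class DdiScenario:
    """A hypothetical-inhibitor scenario.

    r    multiplier applied to the perpetrator driving term I/Ki (r=1
         reproduces rifampicin; r=0 switches inhibition off).
    rho  ratio of synthesis-rate inhibition relative to the effect on the
         biliary clearance (rho=0: transporter inhibition only).
    """

    r: float = 1.0
    rho: float = 0.0

    def __post_init__(self):
        if self.r < 0 or self.rho < 0:
            raise ValueError("scenario multipliers must be >= 0")


RIF_SCENARIO = DdiScenario(r=1.0, rho=0.0)


def rif_input_rate(p: RifParams, t):
    """Drug input rate into the absorption depot (umol/h) at time(s) t.

    Analytic transit-compartment input, evaluated in log space; integrates
    to F*dose over [0, inf).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return transit_input_rate(t, None, p.MTT, p.n, p.dose_umol)


def simulate_rif(p: RifParams, times):
    """RIF plasma concentration profile (uM) at the requested times (h).

    Solves depot/central mass balance with the transit input; C(0) = 0.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0) or np.any(times < 0):
        raise ValueError("times must be sorted and >= 0")
    if p.dose_mg == 0:
        return np.zeros_like(times)

    def rhs(t, y):
        aa, ac = y
        inp = float(transit_input_rate(t, None, p.MTT, p.n, p.dose_umol))
        return [inp - p.ka * aa, p.ka * aa - (p.CL / p.V) * ac]

    t_end = max(times[-1], 1e-6)
    sol = solve_ivp(
        rhs, (0.0, t_end), [0.0, 0.0], t_eval=times, method="LSODA",
        rtol=_RTOL, atol=_ATOL, max_step=0.25,
    )
    if not sol.success:  # pragma: no cover - solver failure surface
        raise RuntimeError(f"RIF ODE solver failed ({sol.message}) with params {p!r}")
    return sol.y[1] / p.V


def cpi_baseline(p: CpiParams) -> float:
    """Steady-state baseline CPI plasma concentration ksyn/(CLb+CLR) (nM)."""
    denom = p.CLb + p.CLR
    if denom <= 0:  # unreachable through CpiParams invariants, kept for raw use
        raise ZeroDivisionError("CLb + CLR must be > 0")
    return p.ksyn / denom


def cpi_rhs(state, p: CpiParams, c_rif: float, scenario: DdiScenario = RIF_SCENARIO,
            rif_present: bool = True):
    """Time derivatives (dC/dt nM/h, dU/dt nmol/h) of the CPI turnover model.

    ``c_rif`` is the perpetrator plasma concentration in uM (>= 0); with
    c_rif = 0 and r arbitrary this reduces exactly to the baseline model.
    """
    if c_rif < 0:
        raise ValueError("c_rif must be >= 0")
    c, _u = state
    x = scenario.r * c_rif / p.Ki
    v = p.V_rif if rif_present else p.V
    dc = (p.ksyn / (1.0 + scenario.rho * (c_rif / p.Ki)) - p.CLb * c / (1.0 + x) - p.CLR * c) / v
    return dc, p.CLR * c


def simulate_cpi(
    p: CpiParams,
    rif_profile=None,
    scenario: DdiScenario = RIF_SCENARIO,
    times=None,
    urine_intervals=DEFAULT_URINE_INTERVALS,
    use_rif_volume: bool = True,
):
    """CPI plasma profile (nM) and per-interval urine amounts (nmol).

    rif_profile : callable t -> perpetrator concentration (uM), or None for
    baseline.  The initial condition is the individual steady state at the
    start of the first urine interval; the urine compartment resets at each
    interval start.  Interval boundaries are integrated as explicit segment
    ends so the solver cannot step across them.
    """
    if times is None:
        times = np.linspace(urine_intervals[0][0], urine_intervals[-1][1], 200)
    times = np.asarray(times, dtype=float)
    t0 = min(float(times[0]), urine_intervals[0][0])
    t_end = max(float(times[-1]), urine_intervals[-1][1])
    rif_present = rif_profile is not None
    v = p.V_rif if (rif_present and use_rif_volume) else p.V
    css = cpi_baseline(p)

    def rhs(t, y):
        c, _u = y
        c_rif = float(rif_profile(t)) if rif_present else 0.0
        c_rif = max(c_rif, 0.0)
        x = scenario.r * c_rif / p.Ki
        dc = (p.ksyn / (1.0 + scenario.rho * (c_rif / p.Ki))
              - p.CLb * c / (1.0 + x) - p.CLR * c) / v
        return [dc, p.CLR * c]

    breaks = sorted({t0, t_end, *(b for iv in urine_intervals for b in iv)})
    breaks = [b for b in breaks if t0 <= b <= t_end]
    conc = np.full_like(times, np.nan)
    urine = {}
    y = [css, 0.0]
    cum_at = {t0: 0.0}
    for a, b in zip(breaks[:-1], breaks[1:]):
        mask = (times >= a - 1e-12) & (times <= b + 1e-12)
        t_eval = np.unique(np.concatenate([times[mask], [a, b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, method="LSODA",
                        rtol=_RTOL, atol=_ATOL, max_step=0.25)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"CPI ODE solver failed ({sol.message}) with params {p!r}")
        conc[mask] = np.interp(times[mask], sol.t, sol.y[0])
        y = [sol.y[0, -1], sol.y[1, -1]]
        cum_at[b] = y[1]
    for a, b in urine_intervals:
        if a in cum_at and b in cum_at:
            urine[(a, b)] = cum_at[b] - cum_at[a]
    return conc, urine


def rsv_rhs(state, p: RsvParams, c_rif: float, rif_present: bool = False):
    """Derivatives of the RSV depot/central/peripheral/urine system (nmol/h)."""
    depot, a1, a2, _u = state
    v1 = p.V1_rif if rif_present else p.V1
    v2 = p.V2_rif if rif_present else p.V2
    q = p.Q_rif if rif_present else p.Q
    c1 = a1 / v1
    x = max(c_rif, 0.0) / p.Ki
    el = (p.CLb / (1.0 + x) + p.CLR) * c1
    tr = q * c1 - q * (a2 / v2)
    return (-p.ka * depot, p.ka * depot - el - tr, tr, p.CLR * c1)


def simulate_rsv(
    p: RsvParams,
    rif_profile=None,
    times=None,
    urine_intervals=((0.0, 7.0), (7.0, 24.0)),
    rif_present=None,
):
    """RSV plasma profile (uM) and per-interval urine amounts (nmol).

    Dose enters the depot at t=0; ``rif_present`` defaults to whether a
    perpetrator profile was supplied and switches the distribution
    parameters to their RIF-condition values.
    """
    if times is None:
        times = np.linspace(0.0, 24.0, 200)
    times = np.asarray(times, dtype=float)
    if rif_present is None:
        rif_present = rif_profile is not None

    def rhs(t, y):
        c_rif = float(rif_profile(t)) if rif_profile is not None else 0.0
        return rsv_rhs(y, p, c_rif, rif_present=rif_present)

    t0 = min(0.0, float(times[0]))
    t_end = max(float(times[-1]), urine_intervals[-1][1])
    breaks = sorted({t0, t_end, *(b for iv in urine_intervals for b in iv)})
    y = [p.dose_nmol, 0.0, 0.0, 0.0]
    conc = np.full_like(times, np.nan)
    cum_at = {t0: 0.0}
    for a, b in zip(breaks[:-1], breaks[1:]):
        mask = (times >= a - 1e-12) & (times <= b + 1e-12)
        t_eval = np.unique(np.concatenate([times[mask], [a, b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=t_eval, method="LSODA",
                        rtol=_RTOL, atol=_ATOL, max_step=0.25)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"RSV ODE solver failed ({sol.message}) with params {p!r}")
        conc[mask] = np.interp(times[mask], sol.t, sol.y[1]) / (p.V1_rif if rif_present else p.V1)
        y = [sol.y[0, -1], sol.y[1, -1], sol.y[2, -1], sol.y[3, -1]]
        cum_at[b] = y[3]
    urine = {}
    for a, b in urine_intervals:
        if a in cum_at and b in cum_at:
            urine[(a, b)] = cum_at[b] - cum_at[a]
    return conc / 1000.0, urine


def clearance_fraction(CLb: float, CLR: float) -> float:
    """Fraction of total clearance that is biliary, CLb/(CLb+CLR)."""
    if CLb < 0 or CLR < 0 or CLb + CLR == 0:
        raise ValueError("clearances must be >= 0 and not both zero")
    return CLb / (CLb + CLR)


def unbound_ki(ki_total: float, fu: float) -> float:
    """Unbound inhibition constant ki_total * fu (uM)."""
    if not 0 < fu <= 1:
        raise ValueError("fu must lie in (0, 1]")
    return ki_total * fu
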
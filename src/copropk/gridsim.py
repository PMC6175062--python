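"""Fixed-grid propagators for population-scale simulation.

These solve the same structural models as :mod:`copropk.structural` but on a
uniform time grid, vectorized across an arbitrary leading batch of parameter
sets (subjects, subjects x occasions, replicate trials ...).  The linear
one-state models (RIF depot/central, CPI turnover) use an exponential
integrator that is exact for source terms linear within a step and
unconditionally stable; the RSV two-compartment system uses classical RK4
with automatic sub-stepping when the central compartment becomes fast (small
V1 under perpetrator co-administration).

The adaptive ODE route in :mod:`copropk.structural` is the reference
implementation; the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

DEFAULT_DT = 0.02
"""Default grid step (h) for population simulation."""


def transit_input_rate(t, ka_unused, mtt, n, dose):
    """Transit-compartment drug input rate (amount/h), log-space evaluation.

    rate(t) = dose * ktr * (ktr t)^n * exp(-ktr t) / Gamma(n+1), ktr=(n+1)/MTT.
    Broadcasts ``t`` against parameter arrays.  rate(0) = 0 for n > 0.
    """
    t = np.asarray(t, dtype=float)
    mtt, n, dose = (np.asarray(a, dtype=float) for a in (mtt, n, dose))
    ktr = (n + 1.0) / mtt
    tt = np.maximum(t, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.where(tt > 0, np.log(np.where(tt > 0, tt, 1.0)), -np.inf)
        lograte = (
            np.log(dose) + (n + 1.0) * np.log(ktr) + n * logt - ktr * tt - gammaln(n + 1.0)
        )
    rate = np.where(tt > 0, np.exp(lograte), 0.0)
    return np.where(dose > 0, rate, 0.0)


def _phi_weights(z):
    """Step weights for the exponential integrator.

    For y' = -k y + f with f linear on a step of length dt and z = k dt:
    y1 = y0 e^-z + dt*(f0*(phi1-phi2) + f1*phi2), phi1=(1-e^-z)/z,
    phi2=(z-1+e^-z)/z^2.  Series used for small z.
    """
    z = np.asarray(z, dtype=float)
    ez = np.exp(-z)
    small = z < 1e-5
    zs = np.where(small, 1.0, z)
    phi1 = np.where(small, 1.0 - z / 2.0 + z * z / 6.0, -np.expm1(-zs) / zs)
    phi2 = np.where(small, 0.5 - z / 3.0 + z * z / 8.0, (zs + np.expm1(-zs)) / (zs * zs))
    return ez, phi1, phi2


def expint_scan(k, f, dt, y0=0.0):
    """Integrate y' = -k(t) y + f(t) on a uniform grid.

    k, f : arrays broadcastable to (..., nt); per-step k is the midpoint
    average of the endpoint values.  y0 broadcasts over the batch.  Returns
    y with the broadcast shape.
    """
    k = np.asarray(k, dtype=float)
    f = np.asarray(f, dtype=float)
    shape = np.broadcast_shapes(k.shape, f.shape)
    k = np.broadcast_to(k, shape)
    f = np.broadcast_to(f, shape)
    nt = shape[-1]
    km = 0.5 * (k[..., :-1] + k[..., 1:])
    ez, phi1, phi2 = _phi_weights(km * dt)
    w0 = dt * (phi1 - phi2)
    w1 = dt * phi2
    y = np.empty(shape)
    y[..., 0] = y0
    cur = np.array(y[..., 0])
    for i in range(nt - 1):
        cur = cur * ez[..., i] + f[..., i] * w0[..., i] + f[..., i + 1] * w1[..., i]
        y[..., i + 1] = cur
    return y


def rif_profile(p, t, dose_time=0.0):
    """RIF plasma concentration (uM) on grid ``t`` for a parameter batch.

    p : mapping with arrays ``ka, CL, V, MTT, n, dose_umol`` of shape (m,).
    t : uniform grid (nt,), may start before ``dose_time`` (zeros there).
    Returns (m, nt).
    """
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    ka = np.asarray(p["ka"], dtype=float)[:, None]
    rel = t[None, :] - dose_time
    inp = transit_input_rate(
        rel,
        None,
        np.asarray(p["MTT"], dtype=float)[:, None],
        np.asarray(p["n"], dtype=float)[:, None],
        np.asarray(p["dose_umol"], dtype=float)[:, None],
    )
    depot = expint_scan(ka, inp, dt)
    V = np.asarray(p["V"], dtype=float)[:, None]
    kel = np.asarray(p["CL"], dtype=float)[:, None] / V
    central = expint_scan(kel, ka * depot, dt)
    return central / V


def cpi_profile(p, c_rif, t, r=1.0, rho=0.0, rif_present=True, use_rif_volume=True):
    """CPI plasma concentration (nM) and cumulative renal excretion (nmol).

    p : mapping with arrays ``ksyn, CLb, CLR, V, V_rif, Ki`` of shape (m,).
    c_rif : perpetrator concentration (m, nt) in uM, or None for baseline.
    r, rho : I/Ki multiplier and synthesis-inhibition ratio of the scenario.
    The initial condition is the individual steady state ksyn/(CLb+CLR).
    Returns (conc (m, nt), cum_urine (m, nt)).
    """
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    ksyn = np.asarray(p["ksyn"], dtype=float)[:, None]
    CLb = np.asarray(p["CLb"], dtype=float)[:, None]
    CLR = np.asarray(p["CLR"], dtype=float)[:, None]
    if rif_present and use_rif_volume:
        V = np.asarray(p["V_rif"], dtype=float)[:, None]
    else:
        V = np.asarray(p["V"], dtype=float)[:, None]
    if c_rif is None or not rif_present:
        x = np.zeros((1, t.size))
    else:
        x = r * np.asarray(c_rif, dtype=float) / np.asarray(p["Ki"], dtype=float)[:, None]
    k = (CLb / (1.0 + x) + CLR) / V
    f = ((ksyn / (1.0 + rho * x)) / V) * np.ones((1, t.size))
    css = (ksyn / (CLb + CLR))[:, 0]
    conc = expint_scan(k, f, dt, y0=css)
    rate = CLR * conc
    cum = np.concatenate(
        [np.zeros_like(conc[..., :1]), np.cumsum(0.5 * (rate[..., :-1] + rate[..., 1:]) * dt, axis=-1)],
        axis=-1,
    )
    return conc, cum


def rsv_profile(p, c_rif, t, dose_time=0.0, rif_present=False, max_rate_dt=0.5):
    """RSV central concentration (uM) and cumulative urine (nmol) on grid t.

    Three-state system (depot, central, peripheral) integrated with RK4 and
    automatic sub-stepping so that max(rate)*substep stays below
    ``max_rate_dt``.  p : mapping with arrays ``ka, CLb, CLR, V1, V2, Q,
    V1_rif, V2_rif, Q_rif, Ki, dose_nmol`` of shape (m,).  Concentrations are
    nmol/L = nM; returned central concentration converted to uM.
    """
    t = np.asarray(t, dtype=float)
    dt = t[1] - t[0]
    nt = t.size
    ka = np.asarray(p["ka"], dtype=float)
    CLb = np.asarray(p["CLb"], dtype=float)
    CLR = np.asarray(p["CLR"], dtype=float)
    Ki = np.asarray(p["Ki"], dtype=float)
    if rif_present:
        V1 = np.asarray(p["V1_rif"], dtype=float)
        V2 = np.asarray(p["V2_rif"], dtype=float)
        Q = np.asarray(p["Q_rif"], dtype=float)
    else:
        V1 = np.asarray(p["V1"], dtype=float)
        V2 = np.asarray(p["V2"], dtype=float)
        Q = np.asarray(p["Q"], dtype=float)
    dose = np.asarray(p["dose_nmol"], dtype=float)
    m = ka.shape[0]
    if c_rif is None:
        c_rif = np.zeros((m, nt))

    max_rate = np.max((CLb + CLR) / V1 + Q / V1 + ka)
    nsub = max(1, int(np.ceil(max_rate * dt / max_rate_dt)))
    h = dt / nsub

    def deriv(depot, a1, a2, x):
        # x: inhibitor driving term c_rif/Ki at the sub-step time
        c1 = a1 / V1
        el = (CLb / (1.0 + x) + CLR) * c1
        tr = Q * c1 - Q * (a2 / V2)
        return (-ka * depot, ka * depot - el - tr, tr, CLR * c1)

    depot = np.zeros(m)
    a1 = np.zeros(m)
    a2 = np.zeros(m)
    ur = np.zeros(m)
    conc = np.zeros((m, nt))
    cum = np.zeros((m, nt))
    # linear interpolation of the inhibitor term within each grid step
    dosed = False
    for i in range(nt - 1):
        if not dosed and t[i] >= dose_time - 1e-12:
            depot = depot + dose
            dosed = True
        x0 = c_rif[:, i] / Ki
        x1 = c_rif[:, i + 1] / Ki
        for s in range(nsub):
            fa = s / nsub
            fm = (s + 0.5) / nsub
            fb = (s + 1.0) / nsub
            xa = x0 + (x1 - x0) * fa
            xm = x0 + (x1 - x0) * fm
            xb = x0 + (x1 - x0) * fb
            k1 = deriv(depot, a1, a2, xa)
            k2 = deriv(depot + 0.5 * h * k1[0], a1 + 0.5 * h * k1[1], a2 + 0.5 * h * k1[2], xm)
            k3 = deriv(depot + 0.5 * h * k2[0], a1 + 0.5 * h * k2[1], a2 + 0.5 * h * k2[2], xm)
            k4 = deriv(depot + h * k3[0], a1 + h * k3[1], a2 + h * k3[2], xb)
            depot = depot + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            a1 = a1 + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            a2 = a2 + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            ur = ur + h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        conc[:, i + 1] = a1 / V1
        cum[:, i + 1] = ur
    return conc / 1000.0, cum


def interval_amounts(t, cum, intervals):
    """Per-interval amounts from a cumulative-excretion grid.

    Returns an array (..., n_intervals); interval bounds must lie on or
    within the grid (nearest grid point is used, grid steps are fine).
    """
    t = np.asarray(t, dtype=float)
    out = []
    for a, b in intervals:
        ia = int(np.argmin(np.abs(t - a)))
        ib = int(np.argmin(np.abs(t - b)))
        out.append(cum[..., ib] - cum[..., ia])
    return np.stack(out, axis=-1)
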
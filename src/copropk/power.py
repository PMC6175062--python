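"""Forward DDI simulation and simulation-based power calculation.

Hypothetical OATP1B inhibitors are expressed relative to the rifampicin
reference through the I/Ki multiplier r of a :class:`DdiScenario`: the
inhibitor driving term in the biomarker ODE becomes r * C_RIF(t)/Ki.  Each
virtual subject is a two-period one-way crossover: a baseline period (the
biomarker at its individual steady state) and, after washout, a single
600 mg oral dose of the perpetrator.  Subject-level random effects (eta) are
shared between periods, occasion effects (kappa) are drawn per period, and
the perpetrator PK of each subject drives that subject's inhibition.

AUCs (0-24 h, linear trapezoid) are computed from the noise-free model
concentrations on the clinical sampling schedule; a switch adds residual
error to the sampled concentrations first.  The perpetrator-condition
volume shift is retained for hypothetical inhibitors (the shifted volume is
treated as a property of the inhibited condition; a switch removes it).
Power for a given sample size is the fraction of replicate trials in which
a two-sided one-sample t-test on the subjects' log AUC ratios rejects the
null of no exposure change.

The default planning grid of sample sizes is {10, 15, 20, 25, 30}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import gridsim
from .population import PopulationModel, draw_random_effects
from .structural import DdiScenario
from .trial import _CPI12

DEFAULT_R_GRID = (0.025, 0.05, 0.1, 0.25, 1.0, 2.0, 5.0, 10.0, 20.0)
DEFAULT_N_GRID = (10, 15, 20, 25, 30)
SIM_DT = 0.05
"""Grid step (h) of the DDI simulations."""

_RIF_NAMES = ("ka", "CL", "V", "MTT", "n")
_CPI_NAMES = ("ksyn", "CLb", "CLR", "V", "V_rif", "Ki")


@dataclass
class PowerResult:
    scenario: DdiScenario
    alpha: float
    n_grid: tuple
    power: dict                  # n -> rejection fraction
    n_reps: int
    minimal_n: int | None        # smallest n on the grid with power >= target
    target_power: float = 0.8

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": list(self.power), "power": list(self.power.values())})


def _draw_occasion_params(pop, names, etas, kappas, occ, n):
    out = {}
    for name in names:
        e = etas.get(name, 0.0)
        k = kappas[name][:, occ] if name in kappas else 0.0
        out[name] = getattr(pop.fixed, name) * np.exp(np.asarray(e) + np.asarray(k))
        out[name] = np.broadcast_to(out[name], (n,))
    return out


def simulate_crossover_aucs(
    scenario: DdiScenario,
    rif_pop: PopulationModel,
    cpi_pop: PopulationModel,
    n_subjects: int,
    rng,
    sampling_times=None,
    include_residual: bool = False,
    use_rif_volume: bool = True,
    dt: float = SIM_DT,
    window=(0.0, 24.0),
):
    """Per-subject control/inhibited CPI AUCs for one crossover batch.

    Returns (auc_control, auc_inhibited) arrays of length n_subjects.
    """
    n = n_subjects
    times = np.asarray(sampling_times if sampling_times is not None else _CPI12, float)
    t = np.arange(0.0, 24.0 + dt / 2, dt)
    cpi_eta, cpi_kap = draw_random_effects(cpi_pop, n, 2, rng)
    rif_eta, rif_kap = draw_random_effects(rif_pop, n, 1, rng)

    # control period: endogenous steady state of that occasion
    p0 = _draw_occasion_params(cpi_pop, _CPI_NAMES, cpi_eta, cpi_kap, 0, n)
    css0 = p0["ksyn"] / (p0["CLb"] + p0["CLR"])
    conc_ctl = np.broadcast_to(css0[:, None], (n, times.size)).copy()

    # treatment period: perpetrator PK drives the inhibition
    rp = _draw_occasion_params(rif_pop, _RIF_NAMES, rif_eta, rif_kap, 0, n)
    rp["dose_umol"] = np.full(n, rif_pop.fixed.dose_umol)
    c_rif = gridsim.rif_profile(rp, t)
    p1 = _draw_occasion_params(cpi_pop, _CPI_NAMES, cpi_eta, cpi_kap, 1, n)
    conc_trt_grid, _ = gridsim.cpi_profile(
        p1, c_rif, t, r=scenario.r, rho=scenario.rho,
        rif_present=scenario.r > 0 or scenario.rho > 0,
        use_rif_volume=use_rif_volume)
    idx = np.clip(np.searchsorted(t, times), 1, t.size - 1)
    w = (times - t[idx - 1]) / (t[idx] - t[idx - 1])
    conc_trt = conc_trt_grid[:, idx - 1] * (1 - w) + conc_trt_grid[:, idx] * w

    if include_residual:
        sp, sa = cpi_pop.err.streams["cpi_plasma"]
        conc_ctl = conc_ctl * (1 + rng.normal(0, sp, conc_ctl.shape)) \
            + rng.normal(0, sa, conc_ctl.shape)
        conc_trt = conc_trt * (1 + rng.normal(0, sp, conc_trt.shape)) \
            + rng.normal(0, sa, conc_trt.shape)

    sel = (times >= window[0]) & (times <= window[1])
    auc_ctl = np.trapezoid(conc_ctl[:, sel], times[sel], axis=1)
    auc_trt = np.trapezoid(conc_trt[:, sel], times[sel], axis=1)
    return auc_ctl, auc_trt


def simulate_ddi_population(
    scenario: DdiScenario,
    rif_pop: PopulationModel,
    cpi_pop: PopulationModel,
    n_subjects: int = 1000,
    seed: int = 0,
    include_residual: bool = False,
    use_rif_volume: bool = True,
    dt: float = SIM_DT,
    chunk: int = 10000,
    return_profiles: bool = False,
):
    """Population DDI simulation: per-subject AUCs, AUCR and summaries.

    Returns a dict with the per-subject table, arithmetic-mean and median
    AUCR, and (optionally) the median concentration profiles on the
    simulation grid.
    """
    rng = np.random.default_rng(seed)
    aucs_c, aucs_t = [], []
    profiles = []
    t = np.arange(0.0, 24.0 + dt / 2, dt)
    for start in range(0, n_subjects, chunk):
        m = min(chunk, n_subjects - start)
        if return_profiles:
            # recompute with profile capture for the median plot
            state = rng.bit_generator.state
            a_c, a_t = simulate_crossover_aucs(
                scenario, rif_pop, cpi_pop, m, rng,
                include_residual=include_residual, use_rif_volume=use_rif_volume, dt=dt)
            rng.bit_generator.state = state
            profiles.append(_median_profile(scenario, rif_pop, cpi_pop, m, rng,
                                            use_rif_volume, dt))
        else:
            a_c, a_t = simulate_crossover_aucs(
                scenario, rif_pop, cpi_pop, m, rng,
                include_residual=include_residual, use_rif_volume=use_rif_volume, dt=dt)
        aucs_c.append(a_c)
        aucs_t.append(a_t)
    auc_c = np.concatenate(aucs_c)
    auc_t = np.concatenate(aucs_t)
    aucr = auc_t / auc_c
    out = {
        "table": pd.DataFrame({"auc_control": auc_c, "auc_inhibited": auc_t, "aucr": aucr}),
        "mean_aucr": float(aucr.mean()),
        "median_aucr": float(np.median(aucr)),
        "n_subjects": int(auc_c.size),
        "scenario": scenario,
    }
    if return_profiles:
        out["t"] = t
        out["median_profile"] = np.median(np.vstack(profiles), axis=0)
    return out


def _median_profile(scenario, rif_pop, cpi_pop, n, rng, use_rif_volume, dt):
    t = np.arange(0.0, 24.0 + dt / 2, dt)
    cpi_eta, cpi_kap = draw_random_effects(cpi_pop, n, 2, rng)
    rif_eta, rif_kap = draw_random_effects(rif_pop, n, 1, rng)
    rp = _draw_occasion_params(rif_pop, _RIF_NAMES, rif_eta, rif_kap, 0, n)
    rp["dose_umol"] = np.full(n, rif_pop.fixed.dose_umol)
    c_rif = gridsim.rif_profile(rp, t)
    p1 = _draw_occasion_params(cpi_pop, _CPI_NAMES, cpi_eta, cpi_kap, 1, n)
    conc, _ = gridsim.cpi_profile(p1, c_rif, t, r=scenario.r, rho=scenario.rho,
                                  rif_present=True, use_rif_volume=use_rif_volume)
    return conc


def ksyn_scenario_profiles(rhos=(0.0, 0.1, 10.0), rif_pop=None, cpi_pop=None,
                           n_subjects=500, seed=0, r=1.0, dt=SIM_DT):
    """Median CPI profiles for hypothetical synthesis-inhibition ratios.

    rho scales inhibition of the synthesis rate relative to the effect on
    the biliary clearance; rho=0 is the transporter-only scenario.  Each rho
    is simulated from the same seed, so rho=0 reproduces the transporter-only
    simulation exactly.
    """
    out = {}
    t = np.arange(0.0, 24.0 + dt / 2, dt)
    for rho in rhos:
        rng = np.random.default_rng(seed)
        conc = _median_profile(DdiScenario(r=r, rho=rho), rif_pop, cpi_pop,
                               n_subjects, rng, True, dt)
        out[rho] = np.median(conc, axis=0)
    return {"t": t, "profiles": out}


def power_curve(
    scenario: DdiScenario,
    rif_pop: PopulationModel,
    cpi_pop: PopulationModel,
    alpha: float = 0.01,
    n_grid=DEFAULT_N_GRID,
    n_reps: int = 5000,
    seed: int = 0,
    target_power: float = 0.8,
    include_residual: bool = False,
    use_rif_volume: bool = True,
    dt: float = SIM_DT,
    chunk: int = 10000,
) -> PowerResult:
    """Simulated power of the crossover biomarker study per sample size.

    A pool of n_reps * max(n_grid) virtual crossover subjects is simulated;
    replicate trials of size n reuse the first n subjects of each replicate
    row.  Power at n = fraction of replicates with two-sided one-sample
    t-test p < alpha on log(AUCR).
    """
    if alpha <= 0 or alpha >= 1:
        raise ValueError("alpha must lie in (0, 1)")
    n_grid = tuple(sorted(int(n) for n in n_grid))
    if n_grid[0] < 2:
        raise ValueError("t-test needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    total = n_reps * n_grid[-1]
    la = np.empty(total)
    for start in range(0, total, chunk):
        m = min(chunk, total - start)
        a_c, a_t = simulate_crossover_aucs(
            scenario, rif_pop, cpi_pop, m, rng,
            include_residual=include_residual, use_rif_volume=use_rif_volume, dt=dt)
        la[start:start + m] = np.log(a_t / a_c)
    la = la.reshape(n_reps, n_grid[-1])
    power = {}
    minimal = None
    for n in n_grid:
        x = la[:, :n]
        sd = x.std(axis=1, ddof=1)
        sd = np.where(sd > 0, sd, np.inf)
        tstat = x.mean(axis=1) / (sd / np.sqrt(n))
        pvals = 2.0 * stats.t.sf(np.abs(tstat), n - 1)
        power[n] = float((pvals < alpha).mean())
        if minimal is None and power[n] >= target_power:
            minimal = n
    return PowerResult(scenario=scenario, alpha=alpha, n_grid=n_grid, power=power,
                       n_reps=n_reps, minimal_n=minimal, target_power=target_power)
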
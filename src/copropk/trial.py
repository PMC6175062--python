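"""Synthetic crossover-trial generator.

Emulates the clinical design behind the reference parameter table: 12
healthy subjects, three occasions separated by 7-day washouts (OCC1: 600 mg
oral RIF alone; OCC2: 5 mg oral RSV alone; OCC3: both), rich plasma sampling
over 24 h and CPI/RSV urine collection over (-7,0), (0,7) and (7,24) h.
Time is occasion-local with the dose at t=0, so pre-dose samples carry
non-positive times.  Occasions are simulated independently except that the
subject-level random effects (eta) are shared; occasion effects (kappa) are
drawn fresh per occasion.

The exact clock times of the clinical schedule are not published; the
schedules below are a rich 12-point grid chosen to reproduce the published
per-occasion record counts (RIF 144+132, CPI 144+144+132, RSV 132+132),
including a pre-dose CPI sample each occasion so that baseline statistics
can be formed.  The published urine-record counts imply a handful of missing
samples; the generator produces complete interval data by default with an
optional missingness mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gridsim
from .population import PopulationModel, draw_random_effects

#: observation/dose stream -> NONMEM-style compartment code
CMT_CODES = {
    "rif_dose": 1,
    "rif_plasma": 2,
    "cpi_plasma": 3,
    "cpi_urine": 4,
    "rsv_dose": 5,
    "rsv_plasma": 6,
    "rsv_urine": 7,
}

STREAM_UNITS = {
    "rif_plasma": "uM",
    "cpi_plasma": "nM",
    "cpi_urine": "nmol",
    "rsv_plasma": "uM",
    "rsv_urine": "nmol",
    "rif_dose": "mg",
    "rsv_dose": "mg",
}

DATASET_COLUMNS = ["ID", "OCC", "TIME", "AMT", "CMT", "EVID", "DV", "MDV", "STREAM"]

_FULL12 = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0)
_DROP16 = tuple(x for x in _FULL12 if x != 16.0)
_CPI12 = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
_CPI11 = tuple(x for x in _CPI12 if x != 0.25)

CPI_URINE_INTERVALS = ((-7.0, 0.0), (0.0, 7.0), (7.0, 24.0))
RSV_URINE_INTERVALS = ((0.0, 7.0), (7.0, 24.0))


@dataclass
class OccasionDesign:
    label: str
    treatments: tuple  # subset of ("RIF", "RSV")
    plasma_times: dict  # stream -> tuple of times (h)
    urine_intervals: dict = field(default_factory=dict)  # stream -> intervals


@dataclass
class TrialDesign:
    n_subjects: int
    occasions: list
    washout_days: float = 7.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for occ in self.occasions:
            for stream, times in occ.plasma_times.items():
                t = np.asarray(times, dtype=float)
                if np.any(t < -7.0) or np.any(t > 24.0):
                    raise ValueError(f"{occ.label}/{stream}: sampling times outside [-7, 24]")
            for stream, ivs in occ.urine_intervals.items():
                ivs = sorted(ivs)
                for (a0, b0), (a1, _b1) in zip(ivs[:-1], ivs[1:]):
                    if a1 < b0:
                        raise ValueError(f"{occ.label}/{stream}: overlapping urine intervals")

    def count_rows(self, stream):
        n = 0
        for occ in self.occasions:
            n += len(occ.plasma_times.get(stream, ()))
            n += len(occ.urine_intervals.get(stream, ()))
        return n * self.n_subjects


def default_design(n_subjects: int = 12) -> TrialDesign:
    """The three-occasion crossover design of the reference study."""
    occ1 = OccasionDesign(
        label="OCC1",
        treatments=("RIF",),
        plasma_times={"rif_plasma": _FULL12, "cpi_plasma": _CPI12},
        urine_intervals={"cpi_urine": CPI_URINE_INTERVALS},
    )
    occ2 = OccasionDesign(
        label="OCC2",
        treatments=("RSV",),
        plasma_times={"rsv_plasma": _DROP16, "cpi_plasma": _CPI12},
        urine_intervals={"cpi_urine": CPI_URINE_INTERVALS, "rsv_urine": RSV_URINE_INTERVALS},
    )
    occ3 = OccasionDesign(
        label="OCC3",
        treatments=("RIF", "RSV"),
        plasma_times={"rif_plasma": _DROP16, "rsv_plasma": _DROP16, "cpi_plasma": _CPI11},
        urine_intervals={"cpi_urine": CPI_URINE_INTERVALS, "rsv_urine": RSV_URINE_INTERVALS},
    )
    return TrialDesign(n_subjects=n_subjects, occasions=[occ1, occ2, occ3])


def _interp_rows(t_grid, Y, times):
    """Linear interpolation of each row of Y (m, nt) at ``times`` (k,)."""
    times = np.asarray(times, dtype=float)
    idx = np.clip(np.searchsorted(t_grid, times), 1, len(t_grid) - 1)
    t0 = t_grid[idx - 1]
    t1 = t_grid[idx]
    w = (times - t0) / (t1 - t0)
    return Y[..., idx - 1] * (1.0 - w) + Y[..., idx] * w


def _param_arrays(pop, etas, kappas, occ_index, n, names):
    out = {}
    for name in names:
        base = getattr(pop.fixed, name)
        e = etas.get(name, 0.0)
        k = kappas[name][:, occ_index] if name in kappas else 0.0
        out[name] = np.full(n, base) * np.exp(np.asarray(e) + np.asarray(k))
    return out


def simulate_trial(
    design: TrialDesign,
    rif_pop: PopulationModel,
    cpi_pop: PopulationModel,
    rsv_pop: PopulationModel = None,
    seed: int = 0,
    residual_noise: bool = True,
    dt: float = gridsim.DEFAULT_DT,
    return_truth: bool = False,
):
    """Simulate a complete dataset for the design.

    Per subject, eta is drawn once per compound model and kappa per
    occasion; the subject's own simulated RIF exposure drives CPI and RSV
    inhibition within the same occasion.  Fully reproducible from ``seed``.
    Returns a long-format DataFrame (see DATASET_COLUMNS), plus the latent
    truth (random effects and noise-free profiles) if ``return_truth``.
    """
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    nocc = len(design.occasions)
    t_grid = np.arange(-7.0, 24.0 + dt / 2, dt)

    rif_eta, rif_kap = draw_random_effects(rif_pop, n, nocc, rng)
    cpi_eta, cpi_kap = draw_random_effects(cpi_pop, n, nocc, rng)
    if rsv_pop is not None:
        rsv_eta, rsv_kap = draw_random_effects(rsv_pop, n, nocc, rng)

    rows = []
    truth = {"t_grid": t_grid, "eta": {"rif": rif_eta, "cpi": cpi_eta},
             "kappa": {"rif": rif_kap, "cpi": cpi_kap}, "profiles": {}}
    if rsv_pop is not None:
        truth["eta"]["rsv"] = rsv_eta
        truth["kappa"]["rsv"] = rsv_kap
    ids = np.arange(1, n + 1)

    def obs_rows(stream, occ_label, times, values):
        for i, sid in enumerate(ids):
            for tt, dv in zip(times, values[i]):
                rows.append((sid, occ_label, float(tt), np.nan, CMT_CODES[stream], 0,
                             float(dv), 0, stream))

    for io, occ in enumerate(design.occasions):
        rif_here = "RIF" in occ.treatments
        rsv_here = "RSV" in occ.treatments
        c_rif = None
        if rif_here:
            rp = _param_arrays(rif_pop, rif_eta, rif_kap, io, n, ("ka", "CL", "V", "MTT", "n"))
            rp["dose_umol"] = np.full(n, rif_pop.fixed.dose_umol)
            c_rif = gridsim.rif_profile(rp, t_grid, dose_time=0.0)
            truth["profiles"][(occ.label, "rif")] = c_rif
            rows.extend(
                (sid, occ.label, 0.0, rif_pop.fixed.dose_mg, CMT_CODES["rif_dose"], 1,
                 np.nan, 1, "rif_dose") for sid in ids)
        cp = _param_arrays(cpi_pop, cpi_eta, cpi_kap, io, n,
                           ("ksyn", "CLb", "CLR", "V", "V_rif", "Ki"))
        cpi_conc, cpi_cum = gridsim.cpi_profile(cp, c_rif, t_grid, rif_present=rif_here)
        truth["profiles"][(occ.label, "cpi")] = cpi_conc
        if rsv_pop is not None and rsv_here:
            sp = _param_arrays(rsv_pop, rsv_eta, rsv_kap, io, n,
                               ("ka", "CLb", "CLR", "V1", "V2", "Q",
                                "V1_rif", "V2_rif", "Q_rif", "Ki"))
            sp["dose_nmol"] = np.full(n, rsv_pop.fixed.dose_nmol)
            rsv_conc, rsv_cum = gridsim.rsv_profile(sp, c_rif, t_grid, dose_time=0.0,
                                                    rif_present=rif_here)
            truth["profiles"][(occ.label, "rsv")] = rsv_conc
            rows.extend(
                (sid, occ.label, 0.0, rsv_pop.fixed.dose_mg, CMT_CODES["rsv_dose"], 1,
                 np.nan, 1, "rsv_dose") for sid in ids)

        for stream, times in occ.plasma_times.items():
            if stream == "rif_plasma" and rif_here:
                f = _interp_rows(t_grid, c_rif, times)
                err = rif_pop.err
            elif stream == "cpi_plasma":
                f = _interp_rows(t_grid, cpi_conc, times)
                err = cpi_pop.err
            elif stream == "rsv_plasma" and rsv_pop is not None and rsv_here:
                f = _interp_rows(t_grid, rsv_conc, times)
                err = rsv_pop.err
            else:
                continue
            if residual_noise:
                spv, sav = err.streams[stream]
                f = f * (1.0 + rng.normal(0.0, spv, f.shape)) + rng.normal(0.0, sav, f.shape)
            obs_rows(stream, occ.label, times, f)

        for stream, intervals in occ.urine_intervals.items():
            if stream == "cpi_urine":
                amt = gridsim.interval_amounts(t_grid, cpi_cum, intervals)
                err = cpi_pop.err
            elif stream == "rsv_urine" and rsv_pop is not None and rsv_here:
                amt = gridsim.interval_amounts(t_grid, rsv_cum, intervals)
                err = rsv_pop.err
            else:
                continue
            if residual_noise:
                spv, sav = err.streams[stream]
                amt = amt * (1.0 + rng.normal(0.0, spv, amt.shape)) + rng.normal(0.0, sav, amt.shape)
            obs_rows(stream, occ.label, [iv[1] for iv in intervals], amt)

    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    # pre-dose convention: at equal times observations precede dose records
    df = df.sort_values(["ID", "OCC", "TIME", "EVID", "CMT"], kind="stable").reset_index(drop=True)
    return (df, truth) if return_truth else df


def occasion_baseline_table(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-occasion pre-dose CPI plasma values.

    The pre-dose sample is the CPI plasma observation at t <= 0 of each
    occasion (mean if several).  Missing baselines raise.
    """
    obs = dataset[(dataset["STREAM"] == "cpi_plasma") & (dataset["EVID"] == 0)
                  & (dataset["TIME"] <= 0.0)]
    if obs.empty:
        raise ValueError("dataset contains no pre-dose CPI plasma rows")
    tab = obs.groupby(["ID", "OCC"], as_index=False)["DV"].mean()
    tab = tab.rename(columns={"DV": "baseline"})
    expected = dataset[dataset["STREAM"] == "cpi_plasma"].groupby(["ID", "OCC"]).size()
    missing = set(expected.index) - set(zip(tab["ID"], tab["OCC"]))
    if missing:
        raise ValueError(f"missing pre-dose CPI baselines for {sorted(missing)[:5]} ...")
    return tab
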
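"""Model diagnostics: visual predictive checks and residual tables.

The VPC simulates replicate trials from the population model (replicates
are stacked as extra subjects so one vectorized pass covers all of them),
bins simulated observations by nominal sampling time, and reports the
2.5/50/97.5 percentile bands, stratified by stream and occasion (the
occasion encodes the perpetrator condition).  Bands of replicate medians
are also returned for calibration checks (an observed median should fall
inside the 95% band of simulated medians about 95% of the time when the
model is true).

Residual diagnostics per observation row:

    PRED    population prediction (random effects at zero)
    IPRED   individual prediction (empirical-Bayes modes)
    IWRES   (DV - IPRED) / sd(IPRED)
    CWRES   linearization-based conditional weighted residual:
            the model is linearized in the random effects at the modes,
            giving marginal mean E = IPRED - J b_hat and covariance
            Sigma = J Omega J' + diag(residual variance); CWRES is the
            Cholesky-whitened residual of DV against that Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial import TrialDesign, simulate_trial


@dataclass
class DiagnosticsBundle:
    vpc_bands: pd.DataFrame | None = None
    residuals: pd.DataFrame | None = None
    n_replicates: int = 0


def vpc(dataset, design: TrialDesign, rif_pop, cpi_pop, rsv_pop=None,
        n_replicates=500, seed=0, streams=("cpi_plasma",), dt=0.05,
        percentiles=(2.5, 50.0, 97.5)) -> DiagnosticsBundle:
    """Percentile bands of simulated replicates, with observed overlays."""
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    import copy
    from dataclasses import replace as dc_replace

    n = design.n_subjects
    big = dc_replace(design, n_subjects=n * n_replicates)
    sim = simulate_trial(big, rif_pop, cpi_pop, rsv_pop, seed=seed,
                         residual_noise=True, dt=dt)
    sim = sim[sim["EVID"] == 0]
    sim = sim[sim["STREAM"].isin(streams)]
    # map the stacked subjects back onto replicates
    sim = sim.assign(REP=(sim["ID"] - 1) // n)
    rows = []
    obs = dataset[dataset["EVID"] == 0] if dataset is not None else None
    for (stream, occ, time), grp in sim.groupby(["STREAM", "OCC", "TIME"]):
        if grp.empty:
            continue
        vals = grp["DV"].to_numpy()
        med_by_rep = grp.groupby("REP")["DV"].median().to_numpy()
        row = {"STREAM": stream, "OCC": occ, "TIME": time,
               "n_sim": vals.size}
        for p in percentiles:
            row[f"p{p:g}"] = float(np.percentile(vals, p))
        row["median_lo"] = float(np.percentile(med_by_rep, 2.5))
        row["median_hi"] = float(np.percentile(med_by_rep, 97.5))
        if obs is not None:
            o = obs[(obs["STREAM"] == stream) & (obs["OCC"] == occ)
                    & (np.isclose(obs["TIME"], time))]
            row["obs_median"] = float(o["DV"].median()) if not o.empty else np.nan
        rows.append(row)
    bands = pd.DataFrame(rows).sort_values(["STREAM", "OCC", "TIME"]).reset_index(drop=True)
    # percentile ordering sanity
    pc = [f"p{p:g}" for p in sorted(percentiles)]
    assert (bands[pc].to_numpy() == np.sort(bands[pc].to_numpy(), axis=1)).all()
    return DiagnosticsBundle(vpc_bands=bands, n_replicates=n_replicates)


def residual_table(model, theta) -> pd.DataFrame:
    """PRED / IPRED / IWRES / CWRES table for a fitted model adapter.

    ``model`` is an estimation adapter (RifModel/CpiModel/RsvModel); theta
    the fitted fixed effects.  Rows follow the adapter's internal
    observation ordering (occasion blocks, plasma then urine).
    """
    inner = model.neg2ll(theta)
    B = inner.modes
    n_subj, nb = B.shape
    zero = np.zeros_like(B)
    pred = model.predict(theta, zero[:, None, :])[:, 0]
    ipred = model.predict(theta, B[:, None, :])[:, 0]
    vi = model.sp**2 * ipred**2 + model.sa**2
    iwres = (model.y - ipred) / np.sqrt(vi)
    # FOCE-style linearization at the modes
    h = 1e-3
    eye = np.eye(nb)
    B3 = B[:, None, :] + np.concatenate([np.zeros((1, 1, nb)), h * eye[None]], axis=1)
    F3 = model.predict(theta, B3)
    J = np.transpose((F3[:, 1:] - F3[:, [0]]) / h, (0, 2, 1))  # (s, n_obs, nb)
    E = ipred - np.einsum("sok,sk->so", J, B)
    cwres = np.empty_like(iwres)
    Om = np.diag(model.prior_var)
    for i in range(n_subj):
        Sigma = J[i] @ Om @ J[i].T + np.diag(vi[i])
        L = np.linalg.cholesky(Sigma)
        cwres[i] = np.linalg.solve(L, model.y[i] - E[i])
    rows = []
    for i in range(n_subj):
        for j in range(model.y.shape[1]):
            rows.append({"subject_index": i, "obs_index": j, "DV": model.y[i, j],
                         "PRED": pred[i, j], "IPRED": ipred[i, j],
                         "IWRES": iwres[i, j], "CWRES": cwres[i, j]})
    return pd.DataFrame(rows)
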
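"""Non-compartmental and descriptive metrics.

AUCs are linear trapezoids on the observed grid with no extrapolation; the
DDI window is 0-24 h throughout (sampling ends at 24 h).  The fraction of a
probe's elimination attributable to the inhibited transporter pathway is
fT = 1 - AUC(control)/AUC(+inhibitor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AucResult:
    auc: float
    window: tuple
    method: str = "linear-trapezoid"


@dataclass
class DdiMetrics:
    aucr: float
    ft: float
    cmax_ratio: float


def auc_trapezoid(times, values, window=None) -> AucResult:
    """Linear trapezoid AUC over ``window`` (defaults to the full range).

    Times must be strictly increasing and the window must lie inside the
    observed range; window edges off the grid are linearly interpolated.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if window is None:
        window = (float(times[0]), float(times[-1]))
    a, b = window
    if a < times[0] - 1e-12 or b > times[-1] + 1e-12 or a >= b:
        raise ValueError(f"window {window} outside observed range "
                         f"({times[0]}, {times[-1]})")
    grid = np.unique(np.clip(np.concatenate([[a], times[(times > a) & (times < b)], [b]]),
                             times[0], times[-1]))
    vals = np.interp(grid, times, values)
    return AucResult(auc=float(np.trapezoid(vals, grid)), window=(a, b))


def compute_ft(auc_control: float, auc_inhibited: float) -> float:
    """Transporter-mediated elimination fraction 1 - AUC(control)/AUC(+I)."""
    if auc_control <= 0 or auc_inhibited <= 0:
        raise ValueError("AUCs must be > 0")
    return 1.0 - auc_control / auc_inhibited


def aucr(auc_control: float, auc_inhibited: float) -> float:
    """AUC ratio (+inhibitor / control)."""
    if auc_control <= 0:
        raise ValueError("control AUC must be > 0")
    return auc_inhibited / auc_control


def ddi_metrics(times_control, values_control, times_inhibited, values_inhibited,
                window=(0.0, 24.0)) -> DdiMetrics:
    """AUCR, fT and Cmax ratio for one subject's paired profiles."""
    a_c = auc_trapezoid(times_control, values_control, window).auc
    a_i = auc_trapezoid(times_inhibited, values_inhibited, window).auc
    return DdiMetrics(
        aucr=aucr(a_c, a_i),
        ft=compute_ft(a_c, a_i),
        cmax_ratio=float(np.max(values_inhibited) / np.max(values_control)),
    )


def baseline_stats(table: pd.DataFrame) -> dict:
    """Between-subject variability and occasion comparison of baselines.

    ``table`` has columns ID, OCC, baseline (one row per subject-occasion).
    Returns between-subject %CV (of occasion-pooled subject means),
    per-occasion means and a one-way ANOVA across occasions.
    """
    if table["OCC"].nunique() < 2 or table["ID"].nunique() < 2:
        raise ValueError("need at least 2 occasions and 2 subjects")
    subj_means = table.groupby("ID")["baseline"].mean()
    cv = float(subj_means.std(ddof=1) / subj_means.mean() * 100.0)
    groups = [g["baseline"].to_numpy() for _, g in table.groupby("OCC")]
    if all(np.allclose(g, groups[0]) for g in groups) and all(
            np.allclose(g, g[0]) for g in groups):
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*groups)
    return {
        "between_subject_cv_percent": cv,
        "occasion_means": table.groupby("OCC")["baseline"].mean().to_dict(),
        "anova_f": float(f_stat),
        "anova_p": float(p_val),
    }


def subject_ddi_table(dataset: pd.DataFrame, stream: str, control_occ: str,
                      ddi_occ: str, window=(0.0, 24.0)) -> pd.DataFrame:
    """Per-subject AUCR/fT/Cmax-ratio between two occasions of a dataset."""
    obs = dataset[(dataset["STREAM"] == stream) & (dataset["EVID"] == 0)]
    out = []
    for sid, g in obs.groupby("ID"):
        gc = g[g["OCC"] == control_occ].sort_values("TIME")
        gi = g[g["OCC"] == ddi_occ].sort_values("TIME")
        if gc.empty or gi.empty:
            continue
        # clip the window to the jointly observed range (no extrapolation)
        lo = max(window[0], gc["TIME"].min(), gi["TIME"].min())
        hi = min(window[1], gc["TIME"].max(), gi["TIME"].max())
        m = ddi_metrics(gc["TIME"].to_numpy(), gc["DV"].to_numpy(),
                        gi["TIME"].to_numpy(), gi["DV"].to_numpy(), (lo, hi))
        out.append({"ID": sid, "AUCR": m.aucr, "fT": m.ft, "Cmax_ratio": m.cmax_ratio})
    return pd.DataFrame(out)
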
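"""Population layer: random effects, covariates and residual error.

Parameters are log-normal across subjects and occasions,

    theta_ik = theta * exp(eta_i + kappa_ik),

with eta ~ N(0, omega^2) constant within a subject (IIV) and kappa ~
N(0, pi^2) drawn independently per occasion (IOV).  Variability is reported
in the parameter table as %CV on the natural scale and converted with
omega^2 = ln(1 + (CV/100)^2).  The binary perpetrator-condition covariate is
applied after the random effects by swapping in the RIF-condition value of
the affected parameter (shared random effect), so removing the flag restores
the baseline parameter exactly.

Residual error is combined proportional + additive per observation stream:
y = f*(1 + eps_p) + eps_a, var(y|f) = sigma_prop^2 f^2 + sigma_add^2.
Simulated observations may be negative; an optional lower-limit-of-
quantification censoring switch exists and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml

from .params import Constants, CpiParams, RifParams, RsvParams

#: parameter -> its RIF-condition counterpart field, per compound model
COVARIATE_FIELDS = {
    CpiParams: {"V": "V_rif"},
    RsvParams: {"V1": "V1_rif", "V2": "V2_rif", "Q": "Q_rif"},
    RifParams: {},
}


def cv_to_variance(cv_percent):
    """Log-scale variance omega^2 from a natural-scale %CV."""
    cv = np.asarray(cv_percent, dtype=float) / 100.0
    return np.log1p(cv**2)


def variance_to_cv(omega2):
    """Natural-scale %CV sqrt(exp(omega^2) - 1) * 100."""
    return np.sqrt(np.expm1(np.asarray(omega2, dtype=float))) * 100.0


@dataclass
class RandomEffectsSpec:
    """IIV and IOV variances (log scale) keyed by parameter name."""

    omega2: dict = field(default_factory=dict)
    pi2: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.omega2, self.pi2):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"variance for {k!r} must be >= 0, got {v!r}")

    @classmethod
    def from_cv(cls, iiv_cv=None, iov_cv=None):
        return cls(
            omega2={k: float(cv_to_variance(v)) for k, v in (iiv_cv or {}).items()},
            pi2={k: float(cv_to_variance(v)) for k, v in (iov_cv or {}).items()},
        )

    @property
    def eta_names(self):
        return sorted(self.omega2)

    @property
    def kappa_names(self):
        return sorted(self.pi2)


@dataclass
class ResidualErrorSpec:
    """Combined residual error per observation stream.

    streams: mapping stream name -> (sigma_prop, sigma_add); sigma_add is in
    the units of the stream.
    """

    streams: dict

    def __post_init__(self):
        for s, (sp, sa) in self.streams.items():
            if sp < 0 or sa < 0 or (sp == 0 and sa == 0):
                raise ValueError(f"stream {s!r}: need sigma_prop, sigma_add >= 0, not both 0")

    def variance(self, stream, f):
        sp, sa = self.streams[stream]
        return sp**2 * np.asarray(f, dtype=float) ** 2 + sa**2


@dataclass
class PopulationModel:
    """Fixed effects + random-effects spec + residual errors for one compound."""

    fixed: object  # RifParams | CpiParams | RsvParams
    re: RandomEffectsSpec
    err: ResidualErrorSpec

    def individual(self, eta=None, kappa=None, rif_present=False):
        return individual_params(self, eta, kappa, rif_present=rif_present)


def individual_params(pop: PopulationModel, eta=None, kappa=None, rif_present=False):
    """Individual structural parameters theta * exp(eta + kappa).

    eta / kappa : mappings parameter name -> random-effect value; names must
    be declared in the random-effects spec.  The RIF-condition covariate is
    applied after the random effects: the shifted parameter's typical value
    is replaced by its RIF-condition counterpart while sharing the same
    random effect (both fields are populated either way, so downstream code
    can still select per-condition values).
    """
    eta = dict(eta or {})
    kappa = dict(kappa or {})
    for name in eta:
        if name not in pop.re.omega2:
            raise KeyError(f"eta supplied for {name!r} which has no IIV term")
    for name in kappa:
        if name not in pop.re.pi2:
            raise KeyError(f"kappa supplied for {name!r} which has no IOV term")
    p = pop.fixed
    cov = COVARIATE_FIELDS[type(p)]
    updates = {}
    for f in fields(p):
        name = f.name
        base = getattr(p, name)
        # RIF-condition fields share the random effect of their baseline field
        src = next((b for b, rf in cov.items() if rf == name), name)
        e = eta.get(src, 0.0) + kappa.get(src, 0.0)
        if e:
            updates[name] = base * float(np.exp(e))
    if rif_present:
        # covariate applied after the random effects: the working field takes
        # its RIF-condition value (same random effect); the *_rif field keeps
        # that value too, so dropping the flag restores baseline exactly
        for base_field, rif_field in cov.items():
            updates[base_field] = updates.get(rif_field, getattr(p, rif_field))
    return replace(p, **updates) if updates else replace(p)


def predict_observation(f, stream, err: ResidualErrorSpec):
    """Prediction + residual variance for an observation of a stream."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("prediction must be >= 0")
    return f, err.variance(stream, f)


def sample_observation(f, stream, err: ResidualErrorSpec, rng, lloq=None):
    """Noisy observation y = f*(1+eps_p) + eps_a.

    Negative draws are retained unless ``lloq`` is given, in which case
    values below it are reported as lloq/2 (simple imputation convention).
    """
    f = np.asarray(f, dtype=float)
    sp, sa = err.streams[stream]
    y = f * (1.0 + rng.normal(0.0, sp, f.shape)) + rng.normal(0.0, sa, f.shape)
    if lloq is not None:
        y = np.where(y < lloq, lloq / 2.0, y)
    return y


def draw_random_effects(pop: PopulationModel, n_subjects, n_occasions, rng):
    """Sample eta (n_subjects,) and kappa (n_subjects, n_occasions) per name.

    Returns (etas, kappas): dicts name -> array.  eta is shared across
    occasions; kappa is independent per occasion.
    """
    etas = {
        k: rng.normal(0.0, np.sqrt(v), n_subjects) if v > 0 else np.zeros(n_subjects)
        for k, v in pop.re.omega2.items()
    }
    kappas = {
        k: (rng.normal(0.0, np.sqrt(v), (n_subjects, n_occasions)) if v > 0
            else np.zeros((n_subjects, n_occasions)))
        for k, v in pop.re.pi2.items()
    }
    return etas, kappas


# ---------------------------------------------------------------------------
# Parameter fixture (reference parameter table)

def _load_fixture():
    with resources.files("copropk.data").joinpath("reference_parameters.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_parameter_table(path=None):
    """Load a parameter file (YAML); defaults to the packaged reference table."""
    if path is None:
        return _load_fixture()
    with open(path) as fh:
        return yaml.safe_load(fh)


def reference_models(path=None):
    """PopulationModel triple (rif, cpi, rsv) from a parameter file."""
    tab = load_parameter_table(path)
    rifblock = tab["rifampicin"]
    rif = PopulationModel(
        fixed=RifParams(dose_mg=float(rifblock.get("dose_mg", 600.0)), **rifblock["fixed"]),
        re=RandomEffectsSpec.from_cv(rifblock.get("iiv_cv"), rifblock.get("iov_cv")),
        err=ResidualErrorSpec({s: (v["sigma_prop"], v["sigma_add"])
                               for s, v in rifblock["error"].items()}),
    )
    cpiblock = tab["cpi"]
    cpi = PopulationModel(
        fixed=CpiParams(**cpiblock["fixed"]),
        re=RandomEffectsSpec.from_cv(cpiblock.get("iiv_cv"), cpiblock.get("iov_cv")),
        err=ResidualErrorSpec({s: (v["sigma_prop"], v["sigma_add"])
                               for s, v in cpiblock["error"].items()}),
    )
    rsvblock = tab["rosuvastatin"]
    rsv = PopulationModel(
        fixed=RsvParams(dose_mg=float(rsvblock.get("dose_mg", 5.0)), **rsvblock["fixed"]),
        re=RandomEffectsSpec.from_cv(rsvblock.get("iiv_cv"), rsvblock.get("iov_cv")),
        err=ResidualErrorSpec({s: (v["sigma_prop"], v["sigma_add"])
                               for s, v in rsvblock["error"].items()}),
    )
    return rif, cpi, rsv


def reference_constants(path=None) -> Constants:
    tab = load_parameter_table(path)
    return Constants(fu_rif=float(tab["constants"]["fu_rif"]))
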
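"""Structural parameter sets for the three compounds.

Units are molar throughout: rifampicin (RIF) and rosuvastatin (RSV) plasma
concentrations in uM, coproporphyrin I (CPI) in nM; urine amounts in nmol
(CPI, RSV); clearances in L/h, volumes in L, times in h.  Oral doses are
converted from mg with the molar masses below; the bioavailability fraction F
is fixed to 1 because all clearances and volumes are apparent oral
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

RIF_MW = 822.94
"""Molar mass of rifampicin (g/mol)."""

RSV_MW = 481.54
"""Molar mass of rosuvastatin (g/mol, free acid)."""

FU_RIF = 0.11
"""Rifampicin unbound fraction in plasma (dimensionless)."""


def _require_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not v > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {v!r}")


@dataclass
class Constants:
    """Physico-chemical constants shared across models."""

    fu_rif: float = FU_RIF

    def __post_init__(self):
        if not 0 < self.fu_rif <= 1:
            raise ValueError(f"fu_rif must lie in (0, 1], got {self.fu_rif!r}")


@dataclass
class RifParams:
    """One-compartment disposition with transit-compartment absorption.

    ka    first-order absorption rate from the depot (1/h)
    CL    apparent oral clearance (L/h)
    V     apparent central volume (L)
    MTT   mean transit time of the absorption delay (h)
    n     number of transit compartments (continuous, >= 0)
    F     bioavailability fraction, fixed 1 for apparent oral parameters
    """

    ka: float
    CL: float
    V: float
    MTT: float
    n: float
    F: float = 1.0
    dose_mg: float = 600.0
    MW: float = RIF_MW

    def __post_init__(self):
        _require_positive(self, ("ka", "CL", "V", "MTT", "MW"))
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n!r}")
        if not 0 < self.F <= 1:
            raise ValueError(f"F must lie in (0, 1], got {self.F!r}")
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be >= 0")

    @property
    def dose_umol(self) -> float:
        """Absorbed dose in umol (F * dose / MW)."""
        return self.F * self.dose_mg / self.MW * 1000.0

    @property
    def ktr(self) -> float:
        """Transit rate constant (n + 1) / MTT (1/h)."""
        return (self.n + 1.0) / self.MTT


@dataclass
class CpiParams:
    """Turnover model of the endogenous biomarker CPI.

    Zero-order synthesis (ksyn, nM/h) into a single distribution volume,
    first-order loss split into a biliary route (CLb, inhibitable by the
    perpetrator) and a renal route (CLR, feeding the urine compartment).
    V_rif is the distribution volume when the perpetrator is co-administered
    (binary covariate); Ki is the total (not unbound) perpetrator inhibition
    constant in uM.
    """

    ksyn: float
    CLb: float
    CLR: float
    V: float
    V_rif: float
    Ki: float

    def __post_init__(self):
        _require_positive(self, ("ksyn", "CLb", "CLR", "V", "V_rif", "Ki"))

    @property
    def css(self) -> float:
        """Baseline steady-state plasma concentration ksyn/(CLb+CLR) (nM)."""
        return self.ksyn / (self.CLb + self.CLR)


@dataclass
class RsvParams:
    """Two-compartment disposition with first-order absorption for RSV.

    Elimination from the central compartment is split into biliary (CLb,
    inhibitable) and renal (CLR) clearances.  V1/V2/Q carry separate values
    under RIF co-administration (binary covariate).  Ki in uM (total).
    """

    ka: float
    CLb: float
    CLR: float
    V1: float
    V2: float
    Q: float
    V1_rif: float
    V2_rif: float
    Q_rif: float
    Ki: float
    F: float = 1.0
    dose_mg: float = 5.0
    MW: float = RSV_MW

    def __post_init__(self):
        _require_positive(
            self,
            ("ka", "CLb", "CLR", "V1", "V2", "Q", "V1_rif", "V2_rif", "Q_rif", "Ki", "MW"),
        )
        if not 0 < self.F <= 1:
            raise ValueError(f"F must lie in (0, 1], got {self.F!r}")

    @property
    def dose_nmol(self) -> float:
        """Absorbed dose in nmol."""
        return self.F * self.dose_mg / self.MW * 1e6


def replace_params(p, **kwargs):
    """Return a copy of a parameter dataclass with fields replaced."""
    values = {f.name: getattr(p, f.name) for f in fields(p)}
    values.update(kwargs)
    return type(p)(**values)
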
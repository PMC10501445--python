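"""Model inputs for the ES-SCLC cost-effectiveness model.

:class:`ModelParams` carries every quantity the cohort engine and the
economic analyses consume: per-cycle drug acquisition costs, adverse-event
management costs and risks, health-state utilities and AE disutilities, the
annual discount rate, the model horizon, cohort demographics and the
willingness-to-pay threshold.  Defaults are the base case of the published
Chinese healthcare-system evaluation of first-line serplulimab +
carboplatin/etoposide versus placebo + carboplatin/etoposide (2022 USD).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

AE_NAMES = ("anemia", "wbc_decrease", "neutrophil_decrease", "platelet_decrease")

ARM_ACTIVE = "active"
ARM_CONTROL = "control"
ARMS = (ARM_ACTIVE, ARM_CONTROL)


@dataclass
class AdverseEventProfile:
    """One grade >=3 adverse event: management cost, disutility, per-arm risk."""

    cost: float
    disutility: float
    risk_active: float
    risk_control: float

    def risk(self, arm: str) -> float:
        return self.risk_active if arm == ARM_ACTIVE else self.risk_control


@dataclass
class Demographics:
    """Cohort averages used for dose auditing (Calvert / Cockcroft-Gault)."""

    weight_kg: float = 65.0
    bsa_m2: float = 1.72
    serum_creatinine_mg_dl: float = 1.0
    age_years: float = 61.1
    sex: str = "male"


@dataclass
class ModelParams:
    """All inputs of the four-state Markov cohort model (base-case defaults).

    Costs are USD per 21-day cycle; utilities are per-year quality weights;
    AE risks are per-patient probabilities of a grade >=3 event during
    first-line treatment; the discount rate is annual and applies to both
    costs and health outcomes.
    """

    # -- structure ---------------------------------------------------------
    cycle_length_days: float = 21.0
    horizon_years: float = 7.44
    discount_annual: float = 0.05
    induction_cycles: int = 4
    secondline_duration: int = 4  # tunnel length (cycles) of 2nd-line therapy
    secondline_mix_irinotecan: float = 0.5  # irinotecan- vs etoposide-based

    # -- per-cycle treatment costs (USD) -----------------------------------
    cost_serplulimab_cycle: float = 2382.65
    cost_etoposide_cycle: float = 362.36
    cost_irinotecan_cycle: float = 312.03
    cost_carboplatin_cycle: float = 55.41
    cost_bsc_cycle: float = 344.76
    cost_followup_cycle: float = 87.42
    serplulimab_price_factor: float = 1.0  # scenario lever: 1 - discount

    # -- utilities ---------------------------------------------------------
    utility_pfs: float = 0.673
    utility_pd: float = 0.473
    utility_death: float = 0.0

    # -- adverse events ----------------------------------------------------
    adverse_events: dict[str, AdverseEventProfile] = field(
        default_factory=lambda: {
            "anemia": AdverseEventProfile(533.61, 0.073, 0.054, 0.056),
            "wbc_decrease": AdverseEventProfile(489.30, 0.2, 0.085, 0.087),
            "neutrophil_decrease": AdverseEventProfile(88.42, 0.2, 0.141, 0.138),
            "platelet_decrease": AdverseEventProfile(1106.70, 0.19, 0.062, 0.082),
        }
    )

    # -- treatment pathway -------------------------------------------------
    subsequent_immuno_share_active: float = 0.5523
    subsequent_immuno_share_control: float = 0.5023

    # -- background mortality and economics --------------------------------
    background_mortality_annual: float = 0.00718
    wtp: float = 37423.0
    demographics: Demographics = field(default_factory=Demographics)

    # ----------------------------------------------------------------------
    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def n_cycles(self) -> int:
        return int(math.floor(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days))

    def immuno_share(self, arm: str) -> float:
        return (
            self.subsequent_immuno_share_active
            if arm == ARM_ACTIVE
            else self.subsequent_immuno_share_control
        )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (AE dict deep-copied)."""
        out = dataclasses.replace(self, **changes)
        if "adverse_events" not in changes:
            out.adverse_events = {
                k: dataclasses.replace(v) for k, v in self.adverse_events.items()
            }
        return out

    # ----------------------------------------------------------------------
    def validation_errors(self) -> list[str]:
        """Itemised list of out-of-range fields (empty when valid)."""
        errs: list[str] = []

        def _prob(name: str, v: float) -> None:
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name} must lie in [0, 1], got {v!r}")

        def _nonneg(name: str, v: float) -> None:
            if v < 0:
                errs.append(f"{name} must be >= 0, got {v!r}")

        if self.horizon_years <= 0:
            errs.append(f"horizon_years must be > 0, got {self.horizon_years!r}")
        if self.cycle_length_days <= 0:
            errs.append(f"cycle_length_days must be > 0, got {self.cycle_length_days!r}")
        if self.discount_annual < 0:
            errs.append(f"discount_annual must be >= 0, got {self.discount_annual!r}")
        for name in ("utility_pfs", "utility_pd", "utility_death"):
            _prob(name, getattr(self, name))
        for name in (
            "secondline_mix_irinotecan",
            "subsequent_immuno_share_active",
            "subsequent_immuno_share_control",
            "background_mortality_annual",
        ):
            _prob(name, getattr(self, name))
        for name in (
            "cost_serplulimab_cycle",
            "cost_etoposide_cycle",
            "cost_irinotecan_cycle",
            "cost_carboplatin_cycle",
            "cost_bsc_cycle",
            "cost_followup_cycle",
            "wtp",
        ):
            _nonneg(name, getattr(self, name))
        for ae, prof in self.adverse_events.items():
            _nonneg(f"adverse_events.{ae}.cost", prof.cost)
            _prob(f"adverse_events.{ae}.disutility", prof.disutility)
            _prob(f"adverse_events.{ae}.risk_active", prof.risk_active)
            _prob(f"adverse_events.{ae}.risk_control", prof.risk_control)
        return errs

    def validate(self) -> "ModelParams":
        errs = self.validation_errors()
        if errs:
            raise ValueError("invalid model parameters:\n  " + "\n  ".join(errs))
        return self

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter fields: {sorted(unknown)}")
        if "adverse_events" in d:
            d["adverse_events"] = {
                k: AdverseEventProfile(**v) if isinstance(v, dict) else v
                for k, v in d["adverse_events"].items()
            }
        if "demographics" in d and isinstance(d["demographics"], dict):
            d["demographics"] = Demographics(**d["demographics"])
        return cls(**d)
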
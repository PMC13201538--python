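"""Energetic efficiency: assimilated intake relative to metabolic expenditure.

The dimensionless efficiency of a fish is

    y = omega * F / I

where ``I`` is its measured metabolic expenditure [J h^-1], ``F`` the
model-predicted feeding intake [J h^-1] for a fish of that size at the
temperature of the metabolic measurement, and ``omega`` the assimilation
efficiency — the fraction of ingested energy actually assimilated,
modelled as a logistic function of Arrhenius temperature with the
activation energy reported for carnivorous invertebrate guts
(0.164 eV, intercept e^2.266 at 293.15 K). ``y < 1`` means intake cannot
cover expenditure: the fish is energetically constrained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from . import scaling
from .constants import DEFAULT_CONTEXT, ArrheniusContext, celsius_to_kelvin
from .feeding import PreyEnergetics, feeding_energy_flux
from .respirometry import MetabolicRate


@dataclass(frozen=True)
class AssimilationParams:
    """Logistic temperature dependence of assimilation efficiency."""

    log_omega0: float = 2.266  # intercept on the log-odds scale at T0*
    E_omega_eV: float = 0.164
    T0_star_K: float = 293.15

    @property
    def omega0(self) -> float:
        return math.exp(self.log_omega0)


DEFAULT_ASSIMILATION = AssimilationParams()


def assimilation_efficiency(
    T_K: float,
    params: AssimilationParams = DEFAULT_ASSIMILATION,
    ctx: ArrheniusContext = DEFAULT_CONTEXT,
) -> float:
    """omega(T): logistic of the Arrhenius-linear predictor, in (0, 1).

    At T = T0* this is omega0 / (1 + omega0); it increases strictly with
    temperature for positive activation energy.
    """
    if T_K <= 0:
        raise ValueError("absolute temperature must be positive")
    x = (T_K - params.T0_star_K) / (ctx.k_eV_per_K * T_K * params.T0_star_K)
    z = params.log_omega0 + params.E_omega_eV * x
    return 1.0 / (1.0 + math.exp(-z))


@dataclass(frozen=True)
class EfficiencyRecord:
    """Per-fish, per-prey energetic efficiency and its ingredients."""

    fish_id: str
    prey_taxon: str
    y: float
    intake_J_per_h: float
    expenditure_J_per_h: float
    omega: float
    constrained: bool


def energetic_efficiency(
    metabolic: MetabolicRate,
    predicted_F: float,
    prey: PreyEnergetics,
    params: AssimilationParams = DEFAULT_ASSIMILATION,
    ctx: ArrheniusContext = DEFAULT_CONTEXT,
) -> EfficiencyRecord:
    """Compute y = omega * F_J / I_J for one fish and one prey taxon.

    ``predicted_F`` [individuals h^-1] must come from the selected feeding
    model evaluated at the fish's size and at ``metabolic.mean_temp_C`` —
    the temperature of the metabolic chamber, which also sets omega.
    Requires a QC-passing metabolic record with positive expenditure.
    """
    if not metabolic.qc_pass:
        raise ValueError(f"metabolic record for {metabolic.fish_id} failed QC")
    if metabolic.rate_J_per_h <= 0:
        raise ValueError("metabolic expenditure must be positive")
    omega = assimilation_efficiency(
        celsius_to_kelvin(metabolic.mean_temp_C), params, ctx
    )
    intake = feeding_energy_flux(predicted_F, prey)
    y = omega * intake / metabolic.rate_J_per_h
    return EfficiencyRecord(
        fish_id=metabolic.fish_id,
        prey_taxon=prey.prey_taxon,
        y=y,
        intake_J_per_h=intake,
        expenditure_J_per_h=metabolic.rate_J_per_h,
        omega=omega,
        constrained=y < 1.0,
    )


def records_to_frame(records: list[EfficiencyRecord], metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("fish_id")
    rows = []
    for r in records:
        m = meta.loc[r.fish_id]
        rows.append(
            {
                "fish_id": r.fish_id,
                "prey_taxon": r.prey_taxon,
                "y": r.y,
                "mass_mg": float(m["mass_mg"]),
                "temp_C": float(m["metabolic_temp_C"]) if "metabolic_temp_C" in m else float("nan"),
                "source": m["regime"],
            }
        )
    return pd.DataFrame(rows)


def fit_efficiency_model(
    records: list[EfficiencyRecord],
    metadata: pd.DataFrame,
    temps_C: dict[str, float] | None = None,
    prey_taxon: str | None = None,
) -> tuple[scaling.ScalingFit, list[scaling.ScalingFit]]:
    """AICc-selected scaling model of ln y for one prey taxon.

    ``temps_C`` optionally overrides per-fish temperatures (fish_id ->
    metabolic-chamber temperature); otherwise metadata must carry a
    ``metabolic_temp_C`` column.
    """
    if not records:
        raise ValueError("no efficiency records supplied")
    frame = records_to_frame(records, metadata)
    if prey_taxon is not None:
        frame = frame[frame["prey_taxon"] == prey_taxon]
    if temps_C is not None:
        frame["temp_C"] = frame["fish_id"].map(temps_C)
    if frame["y"].le(0).any():
        raise ValueError("efficiencies must be positive to take logs")
    if len(frame) < 4:
        raise ValueError(f"only {len(frame)} records; too few to fit")
    rows = scaling.make_design(
        frame["mass_mg"], frame["temp_C"], frame["source"], response=frame["y"]
    )
    return scaling.fit_all(rows)
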
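"""Feeding rates from field predation trials and their scaling model.

Each trial offers a fixed number of prey (default 20) of one taxon to a
single fish for about 24 h in an in-stream arena; the feeding rate is
simply prey eaten per hour, F = Ne / t. Rates are analysed with the same
log-linear Arrhenius machinery as metabolic rate, and converted to an
energy flux [J h^-1] using the taxon's mean individual mass and caloric
content (user-supplied; these depend on the local prey population).

Prey depletion during the trial is ignored, so F understates the
instantaneous rate when most prey are eaten; see the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scaling

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeedingTrial:
    """One predation trial: a fish, a prey taxon, and the 24-h outcome."""

    fish_id: str
    prey_taxon: str
    n_offered: int
    n_eaten: int
    duration_h: float
    trial_temp_C: float

    def __post_init__(self):
        if not 0 <= self.n_eaten <= self.n_offered:
            raise ValueError("n_eaten must lie in [0, n_offered]")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class PreyEnergetics:
    """Energetic value of one prey taxon: mean mass [mg] and J per mg."""

    prey_taxon: str
    mean_mass_mg: float
    energy_J_per_mg: float

    def __post_init__(self):
        if self.mean_mass_mg <= 0 or self.energy_J_per_mg <= 0:
            raise ValueError("prey mass and caloric content must be positive")

    @property
    def J_per_individual(self) -> float:
        return self.mean_mass_mg * self.energy_J_per_mg


def feeding_rate(trial: FeedingTrial) -> float:
    """F = Ne / t [individuals h^-1]."""
    return trial.n_eaten / trial.duration_h


def feeding_energy_flux(F: float, prey: PreyEnergetics) -> float:
    """Convert a feeding rate [ind h^-1] to an energy intake [J h^-1]."""
    return F * prey.J_per_individual


def trials_to_frame(
    trials: list[FeedingTrial], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Join trials onto fish metadata (mass_mg, regime keyed by fish_id)."""
    meta = metadata.set_index("fish_id")
    rows = []
    for t in trials:
        m = meta.loc[t.fish_id]
        rows.append(
            {
                "fish_id": t.fish_id,
                "prey_taxon": t.prey_taxon,
                "F": feeding_rate(t),
                "mass_mg": float(m["mass_mg"]),
                "temp_C": t.trial_temp_C,
                "source": m["regime"],
            }
        )
    return pd.DataFrame(rows)


def fit_feeding_model(
    trials: list[FeedingTrial],
    metadata: pd.DataFrame,
    prey_taxon: str | None = None,
) -> tuple[scaling.ScalingFit, list[scaling.ScalingFit]]:
    """Fit and AICc-select the ln F scaling model for one prey taxon.

    Zero-eaten trials have no defined log rate and are excluded with a
    logged count; the log notes how many were dropped.
    """
    frame = trials_to_frame(trials, metadata)
    if prey_taxon is not None:
        frame = frame[frame["prey_taxon"] == prey_taxon]
    n_zero = int((frame["F"] == 0).sum())
    if n_zero:
        logger.warning(
            "excluding %d zero-feeding trial(s) from the log-linear fit", n_zero
        )
        frame = frame[frame["F"] > 0]
    if len(frame) < 4:
        raise ValueError(f"only {len(frame)} usable trials; too few to fit")
    rows = scaling.make_design(
        frame["mass_mg"], frame["temp_C"], frame["source"], response=frame["F"]
    )
    return scaling.fit_all(rows)
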
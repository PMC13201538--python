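"""Physical constants and the Arrhenius temperature transform.

Metabolic and feeding rates of ectotherms are modelled with a
Boltzmann-Arrhenius temperature dependence, linearised by regressing the
log rate on the Arrhenius temperature ``(T - T0) / (k * T * T0)`` where
``k`` is the Boltzmann constant in eV per kelvin and ``T0`` a normalisation
temperature chosen near the centre of the study's thermal range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Boltzmann constant [eV K^-1]
K_BOLTZMANN_EV = 8.618e-5

#: Normalisation temperature for the scaling models [K] (10 degC)
T0_K = 283.15

#: Density of oxygen gas used to convert mg O2 to mL O2 [g L^-1]
O2_DENSITY_G_PER_L = 1.429

#: Oxycaloric conversion [J per mL O2]
J_PER_ML_O2 = 20.1

#: Joules per mg O2 consumed (20.1 J/mL at 1.429 mg/mL)
J_PER_MG_O2 = J_PER_ML_O2 / O2_DENSITY_G_PER_L

#: Minimum r-squared for a respirometry slope to pass quality control
R2_QC_THRESHOLD = 0.8

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(temp_c):
    """Convert Celsius to Kelvin (arrays allowed)."""
    return np.asarray(temp_c, dtype=float) + CELSIUS_OFFSET


@dataclass(frozen=True)
class ArrheniusContext:
    """Constants of the Arrhenius linearisation.

    Attributes
    ----------
    k_eV_per_K : float
        Boltzmann constant [eV K^-1].
    T0_K : float
        Normalisation temperature [K]; the transform is zero at ``T0_K``.
    """

    k_eV_per_K: float = K_BOLTZMANN_EV
    T0_K: float = T0_K

    def transform(self, T_K):
        """Arrhenius temperature ``(T - T0) / (k * T * T0)`` [eV^-1].

        Positive above ``T0``, negative below, zero at ``T0``. Raises
        ``ValueError`` for non-positive absolute temperatures.
        """
        T = np.asarray(T_K, dtype=float)
        if np.any(T <= 0):
            raise ValueError("absolute temperature must be positive")
        out = (T - self.T0_K) / (self.k_eV_per_K * T * self.T0_K)
        return float(out) if np.isscalar(T_K) else out


DEFAULT_CONTEXT = ArrheniusContext()


def arrhenius_transform(T_K, ctx: ArrheniusContext = DEFAULT_CONTEXT):
    """Module-level convenience wrapper around :meth:`ArrheniusContext.transform`."""
    return ctx.transform(T_K)
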
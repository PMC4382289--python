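"""Whole-body muscle metabolic power.

A heat-rate energetics model in the activation/maintenance + shortening
heat + mechanical work tradition. Per-muscle rates scale with estimated
muscle mass (from maximum isometric force, optimal fiber length, muscle
density and specific tension); a constant basal rate is always included.
All coefficients are reconstructions shipped as editable defaults, and the
model object is pluggable so an alternative energetics formulation can be
swapped in behind the same call signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MUSCLE_DENSITY = 1059.7      # kg / m^3
SPECIFIC_TENSION = 0.25e6    # Pa


@dataclass
class MetabolicRates:
    """Per-muscle and total metabolic power breakdown (W)."""

    activation_maintenance: np.ndarray
    shortening: np.ndarray
    work: np.ndarray
    basal: float
    total: float


@dataclass
class MetabolicModel:
    """Heat-rate coefficients.

    activation_rate : W per kg of active muscle at full activation
    shortening_coeff : heat per unit of shortening power (dimensionless)
    basal_rate : W per kg of (unloaded) body mass, always expended
    """

    activation_rate: float = 74.0
    shortening_coeff: float = 0.25
    basal_rate: float = 1.2

    def muscle_mass(self, F_max, l_opt) -> np.ndarray:
        return (np.asarray(F_max) * np.asarray(l_opt)
                * MUSCLE_DENSITY / SPECIFIC_TENSION)

    def rates(self, a, force, v_ce, F_max, l_opt,
              body_mass: float) -> MetabolicRates:
        """Instantaneous rates from per-muscle activation, MTU force (N)
        and fiber velocity (m/s, negative = shortening)."""
        a = np.asarray(a, dtype=float)
        force = np.asarray(force, dtype=float)
        v_ce = np.asarray(v_ce, dtype=float)
        m = self.muscle_mass(F_max, l_opt)
        h_am = self.activation_rate * m * a
        shortening_power = np.maximum(-force * v_ce, 0.0)
        h_sl = self.shortening_coeff * shortening_power
        w = shortening_power
        basal = self.basal_rate * body_mass
        total = basal + float(np.sum(h_am + h_sl + w))
        return MetabolicRates(activation_maintenance=h_am, shortening=h_sl,
                              work=w, basal=basal, total=total)


def metabolic_power(mtu_states, mtu_params, fiber_velocities,
                    body_mass: float,
                    model: MetabolicModel | None = None) -> MetabolicRates:
    """Whole-body metabolic power from MTU states.

    ``mtu_states``: sequence of :class:`reflexgait.mtu.MTUState`;
    ``mtu_params``: matching sequence of :class:`reflexgait.mtu.MTUParams`;
    ``fiber_velocities``: m/s, negative while shortening. ``body_mass`` is
    the unloaded body mass carrying the basal rate.
    """
    if model is None:
        model = MetabolicModel()
    a = [s.a for s in mtu_states]
    force = [s.F_mtu_norm * p.F_max for s, p in zip(mtu_states, mtu_params)]
    F_max = [p.F_max for p in mtu_params]
    l_opt = [p.l_opt for p in mtu_params]
    return model.rates(a, force, fiber_velocities, F_max, l_opt, body_mass)
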
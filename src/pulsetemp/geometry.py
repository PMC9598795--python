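"""Domain types: materials, probe/phantom geometry, treatment conditions.

The physical setup is a cylindrical agar tissue phantom with a single
bipolar ablation probe inserted along its axis.  The probe carries two
axially separated cylindrical electrodes (the proximal one energized, the
distal one grounded) separated by an insulating gap; fiber-optic
temperature sensors sit 4 mm and 10 mm radially from the electrode
surface, level with the active electrode.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialProperties",
    "AGAR",
    "INSULATION",
    "STAINLESS_STEEL",
    "ProbeGeometry",
    "PhantomGeometry",
    "TreatmentCondition",
    "NumericsConfig",
    "standard_conditions",
    "condition_names",
]


@dataclass(frozen=True)
class MaterialProperties:
    """Electrical and thermal constants of one material region.

    Units: density kg/m^3, specific heat J/(kg K), thermal conductivity
    W/(m K), electrical conductivity S/m, temperature coefficient 1/degC.
    ``reference_temperature`` is the temperature (degC) at which
    ``electrical_conductivity`` is quoted.
    """

    density: float
    specific_heat: float
    thermal_conductivity: float
    electrical_conductivity: float
    temperature_coefficient: float = 0.0
    reference_temperature: float = 37.0

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "thermal_conductivity",
                     "electrical_conductivity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.temperature_coefficient < 0:
            raise ValueError("temperature_coefficient must be >= 0")


# Agar mimics water thermally; its electrical conductivity is set per
# treatment condition (NaCl content), with a 2 %/degC temperature rise.
AGAR = MaterialProperties(
    density=998.0, specific_heat=4182.0, thermal_conductivity=0.598,
    electrical_conductivity=0.526, temperature_coefficient=0.02,
)
INSULATION = MaterialProperties(
    density=2329.0, specific_heat=700.0, thermal_conductivity=0.2,
    electrical_conductivity=1e-12,
)
STAINLESS_STEEL = MaterialProperties(
    density=7900.0, specific_heat=500.0, thermal_conductivity=15.0,
    electrical_conductivity=2.22e6,
)


@dataclass(frozen=True)
class ProbeGeometry:
    """Single-insertion bipolar probe, all lengths in meters.

    The probe enters through the top surface of the phantom to
    ``insertion_depth``.  From the tip upward: distal (ground) electrode of
    ``electrode_exposure``, insulating gap of ``insulation_gap``, active
    electrode of ``electrode_exposure``, then insulated shaft to the
    surface.  ``sensor_offsets`` are radial distances from the electrode
    surface to the temperature sensors.
    """

    shaft_radius: float = 0.825e-3
    electrode_exposure: float = 7e-3
    insulation_gap: float = 8e-3
    insertion_depth: float = 30e-3
    sensor_offsets: tuple[float, ...] = (4e-3, 10e-3)

    def __post_init__(self) -> None:
        vals = [self.shaft_radius, self.electrode_exposure,
                self.insulation_gap, self.insertion_depth,
                *self.sensor_offsets]
        if any(v <= 0 for v in vals):
            raise ValueError("all probe dimensions must be positive")
        if self.insertion_depth < 2 * self.electrode_exposure + self.insulation_gap:
            raise ValueError("insertion depth too short for both electrodes")

    @property
    def electrode_spacing(self) -> float:
        """Center-to-center distance between the two electrodes (m)."""
        return self.electrode_exposure + self.insulation_gap


@dataclass(frozen=True)
class PhantomGeometry:
    """Cylindrical agar phantom with convective exterior boundaries.

    The truncated-cone cup mold (top diameter 71 mm, bottom 46 mm) is
    modeled as a cylinder of radius 29 mm; the wall is >=19 mm from the
    outermost sensor so the far-field shape has negligible effect at the
    sensor locations.
    """

    radius: float = 29e-3
    height: float = 66e-3
    ambient_temperature: float = 18.8
    convective_coefficient: float = 10.0  # free air convection, W/(m^2 K)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.convective_coefficient < 0:
            raise ValueError("convective coefficient must be >= 0")


def _implied_agar_temperature(sigma_ref: float, sigma_initial: float,
                              alpha: float, t_ref: float = 37.0) -> float:
    """Pulsing-time agar temperature implied by the initial conductivity.

    Inverts sigma_f = sigma_ref * (1 + alpha * (T_agar - T_ref)).
    """
    return t_ref + (sigma_initial / sigma_ref - 1.0) / alpha


@dataclass(frozen=True)
class TreatmentCondition:
    """One experimental group: voltage, conductivities, burst timing.

    ``sigma_ref`` is the conductivity measured at 37 degC; ``sigma_initial``
    is the conductivity at the (cooler) pulsing temperature.  If
    ``agar_temperature`` is None it is inferred from the two conductivities
    through the linear temperature coefficient.
    """

    name: str
    applied_voltage: float           # V
    sigma_ref: float                 # S/m at 37 degC
    sigma_initial: float             # S/m at pulsing temperature
    agar_temperature: float | None = None  # degC at pulsing time
    burst_on_time: float = 100e-6    # s energized per burst
    burst_period: float = 1.0        # s between bursts
    duration: float = 300.0          # s of treatment
    alpha: float = 0.02              # 1/degC conductivity coefficient

    def __post_init__(self) -> None:
        if not 0 < self.burst_on_time < self.burst_period:
            raise ValueError("require 0 < burst_on_time < burst_period")
        if self.sigma_ref <= 0 or self.sigma_initial <= 0:
            raise ValueError("conductivities must be positive")
        if self.agar_temperature is None:
            object.__setattr__(
                self, "agar_temperature",
                _implied_agar_temperature(self.sigma_ref, self.sigma_initial,
                                          self.alpha))

    @property
    def duty_cycle(self) -> float:
        return self.burst_on_time / self.burst_period

    def with_sigma_initial(self, sigma_initial: float) -> "TreatmentCondition":
        """Copy with a perturbed initial conductivity (replicate jitter).

        sigma_ref is scaled by the same factor so the implied agar
        temperature is preserved."""
        factor = sigma_initial / self.sigma_initial
        return replace(self, sigma_initial=sigma_initial,
                       sigma_ref=self.sigma_ref * factor)


def standard_conditions() -> dict[str, TreatmentCondition]:
    """The four experimental groups: voltage 1250/2500 V crossed with
    low/high NaCl agar conductivity (0.122/0.526 S/m at 37 degC).

    Initial conductivities at pulsing temperature are the per-group
    measured values (0.331, 0.085, 0.093, 0.331 S/m); they imply slightly
    different agar temperatures per group, which is honored.
    """
    return {
        "HV-HC": TreatmentCondition("HV-HC", 2500.0, 0.526, 0.331),
        "LV-LC": TreatmentCondition("LV-LC", 1250.0, 0.122, 0.085),
        "HV-LC": TreatmentCondition("HV-LC", 2500.0, 0.122, 0.093),
        "LV-HC": TreatmentCondition("LV-HC", 1250.0, 0.526, 0.331),
    }


def condition_names() -> tuple[str, ...]:
    return ("HV-HC", "LV-LC", "HV-LC", "LV-HC")


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and solver controls for the phantom simulator.

    ``fine_spacing`` applies within ``fine_extent`` of the probe (covering
    both sensors), ``coarse_spacing`` elsewhere.  The potential is
    re-solved every ``resolve_interval`` seconds of simulated time, or
    sooner when the maximum temperature change since the last solve
    exceeds ``resolve_dtemp``.  The heat equation advances by implicit
    Euler steps of ``dt``.
    """

    fine_spacing: float = 0.5e-3
    coarse_spacing: float = 2.0e-3
    fine_extent: float = 12e-3
    dt: float = 1.0
    resolve_interval: float = 10.0
    resolve_dtemp: float = 0.5
    sigma_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.fine_spacing <= 0 or self.coarse_spacing < self.fine_spacing:
            raise ValueError("require 0 < fine_spacing <= coarse_spacing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def update_conductivity(temperature, sigma_ref: float, alpha: float,
                        t_ref: float, floor: float = 1e-6):
    """Linear temperature scaling of electrical conductivity.

    sigma(T) = sigma_ref * (1 + alpha * (T - t_ref)), clipped below at
    ``floor`` to stay physical under extreme extrapolation.

    Parameters are the reference conductivity (S/m at ``t_ref`` degC) and
    the fractional temperature coefficient alpha (1/degC).
    """
    if sigma_ref <= 0:
        raise ValueError("sigma_ref must be positive")
    t = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature field contains non-finite values")
    sigma = sigma_ref * (1.0 + alpha * (t - t_ref))
    return np.maximum(sigma, floor) if sigma.ndim else float(max(sigma, floor))
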
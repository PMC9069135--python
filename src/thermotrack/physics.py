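"""Closed-form temperature physics for microswimmers in water.

Water viscosity follows the three-parameter Vogel correlation

    eta(T) = A * base**(B / (T - C)),

with the standard base-10 parameters A = 2.414e-5 Pa*s, B = 247.8 K,
C = 140 K, valid roughly between 0 and 100 degC. Diffusion of a passive
sphere follows Stokes-Einstein, D = kB*T / (6*pi*eta*r). The product of a
swimmer's mean speed and the water viscosity is proportional to the propulsive
(flagellar) force at terminal velocity, F = 6*pi*eta*r*v_inf, and serves as a
radius-free force proxy when comparing one population across temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant, J/K (exact, 2019 SI)
BOLTZMANN_CONSTANT = 1.380649e-23


@dataclass(frozen=True)
class ViscosityModel:
    """Vogel viscosity-temperature correlation for liquid water.

    Attributes
    ----------
    A : float
        High-temperature viscosity prefactor, Pa*s.
    B : float
        Temperature constant, K.
    C : float
        Temperature offset (divergence point), K.
    base : float
        Base of the exponential. The canonical parameter set above is a
        base-10 correlation; an e-base variant can be selected here.
    """

    A: float = 2.414e-5
    B: float = 247.8
    C: float = 140.0
    base: float = 10.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("viscosity prefactor A must be positive")
        if self.base <= 1:
            raise ValueError("exponential base must exceed 1")


DEFAULT_VISCOSITY_MODEL = ViscosityModel()


@dataclass(frozen=True)
class ParticlePhysics:
    """Temperature and hydrodynamic radius of a diffusing particle.

    Temperatures are absolute (kelvin); the water viscosity model is only
    trustworthy in the liquid range, so construction warns outside
    (273 K, 373 K) by raising ValueError.
    """

    temperature: float
    radius: float
    boltzmann_constant: float = BOLTZMANN_CONSTANT

    def __post_init__(self) -> None:
        if not (273.0 < self.temperature < 373.0):
            raise ValueError(
                "temperature must lie in the liquid-water window (273, 373) K; "
                f"got {self.temperature} K"
            )
        if self.radius <= 0:
            raise ValueError("hydrodynamic radius must be positive")

    def diffusion_coefficient(self, eta: float | None = None,
                              model: ViscosityModel = DEFAULT_VISCOSITY_MODEL) -> float:
        """Stokes-Einstein D in m^2/s; eta defaults to water at this temperature."""
        if eta is None:
            eta = water_viscosity(self.temperature, model)
        return stokes_einstein_D(self.temperature, self.radius, eta,
                                 k_B=self.boltzmann_constant)


def water_viscosity(T: float, model: ViscosityModel = DEFAULT_VISCOSITY_MODEL) -> float:
    """Dynamic viscosity of water at absolute temperature ``T`` (K), in Pa*s.

    Strictly decreasing in T. Raises ValueError at or below the model's
    divergence temperature C.

    >>> round(water_viscosity(293.15) * 1e3, 3)  # 20 degC, mPa*s
    1.002
    """
    if T <= model.C:
        raise ValueError(f"temperature {T} K must exceed the model offset C = {model.C} K")
    return model.A * model.base ** (model.B / (T - model.C))


def celsius_to_kelvin(T_celsius: float) -> float:
    return T_celsius + 273.15


def stokes_einstein_D(temperature: float, radius: float, eta: float,
                      k_B: float = BOLTZMANN_CONSTANT) -> float:
    """Diffusion coefficient D = kB*T / (6*pi*eta*r) of a sphere, in m^2/s.

    Parameters are SI: temperature in K, radius in m, eta in Pa*s.
    Note the worked example of a cell diffusing at 0.30 um^2/s at 33 degC
    (and 0.86 um^2/s at 91 degC) corresponds to a hydrodynamic radius of 1 um.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    if temperature <= 0:
        raise ValueError("absolute temperature must be positive")
    return k_B * temperature / (6.0 * math.pi * eta * radius)


def stokes_drag(eta: float, radius: float) -> float:
    """Stokes drag coefficient 6*pi*eta*r (kg/s) of a sphere.

    At terminal velocity the flagellar force balances drag: F = stokes_drag * v.
    """
    if eta <= 0 or radius <= 0:
        raise ValueError("viscosity and radius must be positive")
    return 6.0 * math.pi * eta * radius


def force_proxy(mean_speed: float, T: float,
                model: ViscosityModel = DEFAULT_VISCOSITY_MODEL) -> float:
    """Mean swimming speed times water viscosity, in um*Pa.

    Proportional to the flagellar force of a swimmer at terminal velocity
    (F = 6*pi*eta*r*v), without requiring the cell radius; useful to compare
    propulsion across temperatures where eta varies strongly.
    """
    if mean_speed < 0:
        raise ValueError("mean speed must be non-negative")
    return mean_speed * water_viscosity(T, model)


def brownian_step_sigma(D: float, dt: float) -> float:
    """Per-axis standard deviation sqrt(2*D*dt) of a Brownian displacement.

    Unit-consistent: D in um^2/s and dt in s give the result in um.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt <= 0:
        raise ValueError("time step must be positive")
    return math.sqrt(2.0 * D * dt)


def brownian_D_um2_s(temperature: float, radius_um: float = 1.0,
                     model: ViscosityModel = DEFAULT_VISCOSITY_MODEL) -> float:
    """Convenience: Stokes-Einstein D in um^2/s for water at ``temperature`` K."""
    eta = water_viscosity(temperature, model)
    return stokes_einstein_D(temperature, radius_um * 1e-6, eta) * 1e12
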
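"""Temperature dependence of scatterer spacing, sound speed and resonances.

A tissue with a quasi-regular scattering lattice of mean spacing ``d``
produces echoes whose mean inter-arrival time ``2 d / v`` defines a
fundamental resonance ``f1 = v / (2 d)`` and its overtones ``f_x = x f1``.
Heating the tissue by ``dT`` dilates the lattice, ``d(T) = d0 (1 + a dT)``
with linear expansion coefficient ``a``, and changes the speed of sound,
``v(T) = v0 + (dv/dT) dT``.  To first order in ``dT`` the x-th overtone
shifts by

    df_x = (x / (2 d0)) * (dv/dT - a v0) * dT

so the bracketed *effective thermal coefficient* ``k = dv/dT - a v0``
converts a measured overtone shift directly into a temperature change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError

#: Linear thermal-expansion coefficient default, 1/degC (water-like soft tissue).
DEFAULT_EXPANSION_COEFF = 3.7e-4

#: Effective thermal coefficient k = dv/dT - alpha*v0 in (m/s)/degC,
#: back-solved from a published 43rd-harmonic displacement of 871.66 Hz per
#: 0.1 degC for a 1.1 mm lattice (see ``calibrate_effective_coefficient``).
DEFAULT_EFFECTIVE_COEFF = 871.66 * 2.0 * 1.1e-3 / (43 * 0.1)

#: Default base speed of sound in soft tissue, m/s.
DEFAULT_BASE_SPEED = 1540.0


@dataclass(frozen=True)
class TissueThermalModel:
    """Thermal state of a scattering tissue.

    Parameters
    ----------
    base_spacing : float
        Mean scatterer spacing ``d0`` at the base temperature, in metres.
    base_speed : float
        Speed of sound ``v0`` at the base temperature, m/s.
    base_temperature : float
        Base temperature ``T0`` in degC.  All laws are expressed in terms of
        ``dT = T - T0``; the absolute value is metadata only.
    expansion_coeff : float
        Linear thermal expansion coefficient ``alpha``, 1/degC.
    speed_slope : float or None
        ``dv/dT`` at ``T0``, (m/s)/degC.  When omitted it is derived from
        :data:`DEFAULT_EFFECTIVE_COEFF` so that the effective coefficient
        matches the calibrated default.
    """

    base_spacing: float
    base_speed: float = DEFAULT_BASE_SPEED
    base_temperature: float = 30.0
    expansion_coeff: float = DEFAULT_EXPANSION_COEFF
    speed_slope: float | None = None

    def __post_init__(self) -> None:
        if not self.base_spacing > 0:
            raise ConfigurationError("base_spacing must be positive")
        if not self.base_speed > 0:
            raise ConfigurationError("base_speed must be positive")
        if self.expansion_coeff < 0:
            raise ConfigurationError("expansion_coeff must be >= 0")
        if self.speed_slope is None:
            slope = DEFAULT_EFFECTIVE_COEFF + self.expansion_coeff * self.base_speed
            object.__setattr__(self, "speed_slope", slope)
        if not math.isfinite(self.effective_coefficient):
            raise ConfigurationError("effective coefficient must be finite")

    @property
    def effective_coefficient(self) -> float:
        """``k = dv/dT - alpha * v0``, (m/s)/degC.  May be negative."""
        return self.speed_slope - self.expansion_coeff * self.base_speed

    @property
    def fundamental(self) -> float:
        """Fundamental resonance ``v0 / (2 d0)`` at the base temperature, Hz."""
        return self.base_speed / (2.0 * self.base_spacing)

    def speed_at(self, delta_t: float) -> float:
        """Speed of sound at ``T0 + delta_t``, m/s."""
        return self.base_speed + self.speed_slope * delta_t

    @classmethod
    def with_effective_coefficient(
        cls,
        base_spacing: float,
        effective_coefficient: float,
        *,
        base_speed: float = DEFAULT_BASE_SPEED,
        base_temperature: float = 30.0,
        expansion_coeff: float = DEFAULT_EXPANSION_COEFF,
    ) -> "TissueThermalModel":
        """Build a model whose ``speed_slope`` realises a given ``k``."""
        slope = effective_coefficient + expansion_coeff * base_speed
        return cls(
            base_spacing=base_spacing,
            base_speed=base_speed,
            base_temperature=base_temperature,
            expansion_coeff=expansion_coeff,
            speed_slope=slope,
        )


@dataclass(frozen=True)
class HarmonicSelection:
    """A chosen overtone ``x`` of the fundamental resonance."""

    harmonic_index: int
    expected_frequency: float

    def __post_init__(self) -> None:
        if self.harmonic_index < 1:
            raise ConfigurationError("harmonic_index must be >= 1")


def spacing_at_temperature(model: TissueThermalModel, delta_t: float) -> float:
    """Mean scatterer spacing ``d0 (1 + alpha dT)`` at ``T0 + delta_t``, m."""
    return model.base_spacing * (1.0 + model.expansion_coeff * delta_t)


def harmonic_frequency(model: TissueThermalModel, x: int, delta_t: float = 0.0) -> float:
    """Exact x-th overtone frequency ``x v(T) / (2 d(T))`` in Hz."""
    if x < 1:
        raise ConfigurationError("harmonic index must be >= 1")
    return x * model.speed_at(delta_t) / (2.0 * spacing_at_temperature(model, delta_t))


def harmonic_shift(model: TissueThermalModel, x: int, delta_t: float) -> float:
    """First-order overtone shift ``(x / 2 d0) k dT`` in Hz.

    Linear in both the harmonic index and the temperature change.
    """
    if x < 1:
        raise ConfigurationError("harmonic index must be >= 1")
    return x / (2.0 * model.base_spacing) * model.effective_coefficient * delta_t


def invert_shift_to_temperature(model: TissueThermalModel, x: int, shift: float) -> float:
    """Temperature change (degC) implied by a measured overtone shift (Hz)."""
    k = model.effective_coefficient
    if k == 0:
        raise ConfigurationError(
            "effective thermal coefficient is zero: temperature is unobservable"
        )
    return shift * 2.0 * model.base_spacing / (x * k)


def calibrate_effective_coefficient(
    base_spacing: float, x: int, delta_t: float, shift: float
) -> float:
    """Back-solve the effective coefficient ``k`` from one known shift.

    Given a measured (or tabulated) shift of the x-th overtone for a known
    temperature change, returns ``k = shift * 2 d0 / (x dT)`` in (m/s)/degC.
    """
    if delta_t == 0:
        raise ConfigurationError("cannot calibrate from delta_t = 0")
    if x < 1:
        raise ConfigurationError("harmonic index must be >= 1")
    return shift * 2.0 * base_spacing / (x * delta_t)


def select_harmonic(model: TissueThermalModel, transducer_center: float) -> HarmonicSelection:
    """Overtone of the fundamental nearest a transducer centre frequency.

    Ties at a half-integer ratio break toward the *lower* harmonic, which
    suffers less band-edge filtering by the transducer.
    """
    f1 = model.fundamental
    if not f1 > 0:
        raise ConfigurationError("fundamental must be positive")
    ratio = transducer_center / f1
    x = int(math.floor(ratio))
    if ratio - x > 0.5:
        x += 1
    x = max(x, 1)
    return HarmonicSelection(harmonic_index=x, expected_frequency=x * f1)
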
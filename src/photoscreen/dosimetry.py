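"""Light-dose arithmetic for the 96-LED irradiation array.

Fluence (light dose) is irradiance x exposure time.  The array irradiance is
established by ferrioxalate actinometry: the photo-reduction Fe(III) -> Fe(II)
proceeds with a known quantum yield, so the moles of Fe(II) formed per unit
time measure the photon flux, which the photon energy hc/lambda converts to a
power density.  A homogeneity check over the inner 60 wells (rows B-G,
columns 2-11 -- the only contiguous 60-well interior of a 96-well plate)
guards against edge fall-off of the LED field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import constants

from .plate_model import format_well

#: rows B-G x columns 2-11
INNER_60_WELLS = tuple(
    format_well(r, c) for r in range(1, 7) for c in range(1, 11)
)


@dataclass(frozen=True)
class IrradiationSchedule:
    """LED emission and exposure plan; doses derive from it."""

    wavelength_nominal: float  # nm
    bandwidth: float  # nm, +/- half width
    irradiance: float  # mW/cm^2
    step_durations: tuple[float, ...]  # seconds

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_durations", tuple(self.step_durations))
        if self.irradiance <= 0:
            raise ValueError("irradiance must be > 0")
        if not self.step_durations or any(d <= 0 for d in self.step_durations):
            raise ValueError("every step duration must be > 0")

    @property
    def n_steps(self) -> int:
        return len(self.step_durations)


#: The study's default: 468 nm (+/- 27.3 nm) LEDs at 20.6 mW/cm^2,
#: four 5-minute steps of 6.2 J/cm^2 each (24.7 J/cm^2 total).
DEFAULT_SCHEDULE = IrradiationSchedule(
    wavelength_nominal=468.0,
    bandwidth=27.3,
    irradiance=20.6,
    step_durations=(300.0,) * 4,
)


def cumulative_dose(schedule: IrradiationSchedule, through_step: int) -> float:
    """Cumulative fluence in J/cm^2 after ``through_step`` irradiation steps.

    Exact value; round only for display (:func:`format_dose`).
    """
    if not 0 <= through_step <= schedule.n_steps:
        raise ValueError(
            f"through_step {through_step} outside 0..{schedule.n_steps}"
        )
    seconds = sum(schedule.step_durations[:through_step])
    return schedule.irradiance / 1000.0 * seconds  # mW -> W


def cumulative_doses(schedule: IrradiationSchedule) -> np.ndarray:
    """Dose grid including the pre-irradiation zero point."""
    return np.array(
        [cumulative_dose(schedule, k) for k in range(schedule.n_steps + 1)]
    )


def format_dose(dose: float) -> float:
    """Display rounding to 0.1 J/cm^2 (the precision doses are reported at)."""
    return round(dose, 1)


@dataclass(frozen=True)
class ActinometerReading:
    """One ferrioxalate actinometry measurement in one well."""

    well: str
    moles_photoproduct: float  # mol Fe(II) formed
    exposure_time: float  # s
    illuminated_area: float  # cm^2
    quantum_yield: float = 0.9  # ferrioxalate Phi at the working wavelength

    def __post_init__(self) -> None:
        for name in (
            "moles_photoproduct",
            "exposure_time",
            "illuminated_area",
            "quantum_yield",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def irradiance_from_actinometry(
    reading: ActinometerReading, photon_wavelength: float
) -> float:
    """Irradiance in mW/cm^2 from a ferrioxalate reading.

    photon flux [mol/s] = n(Fe2+) / (Phi * t); each photon carries
    hc/lambda, so irradiance = flux * N_A * hc/lambda / area.
    """
    if not 300 <= photon_wavelength <= 700:
        raise ValueError("photon_wavelength outside 300-700 nm")
    flux_mol_s = reading.moles_photoproduct / (
        reading.quantum_yield * reading.exposure_time
    )
    photon_energy = constants.h * constants.c / (photon_wavelength * 1e-9)  # J
    watts = flux_mol_s * constants.Avogadro * photon_energy
    return watts / reading.illuminated_area * 1000.0  # W -> mW


@dataclass
class HomogeneityReport:
    mean: float
    cv: float
    passed: bool
    n: int = 60
    threshold: float = 0.10


def homogeneity_report(
    per_well_doses: dict[str, float], cv_threshold: float = 0.10
) -> HomogeneityReport:
    """Coefficient of variation of the dose over the inner 60 wells.

    Edge wells in the input are ignored with a warning; missing inner wells
    are an error (the check is only meaningful on the complete interior).
    """
    missing = [w for w in INNER_60_WELLS if w not in per_well_doses]
    if missing:
        raise ValueError(f"missing inner-well doses: {missing}")
    extra = sorted(set(per_well_doses) - set(INNER_60_WELLS))
    if extra:
        warnings.warn(f"ignoring {len(extra)} well(s) outside the inner 60: {extra}")
    doses = np.array([per_well_doses[w] for w in INNER_60_WELLS], dtype=float)
    mean = float(doses.mean())
    cv = float(doses.std(ddof=1) / mean) if mean != 0 else float("inf")
    return HomogeneityReport(
        mean=mean, cv=cv, passed=cv <= cv_threshold, threshold=cv_threshold
    )
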
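"""Synthetic microplate generator with known ground truth.

Real screening plates for this assay are not publicly deposited, so every
downstream stage is exercised against simulated plates whose generating
parameters are known exactly.  The generative model mirrors the structure
the analysis assumes:

* DMA photobleaching is pseudo-first-order in light dose H,
  ``OD377(H) = OD0 * exp(-k H)`` with
  ``k = kappa0 * effective_phi * (1 - 10^(-A_irr)) + solvent_bleach_rate``,
  i.e. the sensitized rate scales with the extract's absorbed fraction and
  its effective singlet-oxygen efficiency on top of the direct (solvent)
  photolysis of the probe.
* Ascorbate suppresses the sensitized rate multiplicatively by the spec's
  ``quenchable`` fraction; the direct photolysis term is untouched.
* Extract-only arms drift linearly by ``side_reaction_drift`` OD per full
  dose (zero for clean extracts).
* SRB dose-response data follow a 4PL with the spec's EC50/Hill parameters
  per arm, plus Gaussian noise truncated to the plausible viability range;
  an infinite EC50 produces a flat curve at ``top``.

Measurement noise is additive Gaussian on OD, independent across wells and
doses, and every dataset is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import EvidenceVector
from .dosimetry import DEFAULT_SCHEDULE, IrradiationSchedule, cumulative_doses
from .photocytotox import DoseResponseSeries, four_pl
from .plate_model import PlateDataset, PlateLayout, WellRole, all_wells


@dataclass(frozen=True)
class SensitizerSpec:
    """Ground-truth photochemistry of one simulated extract."""

    sample_id: str
    a_irr: float  # OD at 468 nm
    effective_phi: float  # relative 1O2 efficiency (reference PS = 1)
    quenchable: float = 0.9  # fraction of bleaching ascorbate suppresses
    side_reaction_drift: float = 0.0  # OD drift per full dose, extract arms
    a_probe_baseline: float = 0.05  # extract's own OD377, extract-only arms

    def __post_init__(self) -> None:
        if self.a_irr < 0 or self.effective_phi < 0:
            raise ValueError("a_irr and effective_phi must be >= 0")
        if not 0 <= self.quenchable <= 1:
            raise ValueError("quenchable must be in [0, 1]")


#: default reference photosensitizer (berberine-like: anchors 100%)
DEFAULT_REFERENCE = SensitizerSpec(
    sample_id="berberine", a_irr=0.5, effective_phi=1.0, quenchable=0.9
)


@dataclass(frozen=True)
class SimConfig:
    """Plate-level simulation conditions."""

    schedule: IrradiationSchedule = DEFAULT_SCHEDULE
    dma_od0: float = 1.0  # initial DMA OD at 377 nm
    kappa0: float = 0.005  # bleaching rate per (J/cm^2) at unit f_abs and phi
    noise_sd: float = 0.005  # OD, additive Gaussian
    replicates: int = 3
    seed: int = 0
    solvent_bleach_rate: float = 2e-4  # direct DMA photolysis, per J/cm^2
    blank_od: float = 0.04  # constant plate/solvent background

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("noise_sd >= 0 and replicates >= 1 required")


def _sensitized_rate(spec: SensitizerSpec, cfg: SimConfig) -> float:
    return cfg.kappa0 * spec.effective_phi * (1.0 - 10.0 ** (-spec.a_irr))


def simulate_dma_plate(
    specs: list[SensitizerSpec],
    cfg: SimConfig | None = None,
    reference: SensitizerSpec | None = None,
    n_blanks: int = 3,
) -> PlateDataset:
    """Build a complete, validated DMA plate for the given extracts.

    Each extract occupies four arms (probe, extract alone, and the two
    ascorbate controls) x replicates; the reference photosensitizer, solvent
    control and blank wells are added automatically.
    """
    cfg = cfg or SimConfig()
    reference = reference or DEFAULT_REFERENCE
    rng = np.random.default_rng(cfg.seed)
    doses = cumulative_doses(cfg.schedule)
    h_total = float(doses[-1])

    per_extract_arms = (
        "dma_probe",
        "extract_alone",
        "dma_plus_quencher",
        "extract_plus_quencher",
    )
    n_needed = (
        len(specs) * len(per_extract_arms) * cfg.replicates
        + 2 * cfg.replicates
        + n_blanks
    )
    if n_needed > 96:
        raise ValueError(
            f"{n_needed} wells needed but a plate holds 96: split across plates"
        )
    coords = iter(all_wells())

    wells: dict[str, WellRole] = {}
    rows: list[dict] = []

    def noise() -> float:
        return float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0

    def emit(well: str, wl: float, dose: float, od: float) -> None:
        rows.append(
            {
                "well": well,
                "wavelength_nm": wl,
                "cumulative_dose_J_cm2": float(dose),
                "od": od + cfg.blank_od + noise(),
            }
        )

    def dma_traj(rate: float) -> np.ndarray:
        return cfg.dma_od0 * np.exp(-rate * doses)

    def add_arm(spec: SensitizerSpec, arm: str, rep: int) -> None:
        well = next(coords)
        wells[well] = WellRole(sample_id=spec.sample_id, arm=arm, replicate=rep)
        k_s = _sensitized_rate(spec, cfg)
        if arm in ("dma_probe", "reference_ps"):
            for dose, od in zip(doses, dma_traj(k_s + cfg.solvent_bleach_rate)):
                emit(well, 377.0, dose, od)
            if arm == "reference_ps":
                for dose in doses:
                    emit(well, 468.0, dose, spec.a_irr)
        elif arm == "dma_plus_quencher":
            k = k_s * (1.0 - spec.quenchable) + cfg.solvent_bleach_rate
            for dose, od in zip(doses, dma_traj(k)):
                emit(well, 377.0, dose, od)
        elif arm in ("extract_alone", "extract_plus_quencher"):
            for dose in doses:
                drift = spec.side_reaction_drift * (dose / h_total)
                emit(well, 377.0, dose, spec.a_probe_baseline + drift)
                emit(well, 468.0, dose, spec.a_irr)
        else:  # pragma: no cover
            raise ValueError(arm)

    for spec in specs:
        for arm in per_extract_arms:
            for rep in range(1, cfg.replicates + 1):
                add_arm(spec, arm, rep)
    for rep in range(1, cfg.replicates + 1):
        add_arm(reference, "reference_ps", rep)
    solvent = SensitizerSpec("solvent", a_irr=0.0, effective_phi=0.0, quenchable=0.0)
    for rep in range(1, cfg.replicates + 1):
        well = next(coords)
        wells[well] = WellRole(sample_id="solvent", arm="solvent_control", replicate=rep)
        for dose, od in zip(doses, cfg.dma_od0 * np.exp(-cfg.solvent_bleach_rate * doses)):
            emit(well, 377.0, dose, od)
    for rep in range(1, n_blanks + 1):
        well = next(coords)
        wells[well] = WellRole(sample_id="blank", arm="blank", replicate=rep)
        for dose in doses:
            emit(well, 377.0, dose, 0.0)
            emit(well, 468.0, dose, 0.0)

    layout = PlateLayout(plate_id=f"sim-seed{cfg.seed}", wells=wells)
    return PlateDataset(layout=layout, records=pd.DataFrame(rows), schedule=cfg.schedule)


@dataclass(frozen=True)
class CytotoxSpec:
    """Ground-truth dose-response of one simulated extract (both arms)."""

    sample_id: str
    ec50_dark: float  # ug/mL; inf = inactive over any tested range
    ec50_irr: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    noise_sd_pct: float = 5.0
    cell_line: str = "A549"

    def __post_init__(self) -> None:
        if self.ec50_dark <= 0 or self.ec50_irr <= 0:
            raise ValueError("EC50 values must be > 0 (use inf for inactive)")


def simulate_dose_response(
    spec: CytotoxSpec,
    concentrations,
    replicates: int = 3,
    seed: int = 0,
) -> dict[str, DoseResponseSeries]:
    """Simulate dark and irradiated SRB series for one extract.

    Returns ``{"dark": ..., "irradiated": ...}``.
    """
    conc = np.asarray(sorted(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    rng = np.random.default_rng(seed)
    out: dict[str, DoseResponseSeries] = {}
    for arm, ec50 in (("dark", spec.ec50_dark), ("irradiated", spec.ec50_irr)):
        if math.isinf(ec50):
            mean = np.full_like(conc, spec.top)
        else:
            mean = four_pl(conc, spec.top, spec.bottom, ec50, spec.hill)
        viab = [
            np.clip(m + rng.normal(0.0, spec.noise_sd_pct, replicates), -20.0, 150.0)
            for m in mean
        ]
        out[arm] = DoseResponseSeries(
            sample_id=spec.sample_id,
            cell_line=spec.cell_line,
            arm=arm,
            concentrations=conc,
            viability=viab,
        )
    return out


def dose_response_to_frame(series: list[DoseResponseSeries]) -> pd.DataFrame:
    """Long-format dose-response table (the CSV interchange format)."""
    rows = []
    for s in series:
        for conc, reps in zip(s.concentrations, s.viability):
            for i, v in enumerate(reps, start=1):
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "cell_line": s.cell_line,
                        "arm": s.arm,
                        "concentration_ug_per_ml": conc,
                        "replicate": i,
                        "viability_pct": float(v),
                    }
                )
    return pd.DataFrame(rows)


def study_fixture() -> dict[str, tuple[EvidenceVector, str | None]]:
    """Qualitative evidence table for the study's extracts, with the printed
    case assignments where the original report states one (else ``None``).

    Relative DMA yields (% of berberine): C. croceus AC/PE 205, MeOH 82;
    I. obliquus 28-30; T. atrotomentosa MeOH/AC 6; R. subterranea 73;
    M. brunneum 124; B. brongniartii none.
    """

    def ev(sid, dma, uv, ct, pct, si=None, bound=False):
        return EvidenceVector(
            sample_id=sid,
            dma_positive=dma,
            quench_confirmed=dma,  # all positives were quench-confirmed
            uv_vis_change=uv,
            ct_positive=ct,
            pct_positive=pct,
            si=si,
            si_is_bound=bound,
        )

    return {
        "C. croceus MeOH": (
            ev("C. croceus MeOH", True, True, False, True),
            "case5_pdt_candidate",
        ),
        "C. croceus AC": (
            ev("C. croceus AC", True, True, False, True, si=50.0, bound=True),
            None,  # selectivity > 50, dark-inactive; no printed case label
        ),
        "C. croceus PE": (
            ev("C. croceus PE", True, True, True, True),
            "case3_broad_toxic",
        ),
        "T. atrotomentosa": (
            ev("T. atrotomentosa", True, False, True, False),
            None,  # minimal 1O2; weak light-independent cytotoxicity (PE)
        ),
        "I. obliquus": (
            ev("I. obliquus", True, True, False, False),
            None,
        ),
        "R. subterranea": (
            ev("R. subterranea", True, True, False, True),
            None,
        ),
        "M. brunneum": (
            ev("M. brunneum", True, True, False, False),
            "case4_apdi_candidate",
        ),
        "B. brongniartii": (
            ev("B. brongniartii", False, True, False, True),
            "case2_photochemical",
        ),
    }
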
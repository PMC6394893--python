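"""Relative singlet-oxygen quantification from DMA photobleaching.

9,10-dimethylanthracene (DMA) is a selective singlet-oxygen probe: the
[4+2] oxidation to the endoperoxide destroys its 377 nm absorption band, so
the drop in OD at 377 nm over an irradiation series (dOD377) reports how
much 1O2 a photosensitizer produced.  Because extracts absorb different
fractions of the incident light, the raw dOD is corrected by the probability
of absorption f_abs(A) = 1 - 10^(-A) at the irradiation wavelength, and
expressed relative to a reference photosensitizer (here berberine, set to
100%):

    yield% = 100 * (dOD_s / dOD_ref) * (f_abs(A_ref) / f_abs(A_s))

Two controls police the call: co-incubation with ascorbic acid must suppress
the bleaching (otherwise the signal is not 1O2-mediated and the extract is a
candidate false positive), and an extract + ascorbate arm without DMA must
stay flat (otherwise some side reaction is drifting the baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import PlateDataset, aggregate_replicates

MODES = ("endpoint", "slope", "kinetic")


@dataclass(frozen=True)
class DMAConfig:
    """Tunables of the DMA scoring stage.

    mode
        ``endpoint`` (default): dOD = OD(0) - OD(final dose), the study's
        estimator.  ``slope``: -least-squares slope x final dose, more robust
        to single-read noise.  ``kinetic``: log-linear bleaching-rate fit;
        rate-proportional signal, exact on first-order kinetics.
    positivity_pct
        Minimum relative yield (% of reference) to call an extract DMA+.
    quench_ratio_max
        Maximum (dOD with ascorbate)/(dOD without) for the 1O2 mechanism to
        count as confirmed.
    side_reaction_od
        Maximum tolerated |OD377 drift| of the extract+ascorbate arm.
    noise_floor_od
        dOD magnitudes below this are treated as zero signal.
    """

    mode: str = "endpoint"
    positivity_pct: float = 5.0
    quench_ratio_max: float = 0.5
    side_reaction_od: float = 0.02
    noise_floor_od: float = 0.01
    wavelength_probe: float = 377.0
    wavelength_irr: float = 468.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class DMATrajectory:
    """Replicate-aggregated OD377 time course of one arm of one sample."""

    sample_id: str
    doses: np.ndarray  # J/cm^2, strictly increasing from 0
    od377: np.ndarray
    od377_se: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.od377 = np.asarray(self.od377, dtype=float)
        self.od377_se = np.asarray(self.od377_se, dtype=float)
        if len(self.doses) < 2:
            raise ValueError("trajectory needs at least 2 dose points")
        if not (len(self.doses) == len(self.od377) == len(self.od377_se)):
            raise ValueError("doses/od/se length mismatch")
        if self.doses[0] != 0 or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing starting at 0")


@dataclass(frozen=True)
class ReferencePS:
    """The positive-control photosensitizer anchoring 100%."""

    name: str
    a_irr: float  # OD at the irradiation wavelength
    delta_od377: float  # bleaching signal at the final dose
    nominal_phi: float | None = None  # literature 1O2 quantum yield, metadata

    def __post_init__(self) -> None:
        if self.delta_od377 <= 0:
            raise ValueError(
                "reference PS bleaches no DMA (delta_od377 <= 0): invalid anchor"
            )


@dataclass
class DMAResult:
    sample_id: str
    delta_od377: float
    a_irr: float
    absorbed_fraction: float
    relative_yield_pct: float
    relative_yield_se: float
    quench_ratio: float
    quench_confirmed: bool
    side_reaction_flag: bool
    dma_positive: bool


def absorbed_fraction(a_irr: float, noise_floor: float = 0.01) -> float:
    """Probability of absorption 1 - 10^(-A) at the irradiation wavelength."""
    if a_irr < -noise_floor:
        raise ValueError(f"absorbance {a_irr} below the noise floor: invalid")
    a = max(a_irr, 0.0)
    return 1.0 - 10.0 ** (-a)


def delta_od(
    traj: DMATrajectory, mode: str = "endpoint"
) -> tuple[float, float]:
    """Bleaching signal (OD units) and its standard error for one trajectory.

    All three modes coincide for data that are linear in dose; they differ in
    how they average noise and curvature.
    """
    h, y, se = traj.doses, traj.od377, traj.od377_se
    if mode == "endpoint":
        return float(y[0] - y[-1]), float(math.hypot(se[0], se[-1]))
    if mode == "slope":
        slope, _ = np.polyfit(h, y, 1)
        xc = h - h.mean()
        w = xc / float(xc @ xc)  # slope = w . y
        var = float((w**2) @ (se**2))
        return float(-slope * h[-1]), float(math.sqrt(var) * h[-1])
    if mode == "kinetic":
        # first-order bleaching OD(H) = OD0 exp(-kH): log-linear rate fit;
        # signal = OD0 * k * H_final is exactly proportional to the rate.
        if np.any(y <= 0):
            raise ValueError("kinetic mode requires strictly positive ODs")
        k = -np.polyfit(h, np.log(y), 1)[0]
        xc = h - h.mean()
        w = xc / float(xc @ xc)
        var = float((w**2) @ ((se / y) ** 2))  # delta method on log
        return float(y[0] * k * h[-1]), float(y[0] * math.sqrt(var) * h[-1])
    raise ValueError(f"unknown mode {mode!r}")


def relative_yield(
    delta_od_sample: float,
    a_irr_sample: float,
    reference: ReferencePS,
    noise_floor: float = 0.01,
) -> float:
    """Relative 1O2 yield in % of the reference photosensitizer."""
    f_ref = absorbed_fraction(reference.a_irr, noise_floor)
    if f_ref <= 0:
        raise ValueError("reference PS absorbs no light at the irradiation band")
    if a_irr_sample <= noise_floor and abs(a_irr_sample) <= noise_floor:
        # transparent sample: no photons absorbed, no sensitized signal
        if delta_od_sample <= noise_floor:
            return 0.0
        raise ValueError(
            "inconsistent data: DMA bleaching without measurable absorption "
            "at the irradiation wavelength"
        )
    f_s = absorbed_fraction(a_irr_sample, noise_floor)
    return 100.0 * (delta_od_sample / reference.delta_od377) * (f_ref / f_s)


def validate_controls(
    without_q: float,
    with_q: float,
    extract_plus_q_drift: float,
    quench_ratio_max: float = 0.5,
    side_reaction_od: float = 0.02,
    noise_floor: float = 0.01,
) -> tuple[float, bool, bool]:
    """Evaluate the ascorbate-quench and side-reaction controls.

    Returns ``(quench_ratio, quench_confirmed, side_reaction_flag)``.  With
    no measurable bleaching the ratio is defined as 1 (nothing to quench, so
    nothing is confirmed).
    """
    if without_q <= noise_floor:
        ratio = 1.0
    else:
        ratio = max(with_q, 0.0) / without_q
    quench_confirmed = ratio <= quench_ratio_max and without_q > noise_floor
    side_flag = abs(extract_plus_q_drift) > side_reaction_od
    return float(ratio), bool(quench_confirmed), bool(side_flag)


def extract_trajectory(
    ds: PlateDataset, sample_id: str, arm: str, wavelength: float = 377.0
) -> DMATrajectory:
    """Replicate-aggregated trajectory of one (sample, arm) across wells."""
    wells = ds.layout.wells_for(sample_id, arm)
    if not wells:
        raise ValueError(f"sample {sample_id!r}: missing arm {arm!r}")
    sub = ds.records[
        ds.records["well"].isin(wells)
        & (ds.records["wavelength_nm"] == wavelength)
    ]
    if sub.empty:
        raise ValueError(
            f"sample {sample_id!r}, arm {arm!r}: no readings at {wavelength} nm"
        )
    doses, means, ses = [], [], []
    for dose, grp in sub.groupby("cumulative_dose_J_cm2"):
        m, se, _ = aggregate_replicates(grp["od"].to_numpy())
        doses.append(float(dose))
        means.append(m)
        ses.append(se)
    return DMATrajectory(sample_id, np.array(doses), np.array(means), np.array(ses))


def _absorbance_at_irr(
    ds: PlateDataset, sample_id: str, arm: str, cfg: DMAConfig
) -> tuple[float, float]:
    wells = ds.layout.wells_for(sample_id, arm)
    sub = ds.records[
        ds.records["well"].isin(wells)
        & (ds.records["wavelength_nm"] == cfg.wavelength_irr)
        & (ds.records["cumulative_dose_J_cm2"] == 0)
    ]
    if sub.empty:
        raise ValueError(
            f"sample {sample_id!r}: no {cfg.wavelength_irr} nm reading at dose 0 "
            f"in arm {arm!r}"
        )
    m, se, _ = aggregate_replicates(sub["od"].to_numpy())
    return m, se


def score_extract(
    ds: PlateDataset,
    sample_id: str,
    config: DMAConfig | None = None,
    reference_id: str | None = None,
) -> DMAResult:
    """Assemble the full DMA verdict for one extract on one plate.

    Requires the four per-extract arms (probe, extract alone, both ascorbate
    arms) plus the plate's solvent control and reference photosensitizer.
    The solvent-control bleaching (direct DMA photolysis) is subtracted from
    the sample, quencher and reference signals before the relative yield is
    formed, so an extract indistinguishable from solvent scores 0%.
    """
    cfg = config or DMAConfig()
    ds.layout.require_dma_controls()

    solvent_id = ds.layout.wells[ds.layout.wells_by_arm("solvent_control")[0]].sample_id
    if reference_id is None:
        reference_id = ds.layout.wells[ds.layout.wells_by_arm("reference_ps")[0]].sample_id

    traj_probe = extract_trajectory(ds, sample_id, "dma_probe", cfg.wavelength_probe)
    traj_quench = extract_trajectory(
        ds, sample_id, "dma_plus_quencher", cfg.wavelength_probe
    )
    traj_solvent = extract_trajectory(
        ds, solvent_id, "solvent_control", cfg.wavelength_probe
    )
    traj_ref = extract_trajectory(ds, reference_id, "reference_ps", cfg.wavelength_probe)

    sig_s, se_s = delta_od(traj_probe, cfg.mode)
    sig_q, _ = delta_od(traj_quench, cfg.mode)
    sig_solv, se_solv = delta_od(traj_solvent, cfg.mode)
    sig_r, se_r = delta_od(traj_ref, cfg.mode)

    d_s = sig_s - sig_solv
    d_q = sig_q - sig_solv
    d_r = sig_r - sig_solv
    se_ds = math.hypot(se_s, se_solv)
    se_dr = math.hypot(se_r, se_solv)
    if d_r <= 0:
        raise ValueError(
            f"reference PS {reference_id!r} shows no bleaching beyond solvent: "
            "plate cannot anchor 100%"
        )

    a_irr, _ = _absorbance_at_irr(ds, sample_id, "extract_alone", cfg)
    a_ref, _ = _absorbance_at_irr(ds, reference_id, "reference_ps", cfg)
    reference = ReferencePS(name=reference_id, a_irr=a_ref, delta_od377=d_r)

    d_s_eff = max(d_s, 0.0)
    yield_pct = relative_yield(d_s_eff, a_irr, reference, cfg.noise_floor_od)
    # first-order (delta-method) propagation on the dOD ratio; the absorbance
    # terms enter log-multiplicatively and contribute little at triplicate SEs
    if yield_pct > 0 and d_s_eff > 0:
        rel_var = (se_ds / d_s_eff) ** 2 + (se_dr / d_r) ** 2
        yield_se = yield_pct * math.sqrt(rel_var)
    else:
        yield_se = 100.0 * se_ds / d_r if d_r > 0 else 0.0

    traj_side = extract_trajectory(
        ds, sample_id, "extract_plus_quencher", cfg.wavelength_probe
    )
    drift = float(np.max(np.abs(traj_side.od377 - traj_side.od377[0])))

    ratio, confirmed, side_flag = validate_controls(
        d_s_eff,
        d_q,
        drift,
        cfg.quench_ratio_max,
        cfg.side_reaction_od,
        cfg.noise_floor_od,
    )
    positive = yield_pct >= cfg.positivity_pct and confirmed

    return DMAResult(
        sample_id=sample_id,
        delta_od377=d_s,
        a_irr=a_irr,
        absorbed_fraction=absorbed_fraction(a_irr, cfg.noise_floor_od),
        relative_yield_pct=yield_pct,
        relative_yield_se=yield_se,
        quench_ratio=ratio,
        quench_confirmed=confirmed,
        side_reaction_flag=side_flag,
        dma_positive=positive,
    )


def score_plate(
    ds: PlateDataset, config: DMAConfig | None = None
) -> list[DMAResult]:
    """Score every extract that has a dma_probe arm on the plate."""
    return [score_extract(ds, sid, config) for sid in ds.layout.sample_ids("dma_probe")]


def results_to_frame(results: list[DMAResult]) -> pd.DataFrame:
    """Per-extract results in the documented CSV column order."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "delta_od377": r.delta_od377,
                "a_468": r.a_irr,
                "absorbed_fraction": r.absorbed_fraction,
                "relative_yield_pct": r.relative_yield_pct,
                "relative_yield_se": r.relative_yield_se,
                "quench_ratio": r.quench_ratio,
                "quench_confirmed": r.quench_confirmed,
                "side_reaction": r.side_reaction_flag,
                "dma_positive": r.dma_positive,
            }
            for r in results
        ]
    )
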
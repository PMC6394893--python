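"""End-to-end screening workflow: dosimetry checks -> DMA scoring ->
photo-cytotoxicity -> classification -> ranked report.

The three sub-assays are independent; the conclusion is drawn from their
combined evidence.  Runs with only DMA inputs are allowed — extracts are
then reported with an explicit "incomplete: cytotoxicity pending" status
instead of a forced classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import EvidenceVector, classify, rank_extracts, uv_vis_change
from .dma_assay import DMAConfig, results_to_frame as dma_frame, score_plate
from .dosimetry import IrradiationSchedule
from .photocytotox import (
    DoseResponseResult,
    SelectivityResult,
    fit_4pl,
    read_dose_response,
    results_to_frame as cytotox_frame,
    selectivity,
)
from .plate_model import PlateDataset, blank_correct, read_plate

log = logging.getLogger("photoscreen")

#: caveat printed at the top of every report: the relative-yield expression
#: is the standard reference-comparison form with the absorption-probability
#: correction; see docs/methods.md for the assumption it encodes.
YIELD_FORMULA_NOTE = (
    "relative 1O2 yields computed as "
    "100 * (dOD_s/dOD_ref) * (f_abs,ref/f_abs,s), f_abs = 1 - 10^(-A); "
    "the standard reference-comparison form (see methods documentation)."
)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one screening run (flat, serializable)."""

    layout_path: str = ""
    readings_path: str = ""
    dose_response_path: str = ""  # optional
    output_dir: str = "screen_out"
    seed: int = 0
    log_level: str = "INFO"
    # irradiation schedule
    wavelength_nm: float = 468.0
    bandwidth_nm: float = 27.3
    irradiance_mw_cm2: float = 20.6
    step_seconds: list[float] = field(default_factory=lambda: [300.0] * 4)
    # dma thresholds
    dma_mode: str = "endpoint"
    dma_positivity_pct: float = 5.0
    dma_quench_ratio_max: float = 0.5
    dma_side_reaction_od: float = 0.02
    dma_noise_floor_od: float = 0.01
    # cytotox thresholds
    cytotox_n_boot: int = 1000
    cytotox_activity_cap: float = 50.0
    cytotox_min_effect: float = 25.0
    si_threshold: float = 2.0
    # classifier
    uv_tolerance_od: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.dma_quench_ratio_max <= 1:
            raise ValueError("dma_quench_ratio_max must be in (0, 1]")
        if self.dma_positivity_pct < 0 or self.cytotox_activity_cap <= 0:
            raise ValueError("thresholds out of range")
        if self.cytotox_n_boot < 0 or self.uv_tolerance_od < 0:
            raise ValueError("thresholds out of range")

    @property
    def schedule(self) -> IrradiationSchedule:
        return IrradiationSchedule(
            wavelength_nominal=self.wavelength_nm,
            bandwidth=self.bandwidth_nm,
            irradiance=self.irradiance_mw_cm2,
            step_durations=tuple(self.step_seconds),
        )

    @property
    def dma_config(self) -> DMAConfig:
        return DMAConfig(
            mode=self.dma_mode,
            positivity_pct=self.dma_positivity_pct,
            quench_ratio_max=self.dma_quench_ratio_max,
            side_reaction_od=self.dma_side_reaction_od,
            noise_floor_od=self.dma_noise_floor_od,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class ScreenReport:
    dma_results: pd.DataFrame
    cytotox_results: pd.DataFrame | None
    ranking: pd.DataFrame
    output_dir: Path
    incomplete: bool


def _uv_evidence(ds: PlateDataset, sample_id: str, tol: float) -> bool:
    """Spectral-evolution evidence from the extract-alone arm: compare the
    mean spectrum at dose 0 with the one at the final dose."""
    wells = ds.layout.wells_for(sample_id, "extract_alone")
    sub = ds.records[ds.records["well"].isin(wells)]
    if sub.empty:
        return False
    spectra = []
    for dose in (sub["cumulative_dose_J_cm2"].min(), sub["cumulative_dose_J_cm2"].max()):
        s = (
            sub[sub["cumulative_dose_J_cm2"] == dose]
            .groupby("wavelength_nm")["od"]
            .mean()
        )
        spectra.append((s.index.to_numpy(float), s.to_numpy(float)))
    try:
        return uv_vis_change(spectra, tolerance=tol)
    except ValueError:
        return False


def run_screen(cfg: PipelineConfig) -> ScreenReport:
    """Run the full screen and write per-stage CSVs plus the ranked report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("photoscreen %s | seed=%d | %s", __version__, cfg.seed, YIELD_FORMULA_NOTE)

    # ---- stage 1: plate I/O + blank correction + DMA scoring -------------
    try:
        ds = read_plate(cfg.layout_path, cfg.readings_path, schedule=cfg.schedule)
        ds = blank_correct(ds)
        dma_results = score_plate(ds, cfg.dma_config)
    except Exception as exc:
        raise RuntimeError(f"DMA stage failed: {exc}") from exc
    dma_df = dma_frame(dma_results)
    dma_df.to_csv(out / "dma_results.csv", index=False)

    # ---- stage 2: photo-cytotoxicity (optional) --------------------------
    fits: list[DoseResponseResult] = []
    sels: list[SelectivityResult] = []
    cytotox_df = None
    have_cytotox = bool(cfg.dose_response_path)
    if have_cytotox:
        try:
            series = read_dose_response(cfg.dose_response_path)
            by_key: dict[tuple[str, str], dict[str, DoseResponseResult]] = {}
            for s in series:
                r = fit_4pl(
                    s,
                    n_boot=cfg.cytotox_n_boot,
                    seed=cfg.seed,
                    activity_cap=cfg.cytotox_activity_cap,
                    min_effect=cfg.cytotox_min_effect,
                )
                fits.append(r)
                by_key.setdefault((s.sample_id, s.cell_line), {})[s.arm] = r
            for (sid, line), arms in by_key.items():
                if "dark" in arms and "irradiated" in arms:
                    sels.append(
                        selectivity(arms["dark"], arms["irradiated"], cfg.si_threshold)
                    )
        except Exception as exc:
            raise RuntimeError(f"cytotoxicity stage failed: {exc}") from exc
        cytotox_df = cytotox_frame(fits, sels)
        cytotox_df.to_csv(out / "cytotox_results.csv", index=False)

    # ---- stage 3: evidence assembly + classification ---------------------
    active_by_arm: dict[tuple[str, str], bool] = {
        (r.sample_id, r.arm): r.active for r in fits
    }
    si_map: dict[str, tuple[float, bool]] = {
        s.sample_id: (s.si, s.si_censored) for s in sels if s.defined
    }
    calls = []
    yields = {}
    for r in dma_results:
        uv = _uv_evidence(ds, r.sample_id, cfg.uv_tolerance_od)
        ev = EvidenceVector(
            sample_id=r.sample_id,
            dma_positive=r.dma_positive,
            quench_confirmed=r.quench_confirmed,
            uv_vis_change=uv,
            ct_positive=active_by_arm.get((r.sample_id, "dark"), False),
            pct_positive=active_by_arm.get((r.sample_id, "irradiated"), False),
            si=si_map.get(r.sample_id, (None, False))[0],
            si_is_bound=si_map.get(r.sample_id, (None, False))[1],
        )
        calls.append(classify(ev))
        yields[r.sample_id] = r.relative_yield_pct

    ranking = rank_extracts(calls, dma_yields=yields, si=si_map)
    if not have_cytotox:
        ranking["status"] = "incomplete: cytotoxicity pending"
    else:
        ranking["status"] = "complete"
    ranking.to_csv(out / "ranked_report.csv", index=False)

    # ---- human-readable summary + run log --------------------------------
    lines = [
        "# Phototoxicity screen report",
        "",
        f"Note: {YIELD_FORMULA_NOTE}",
        "",
        ranking.to_string(index=False),
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
    (out / "run_log.json").write_text(
        json.dumps(
            {"version": __version__, "seed": cfg.seed, "config": asdict(cfg)},
            indent=2,
            default=str,
        )
    )
    return ScreenReport(
        dma_results=dma_df,
        cytotox_results=cytotox_df,
        ranking=ranking,
        output_dir=out,
        incomplete=not have_cytotox,
    )
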
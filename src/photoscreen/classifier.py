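"""Interpretation engine: map assay evidence to screening outcomes.

The screen produces, per extract, a small evidence vector — singlet-oxygen
production (DMA, quench-confirmed), a UV-Vis spectral change under
irradiation, dark cytotoxicity (CT) and photo-cytotoxicity (PCT) below the
activity cap — which this module folds into one of five interpretation
cases plus two honest fall-through outcomes:

case1  no 1O2, no toxicity, but the spectra evolve: putative sun-protecting
       (or photolabile, biologically silent) extract
case2  no 1O2 yet photo-cytotoxic: a non-1O2 photochemical mechanism;
       candidate for hypoxic-tumour (oxygen-independent) photosensitizers
case3  active on every level: potent but at risk of systemic toxicity
case4  1O2 producer without photo-cytotoxicity: candidate for antimicrobial
       photodynamic inhibition (aPDI) if it crosses microbial envelopes
case5  1O2 producer, toxic only under light: the PDT lead profile
dark_cytotoxic_only  dark toxicity without photo-enhancement
inactive             nothing observed
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CASES = (
    "case1_sun_protect_or_inert",
    "case2_photochemical",
    "case3_broad_toxic",
    "case4_apdi_candidate",
    "case5_pdt_candidate",
    "dark_cytotoxic_only",
    "inactive",
)

#: ranking priority, most to least interesting for PDT lead discovery
DEFAULT_CASE_PRIORITY = (
    "case5_pdt_candidate",
    "case2_photochemical",
    "case4_apdi_candidate",
    "case3_broad_toxic",
    "case1_sun_protect_or_inert",
    "dark_cytotoxic_only",
    "inactive",
)


@dataclass(frozen=True)
class EvidenceVector:
    """Boolean evidence for one extract, plus optional selectivity metadata."""

    sample_id: str
    dma_positive: bool
    quench_confirmed: bool
    uv_vis_change: bool
    ct_positive: bool  # dark-active below the activity cap
    pct_positive: bool  # light-active below the activity cap
    si: Optional[float] = None
    si_is_bound: bool = False


@dataclass(frozen=True)
class PhotoactivityCall:
    sample_id: str
    case: str
    rationale: str
    rank_score: float = 0.0


def classify(ev: EvidenceVector) -> PhotoactivityCall:
    """Assign exactly one outcome to an evidence vector (total function).

    A DMA+ signal whose ascorbate quench was not confirmed is demoted to
    DMA- with a Type I / artifact note, since an unquenched bleaching signal
    does not establish singlet oxygen.
    """
    dma = ev.dma_positive and ev.quench_confirmed
    note = ""
    if ev.dma_positive and not ev.quench_confirmed:
        note = (
            " (DMA signal demoted: ascorbate quench unconfirmed, possible "
            "Type I mechanism or assay artifact)"
        )

    if dma:
        if ev.ct_positive and ev.pct_positive:
            case, why = "case3_broad_toxic", (
                "1O2 producer, active in the dark and under light: potent but "
                "possibly too broadly toxic; deconvolute the extract"
            )
        elif not ev.ct_positive and ev.pct_positive:
            case, why = "case5_pdt_candidate", (
                "1O2 producer, cytotoxic solely under irradiation: PDT lead profile"
            )
        elif not ev.ct_positive and not ev.pct_positive:
            case, why = "case4_apdi_candidate", (
                "1O2 producer without (photo-)cytotoxicity in mammalian cells: "
                "candidate for antimicrobial photodynamic inhibition"
            )
        else:  # ct+ pct-
            case, why = "dark_cytotoxic_only", (
                "1O2 producer, yet toxicity is dark-only: no photo-enhancement "
                "reached the cells"
            )
    else:
        if ev.pct_positive:
            case, why = "case2_photochemical", (
                "photo-cytotoxic without 1O2: a non-1O2 photochemical mechanism; "
                "candidate for oxygen-independent (hypoxic-tumour) photosensitizers"
            )
        elif ev.ct_positive:
            case, why = "dark_cytotoxic_only", (
                "dark cytotoxicity without any photoactivity"
            )
        elif ev.uv_vis_change:
            case, why = "case1_sun_protect_or_inert", (
                "spectra evolve under irradiation without any toxicity: putative "
                "sun-protecting or photolabile, biologically silent extract"
            )
        else:
            case, why = "inactive", "no 1O2, no spectral change, no toxicity"
    return PhotoactivityCall(sample_id=ev.sample_id, case=case, rationale=why + note)


def uv_vis_change(
    spectra: Sequence[tuple[np.ndarray, np.ndarray]], tolerance: float = 0.05
) -> bool:
    """True iff the spectrum moved anywhere by more than ``tolerance`` OD.

    ``spectra`` is a dose-ordered sequence of ``(wavelengths, od)`` pairs;
    the first and last are compared on the overlap of their wavelength grids
    (linear interpolation where the grids differ).
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to assess spectral evolution")
    wl0, a0 = (np.asarray(x, float) for x in spectra[0])
    wlf, af = (np.asarray(x, float) for x in spectra[-1])
    lo, hi = max(wl0.min(), wlf.min()), min(wl0.max(), wlf.max())
    if lo > hi:
        raise ValueError("spectra share no wavelength overlap")
    grid = np.union1d(wl0, wlf)
    grid = grid[(grid >= lo) & (grid <= hi)]
    d = np.interp(grid, wlf, af) - np.interp(grid, wl0, a0)
    return bool(np.max(np.abs(d)) > tolerance)


def _si_key(ev_si: Optional[float], is_bound: bool) -> tuple[float, int]:
    if ev_si is None or not np.isfinite(ev_si):
        return (-np.inf, 0)
    # a bound "> x" sorts above the exact value x among equals
    return (float(ev_si), 1 if is_bound else 0)


def rank_extracts(
    calls: Sequence[PhotoactivityCall],
    dma_yields: Mapping[str, float] | None = None,
    si: Mapping[str, tuple[float, bool]] | None = None,
    case_priority: Sequence[str] = DEFAULT_CASE_PRIORITY,
) -> pd.DataFrame:
    """Rank extracts by case priority, then selectivity index, then DMA yield.

    Returns a DataFrame with columns
    ``sample_id, case, rank, si, relative_yield_pct, rationale``.
    """
    if not calls:
        raise ValueError("rank_extracts: empty call list")
    dma_yields = dma_yields or {}
    si = si or {}
    prio = {c: i for i, c in enumerate(case_priority)}

    def key(call: PhotoactivityCall):
        s = si.get(call.sample_id)
        si_k = _si_key(*s) if s else (-np.inf, 0)
        y = dma_yields.get(call.sample_id, -np.inf)
        return (prio.get(call.case, len(prio)), tuple(-x for x in si_k), -y)

    ordered = sorted(calls, key=key)
    rows = []
    for rank, call in enumerate(ordered, start=1):
        s = si.get(call.sample_id)
        rows.append(
            {
                "sample_id": call.sample_id,
                "case": call.case,
                "rank": rank,
                "si": (f"> {s[0]:.3g}" if s[1] else f"{s[0]:.3g}") if s else "",
                "relative_yield_pct": dma_yields.get(call.sample_id, np.nan),
                "rationale": call.rationale,
            }
        )
    return pd.DataFrame(rows)
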
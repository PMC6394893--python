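"""SRB photo-cytotoxicity analysis: 4PL dose-response fits, EC50 confidence
intervals, activity calls and the selectivity index.

Viability is measured with the sulforhodamine-B (SRB) protein stain, run in a
dark arm and an irradiated arm for each extract.  Each arm is fitted with a
four-parameter logistic

    v(c) = bottom + (top - bottom) / (1 + (c / EC50)^h)

on log-concentration, with a case-resampling bootstrap over replicates for
the 95% EC50 confidence interval.  Curves that stay flat or whose EC50 falls
beyond the tested range are censored ("EC50 > max tested") rather than
reported as a point value.  Photo-enhancement is summarized by the
selectivity index

    S.I. = EC50,dark / EC50,irradiated

with censoring propagated as a lower bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import t as t_dist

DEFAULT_ACTIVITY_CAP = 50.0  # ug/mL; "not active below 50 ug/mL" convention
DEFAULT_MIN_EFFECT = 25.0  # percentage points of top - bottom to call a curve
TOP_BOUNDS = (80.0, 120.0)
BOTTOM_BOUNDS = (-10.0, 40.0)


def four_pl(c, top, bottom, ec50, hill):
    """Four-parameter logistic viability curve (decreasing for hill > 0)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ec50) ** hill)


def normalize_srb(
    raw_od: Sequence[float],
    untreated_controls: Sequence[float],
    blanks: Sequence[float],
) -> np.ndarray:
    """Viability in % of untreated controls from raw SRB ODs."""
    raw = np.asarray(raw_od, dtype=float)
    u = float(np.mean(untreated_controls))
    b = float(np.mean(blanks))
    if u <= b:
        raise ValueError(
            "assay failure: untreated-control OD does not exceed blank OD"
        )
    return 100.0 * (raw - b) / (u - b)


@dataclass
class DoseResponseSeries:
    """Replicated viability measurements over a concentration series.

    ``viability`` holds one array of replicate values per concentration level
    (ragged allowed).  Aggregated means/SEs are derived views.
    """

    sample_id: str
    cell_line: str
    arm: str  # dark | irradiated
    concentrations: np.ndarray  # strictly increasing, ug/mL
    viability: list[np.ndarray]  # % of untreated control, per level
    flagged_subzero: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = [np.atleast_1d(np.asarray(v, float)) for v in self.viability]
        if self.arm not in ("dark", "irradiated"):
            raise ValueError("arm must be 'dark' or 'irradiated'")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if len(self.viability) != len(self.concentrations):
            raise ValueError("one replicate array per concentration required")
        allv = np.concatenate(self.viability)
        if np.any(allv < -20) or np.any(allv > 150):
            raise ValueError("viability outside the plausible [-20, 150]% range")
        self.flagged_subzero = bool(np.any(allv < 0))

    @property
    def viability_pct(self) -> np.ndarray:
        return np.array([v.mean() for v in self.viability])

    @property
    def viability_se(self) -> np.ndarray:
        return np.array(
            [v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0
             for v in self.viability]
        )

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.concatenate(
            [np.full(len(v), conc) for conc, v in zip(self.concentrations, self.viability)]
        )
        return c, np.concatenate(self.viability)


@dataclass
class DoseResponseResult:
    sample_id: str
    cell_line: str
    arm: str
    ec50: float  # nan when censored
    ec50_ci: tuple[float, float] | None
    hill: float
    top: float
    bottom: float
    censored: bool
    censor_bound: float  # max tested concentration
    active: bool
    fit_ok: bool
    message: str = ""

    @property
    def ec50_display(self) -> str:
        if not self.fit_ok:
            return "fit failed"
        if self.censored:
            return f"> {self.censor_bound:g}"
        return f"{self.ec50:.3g}"


class FourParamLogistic:
    """Least-squares 4PL fitter with multistart and bounded asymptotes.

    Fit-style interface: ``fit(concentrations, viability)`` estimates
    ``top_``, ``bottom_``, ``ec50_`` and ``hill_``; ``predict`` evaluates the
    fitted curve.  EC50 is parameterized on log10 concentration; the start
    grid spans the minimum, geometric mean and maximum of the tested range.
    """

    def __init__(
        self,
        top_bounds: tuple[float, float] = TOP_BOUNDS,
        bottom_bounds: tuple[float, float] = BOTTOM_BOUNDS,
        hill_bounds: tuple[float, float] = (1e-3, 50.0),
        ec50_log_margin: float = 2.0,
    ) -> None:
        self.top_bounds = top_bounds
        self.bottom_bounds = bottom_bounds
        self.hill_bounds = hill_bounds
        self.ec50_log_margin = ec50_log_margin

    def get_params(self) -> dict:
        return {
            "top_bounds": self.top_bounds,
            "bottom_bounds": self.bottom_bounds,
            "hill_bounds": self.hill_bounds,
            "ec50_log_margin": self.ec50_log_margin,
        }

    def set_params(self, **params) -> "FourParamLogistic":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, concentrations, viability, x0=None) -> "FourParamLogistic":
        c = np.asarray(concentrations, dtype=float)
        v = np.asarray(viability, dtype=float)
        if len(np.unique(c)) < 4:
            raise ValueError("need at least 4 concentration levels to fit a 4PL")
        logc = np.log10(c)
        lo = [self.top_bounds[0], self.bottom_bounds[0],
              logc.min() - self.ec50_log_margin, math.log10(self.hill_bounds[0])]
        hi = [self.top_bounds[1], self.bottom_bounds[1],
              logc.max() + self.ec50_log_margin, math.log10(self.hill_bounds[1])]

        def model(logc_, top, bottom, logec50, loghill):
            return bottom + (top - bottom) / (
                1.0 + 10.0 ** ((logc_ - logec50) * 10.0**loghill)
            )

        top0 = float(np.clip(v.max(), *self.top_bounds))
        bot0 = float(np.clip(v.min(), *self.bottom_bounds))
        if x0 is not None:
            starts = [x0]
        else:
            starts = [
                [top0, bot0, g, 0.0]
                for g in (logc.min(), float(logc.mean()), logc.max())
            ]
        best, best_sse = None, np.inf
        for s in starts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = curve_fit(
                        model, logc, v, p0=np.clip(s, lo, hi), bounds=(lo, hi),
                        maxfev=5000,
                    )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((model(logc, *popt) - v) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
        if best is None:
            raise RuntimeError("4PL fit failed to converge from every start")
        self.top_, self.bottom_ = float(best[0]), float(best[1])
        self.ec50_ = float(10.0 ** best[2])
        self.hill_ = float(10.0 ** best[3])
        self.sse_ = best_sse
        self.x0_ = list(map(float, best))
        return self

    def predict(self, concentrations) -> np.ndarray:
        return four_pl(concentrations, self.top_, self.bottom_, self.ec50_, self.hill_)


def fit_4pl(
    series: DoseResponseSeries,
    n_boot: int = 1000,
    seed: int | None = None,
    activity_cap: float = DEFAULT_ACTIVITY_CAP,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> DoseResponseResult:
    """Fit one arm, bootstrap the EC50 CI, and apply the censoring rules.

    Censoring: a fitted EC50 above the highest tested concentration, or a
    fitted span (top - bottom) below ``min_effect`` percentage points, yields
    "EC50 > max tested" and ``active = False``; a censored arm never reports
    a point EC50.
    """
    cmax = float(series.concentrations.max())
    c, v = series.flatten()
    est = FourParamLogistic()
    try:
        est.fit(c, v)
    except (RuntimeError, ValueError) as exc:
        return DoseResponseResult(
            series.sample_id, series.cell_line, series.arm,
            ec50=float("nan"), ec50_ci=None, hill=float("nan"),
            top=float("nan"), bottom=float("nan"),
            censored=True, censor_bound=cmax, active=False,
            fit_ok=False, message=str(exc),
        )

    censored = est.ec50_ > cmax or (est.top_ - est.bottom_) < min_effect
    ci = None
    if not censored and n_boot > 0:
        # case-resampling bootstrap over replicates within each concentration,
        # with the small-sample inflation factor sqrt(n/(n-1)) on deviations
        # (plain within-group resampling shrinks the variance by (n-1)/n);
        # the 95% interval is a t interval on log EC50 with the bootstrap SE.
        rng = np.random.default_rng(seed)
        log_boots = []
        for _ in range(n_boot):
            vb = []
            for v_i in series.viability:
                m = v_i.mean()
                r = v_i[rng.integers(0, len(v_i), len(v_i))]
                infl = math.sqrt(len(v_i) / (len(v_i) - 1)) if len(v_i) > 1 else 1.0
                vb.append(m + (r - m) * infl)
            cb = np.concatenate(
                [np.full(len(x), conc)
                 for conc, x in zip(series.concentrations, vb)]
            )
            try:
                b = FourParamLogistic().fit(cb, np.concatenate(vb), x0=est.x0_)
            except (RuntimeError, ValueError):
                continue
            log_boots.append(math.log(b.ec50_))
        if len(log_boots) >= max(20, n_boot // 2):
            n_obs = len(v)
            tq = float(t_dist.ppf(0.975, max(n_obs - 4, 1)))
            sd = float(np.std(log_boots, ddof=1))
            ci = (
                float(math.exp(math.log(est.ec50_) - tq * sd)),
                float(math.exp(math.log(est.ec50_) + tq * sd)),
            )

    return DoseResponseResult(
        series.sample_id, series.cell_line, series.arm,
        ec50=float("nan") if censored else est.ec50_,
        ec50_ci=ci,
        hill=est.hill_, top=est.top_, bottom=est.bottom_,
        censored=censored, censor_bound=cmax,
        active=(not censored) and est.ec50_ < activity_cap,
        fit_ok=True,
    )


@dataclass
class SelectivityResult:
    sample_id: str
    cell_line: str
    si: float  # point value, or the lower bound when censored
    si_censored: bool  # True when si is a lower bound ("> si")
    photo_enhanced: bool
    defined: bool = True

    @property
    def si_display(self) -> str:
        if not self.defined:
            return "undefined"
        return f"> {self.si:.3g}" if self.si_censored else f"{self.si:.3g}"


def selectivity(
    dark: DoseResponseResult,
    irr: DoseResponseResult,
    threshold: float = 2.0,
) -> SelectivityResult:
    """Selectivity index S.I. = EC50,dark / EC50,irradiated.

    A censored dark arm with an active irradiated arm yields a lower bound
    (censor bound / EC50,irradiated); both arms censored leave the index
    undefined.
    """
    if dark.sample_id != irr.sample_id or dark.cell_line != irr.cell_line:
        raise ValueError("selectivity requires matching sample and cell line")
    if dark.censored and irr.censored:
        return SelectivityResult(
            dark.sample_id, dark.cell_line,
            si=float("nan"), si_censored=False, photo_enhanced=False, defined=False,
        )
    if dark.censored:
        bound = dark.censor_bound / irr.ec50
        return SelectivityResult(
            dark.sample_id, dark.cell_line,
            si=float(bound), si_censored=True, photo_enhanced=bound >= threshold,
        )
    if irr.censored:
        # light arm weaker than dark arm out to the tested cap: no enhancement
        upper = dark.ec50 / irr.censor_bound
        return SelectivityResult(
            dark.sample_id, dark.cell_line,
            si=float(upper), si_censored=False, photo_enhanced=False,
        )
    si = dark.ec50 / irr.ec50
    return SelectivityResult(
        dark.sample_id, dark.cell_line,
        si=float(si), si_censored=False, photo_enhanced=si >= threshold,
    )


def read_dose_response(path) -> list[DoseResponseSeries]:
    """Load the long-format dose-response CSV into one series per
    (sample, cell line, arm)."""
    df = pd.read_csv(path)
    required = [
        "sample_id", "cell_line", "arm",
        "concentration_ug_per_ml", "replicate", "viability_pct",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response CSV missing column(s) {missing}")
    out = []
    for (sid, line, arm), grp in df.groupby(["sample_id", "cell_line", "arm"]):
        concs = np.sort(grp["concentration_ug_per_ml"].unique())
        viab = [
            grp.loc[grp["concentration_ug_per_ml"] == c, "viability_pct"].to_numpy()
            for c in concs
        ]
        out.append(DoseResponseSeries(str(sid), str(line), str(arm), concs, viab))
    return out


def results_to_frame(
    fits: list[DoseResponseResult], sels: list[SelectivityResult] | None = None
) -> pd.DataFrame:
    """Fit results (one row per arm) joined with per-sample selectivity."""
    rows = []
    sel_map = {(s.sample_id, s.cell_line): s for s in (sels or [])}
    for r in fits:
        sel = sel_map.get((r.sample_id, r.cell_line))
        rows.append(
            {
                "sample_id": r.sample_id,
                "cell_line": r.cell_line,
                "arm": r.arm,
                "ec50": r.ec50,
                "ec50_low": r.ec50_ci[0] if r.ec50_ci else np.nan,
                "ec50_high": r.ec50_ci[1] if r.ec50_ci else np.nan,
                "hill": r.hill,
                "censored": r.censored,
                "active": r.active,
                "si": sel.si if sel else np.nan,
                "si_censored": sel.si_censored if sel else False,
                "photo_enhanced": sel.photo_enhanced if sel else False,
            }
        )
    return pd.DataFrame(rows)
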
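"""PC150 phenotype derivation from Penh dose-response data.

The methacholine-responsiveness phenotype of a mouse is the provocative
concentration PC150: the methacholine dose (mg/ml) at which its Penh
response, expressed as percent of the dose-0 value, reaches 150% (a 50%
increase over baseline — the murine analogue of the human PC20). Per
mouse and session the pipeline

1. averages the two baseline replicate series dose-by-dose (a single
   available replicate is used as-is),
2. converts Penh to percent-control (100 x Penh(d) / Penh(0)),
3. fits the quadratic ``percent_control = alpha + beta1*d + beta2*d^2``
   by ordinary least squares,
4. inverts the fit at the 150% threshold, taking the smallest positive
   real root within an extrapolation cap, falling back to a straight-line
   fit when the quadratic admits no root but the data trend upward,
5. reports baseline PC150, final (post-allergen) PC150 and their
   difference delta = baseline - final (positive delta = allergen
   increased responsiveness).

Mice whose curves never reach the threshold are flagged "unresponsive"
and excluded from downstream mapping with a logged count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_THRESHOLD = 150.0
DEFAULT_EXTRAPOLATION_CAP = 2.0


class PhenotypeUndefined(Exception):
    """A phenotype value could not be derived; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class DoseResponseSeries:
    """Ordered (dose, response) pairs for one mouse and session."""

    mouse_id: str
    session: str
    doses: np.ndarray
    responses: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if self.doses.size and np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.doses)


@dataclass
class QuadraticFit:
    """Per-mouse percent-control dose-response fit.

    ``kind`` is "quadratic" (alpha + beta1*d + beta2*d^2) or "linear"
    (beta2 fixed at 0).
    """

    alpha: float
    beta1: float
    beta2: float
    rss: float
    n_points: int
    kind: str = "quadratic"

    def predict(self, dose):
        d = np.asarray(dose, dtype=float)
        return self.alpha + self.beta1 * d + self.beta2 * d**2


def percent_control(series: DoseResponseSeries) -> DoseResponseSeries:
    """Express responses as percent of the dose-0 response.

    The first element is exactly 100 by construction. A missing or
    non-positive dose-0 response makes the phenotype underivable.
    """
    if len(series) == 0 or series.doses[0] != 0.0:
        raise PhenotypeUndefined("missing dose-0 response")
    base = series.responses[0]
    if not np.isfinite(base) or base <= 0:
        raise PhenotypeUndefined("non-positive dose-0 response")
    pc = 100.0 * series.responses / base
    pc[0] = 100.0
    return replace(series, responses=pc)


def average_baselines(
    s1: DoseResponseSeries, s2: DoseResponseSeries | None = None
) -> DoseResponseSeries:
    """Dose-wise mean of the two baseline replicate series.

    Doses present in only one replicate (e.g. after truncation) keep the
    available value; if only one replicate exists it is returned unchanged.
    """
    if s2 is None:
        return s1
    if s1.mouse_id != s2.mouse_id:
        raise ValueError("baseline series belong to different mice")
    common = np.intersect1d(s1.doses, s2.doses)
    if common.size < 2:
        raise PhenotypeUndefined("baseline replicates share fewer than 2 doses")
    all_doses = np.union1d(s1.doses, s2.doses)
    m1 = dict(zip(s1.doses, s1.responses))
    m2 = dict(zip(s2.doses, s2.responses))
    merged = np.array(
        [np.mean([m[d] for m in (m1, m2) if d in m]) for d in all_doses]
    )
    return DoseResponseSeries(
        mouse_id=s1.mouse_id,
        session="baseline",
        doses=all_doses,
        responses=merged,
        truncated=s1.truncated or s2.truncated,
    )


def fit_dose_response(series: DoseResponseSeries) -> QuadraticFit:
    """Ordinary least squares of percent-control on (1, dose, dose^2).

    With exactly three points the quadratic interpolates (RSS = 0); with
    two points a straight line is fitted instead; fewer points leave the
    phenotype undefined.
    """
    d, y = series.doses, series.responses
    n = len(d)
    if n < 2:
        raise PhenotypeUndefined("fewer than 2 dose-response points")
    if n == 2:
        slope = (y[1] - y[0]) / (d[1] - d[0])
        return QuadraticFit(
            alpha=float(y[0] - slope * d[0]),
            beta1=float(slope),
            beta2=0.0,
            rss=0.0,
            n_points=2,
            kind="linear",
        )
    X = np.column_stack([np.ones(n), d, d**2])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return QuadraticFit(
        alpha=float(coef[0]),
        beta1=float(coef[1]),
        beta2=float(coef[2]),
        rss=float(resid @ resid),
        n_points=n,
        kind="quadratic",
    )


def invert_pc(
    fit: QuadraticFit,
    threshold: float = DEFAULT_THRESHOLD,
    max_dose: float = 25.0,
    extrapolation_cap: float = DEFAULT_EXTRAPOLATION_CAP,
) -> float | None:
    """Dose at which the fitted curve reaches the percent-control threshold.

    Returns the smallest positive real root of
    ``alpha + beta1*d + beta2*d^2 = threshold`` not exceeding
    ``extrapolation_cap * max_dose``; ``None`` (an "unresponsive" animal)
    when no admissible root exists.
    """
    if threshold <= 100.0:
        raise ValueError("threshold must exceed 100 (percent of control)")
    cap = extrapolation_cap * max_dose
    c = fit.alpha - threshold
    roots: list[float]
    if abs(fit.beta2) < 1e-12:  # linear (or linear-kind) curve
        if fit.beta1 == 0.0:
            return None
        roots = [-c / fit.beta1]
    else:
        disc = fit.beta1**2 - 4.0 * fit.beta2 * c
        if disc < 0:
            return None
        sq = math.sqrt(disc)
        roots = [(-fit.beta1 - sq) / (2 * fit.beta2), (-fit.beta1 + sq) / (2 * fit.beta2)]
    admissible = [r for r in roots if 1e-12 < r <= cap]
    return min(admissible) if admissible else None


def linear_fallback(series: DoseResponseSeries) -> QuadraticFit:
    """Straight-line fit used when the quadratic admits no threshold crossing.

    Invoked only for series whose quadratic fit yields no admissible root
    while the points still trend upward across the threshold; every use is
    logged by the caller.
    """
    d, y = series.doses, series.responses
    if len(d) < 2:
        raise PhenotypeUndefined("fewer than 2 points for linear fallback")
    X = np.column_stack([np.ones(len(d)), d])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return QuadraticFit(
        alpha=float(coef[0]),
        beta1=float(coef[1]),
        beta2=0.0,
        rss=float(resid @ resid),
        n_points=len(d),
        kind="linear",
    )


def _pc_for_series(
    series: DoseResponseSeries,
    threshold: float,
    max_dose: float,
    extrapolation_cap: float,
) -> tuple[float | None, str, bool]:
    """(PC value or None, model kind used, fallback flag) for one series."""
    pc_series = percent_control(series)
    fit = fit_dose_response(pc_series)
    value = invert_pc(fit, threshold, max_dose, extrapolation_cap)
    if value is not None or fit.kind == "linear":
        return value, fit.kind, False
    lin = linear_fallback(pc_series)
    if lin.beta1 > 0:
        lin_value = invert_pc(lin, threshold, max_dose, extrapolation_cap)
        if lin_value is not None:
            return lin_value, "linear", True
    return None, fit.kind, False


def _series_from_group(mouse_id: str, session: str, grp: pd.DataFrame) -> DoseResponseSeries:
    # duplicate doses within a session are averaged before fitting
    agg = grp.groupby("dose_mg_ml", as_index=False).agg(
        penh=("penh", "mean"), truncated=("truncated", "max")
    )
    agg = agg.sort_values("dose_mg_ml")
    return DoseResponseSeries(
        mouse_id=mouse_id,
        session=session,
        doses=agg["dose_mg_ml"].to_numpy(),
        responses=agg["penh"].to_numpy(),
        truncated=bool(agg["truncated"].max()) if "truncated" in agg else False,
    )


def build_phenotypes(
    penh: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    extrapolation_cap: float = DEFAULT_EXTRAPOLATION_CAP,
    max_dose: float | None = None,
) -> pd.DataFrame:
    """Per-mouse PC150 phenotype table from a long-format Penh table.

    ``penh`` needs columns mouse_id, session (baseline1/baseline2/final),
    dose_mg_ml, penh and optionally truncated. Returns one row per mouse:
    pc150_baseline, pc150_final, delta (baseline - final), ln_baseline,
    ln_final, model kinds, fallback flags and a status column; mice with
    an underivable PC150 keep their row with status set and NaN values.
    """
    required = {"mouse_id", "session", "dose_mg_ml", "penh"}
    missing = required - set(penh.columns)
    if missing:
        raise ValueError(f"penh table lacks columns: {sorted(missing)}")
    penh = penh.copy()
    if "truncated" not in penh.columns:
        penh["truncated"] = 0
    if max_dose is None:
        max_dose = float(penh["dose_mg_ml"].max())

    records = []
    for mouse_id, mgrp in penh.groupby("mouse_id", sort=True):
        series = {
            session: _series_from_group(str(mouse_id), session, sgrp)
            for session, sgrp in mgrp.groupby("session")
        }
        unknown = set(series) - {"baseline1", "baseline2", "final"}
        if unknown:
            raise ValueError(f"mouse {mouse_id}: unknown session labels {sorted(unknown)}")
        rec: dict = {"mouse_id": str(mouse_id)}
        results: dict[str, tuple[float | None, str, bool]] = {}
        for phase in ("baseline", "final"):
            try:
                if phase == "baseline":
                    if "baseline1" not in series and "baseline2" not in series:
                        raise PhenotypeUndefined("no baseline session")
                    s1 = series.get("baseline1") or series.get("baseline2")
                    s2 = series.get("baseline2") if "baseline1" in series else None
                    s = average_baselines(s1, s2)
                else:
                    if "final" not in series:
                        raise PhenotypeUndefined("no final session")
                    s = series["final"]
                results[phase] = _pc_for_series(s, threshold, max_dose, extrapolation_cap)
                rec[f"undefined_reason_{phase}"] = (
                    "" if results[phase][0] is not None else "unresponsive"
                )
            except PhenotypeUndefined as exc:
                results[phase] = (None, "none", False)
                rec[f"undefined_reason_{phase}"] = exc.reason

        (pc_b, kind_b, fb_b), (pc_f, kind_f, fb_f) = results["baseline"], results["final"]
        rec.update(
            pc150_baseline=pc_b if pc_b is not None else np.nan,
            pc150_final=pc_f if pc_f is not None else np.nan,
            delta=(pc_b - pc_f) if (pc_b is not None and pc_f is not None) else np.nan,
            ln_baseline=np.log(pc_b) if pc_b is not None and pc_b > 0 else np.nan,
            ln_final=np.log(pc_f) if pc_f is not None and pc_f > 0 else np.nan,
            model_kind_baseline=kind_b,
            model_kind_final=kind_f,
            fallback_baseline=fb_b,
            fallback_final=fb_f,
        )
        if pc_b is not None and pc_f is not None:
            rec["status"] = "ok"
        elif pc_b is None and pc_f is None:
            rec["status"] = "undefined_both"
        else:
            rec["status"] = "undefined_baseline" if pc_b is None else "undefined_final"
        records.append(rec)

    cols = [
        "mouse_id", "pc150_baseline", "pc150_final", "delta",
        "ln_baseline", "ln_final", "model_kind_baseline", "model_kind_final",
        "fallback_baseline", "fallback_final",
        "undefined_reason_baseline", "undefined_reason_final", "status",
    ]
    return pd.DataFrame(records)[cols]


def delta_pc150(baseline, final):
    """Change in PC150 due to allergen: baseline - final (mg/ml).

    Positive values mean allergen increased methacholine responsiveness
    (the provocative dose fell); negative deltas are retained.
    """
    return np.asarray(baseline, dtype=float) - np.asarray(final, dtype=float)


def relative_change_percent(baseline, final):
    """Delta as a percentage of the baseline value."""
    b = np.asarray(baseline, dtype=float)
    return 100.0 * delta_pc150(b, final) / b


def boxcox_profile(
    values: np.ndarray,
    mouse_ids: list[str] | None = None,
    lambdas: np.ndarray | None = None,
) -> dict:
    """Box-Cox profile log-likelihood over a lambda grid.

    Used as a diagnostic for the transformation choice: a confidence
    region covering lambda=0 supports the natural-log transform applied to
    baseline and final PC150, one covering lambda=1 supports leaving the
    value (e.g. delta) untransformed. Returns a dict with the grid, the
    profile, the ~95% region, a suggested transform and a degeneracy flag.
    """
    from scipy import stats

    x = np.asarray(values, dtype=float)
    bad = ~(x > 0) | ~np.isfinite(x)
    if bad.any():
        if mouse_ids is not None:
            names = [m for m, b in zip(mouse_ids, bad) if b]
            raise ValueError(f"non-positive phenotype values for mice: {names}")
        raise ValueError("non-positive phenotype values")
    if lambdas is None:
        lambdas = np.linspace(-2.0, 2.0, 161)
    if np.ptp(x) == 0:
        return {
            "lambdas": lambdas,
            "llf": np.full_like(lambdas, np.nan),
            "ci": (np.nan, np.nan),
            "suggested": "undetermined",
            "degenerate": True,
        }
    llf = np.array([stats.boxcox_llf(lam, x) for lam in lambdas])
    cutoff = llf.max() - stats.chi2.ppf(0.95, 1) / 2.0
    in_region = llf >= cutoff
    ci = (float(lambdas[in_region].min()), float(lambdas[in_region].max()))
    if ci[0] <= 0.0 <= ci[1]:
        suggested = "ln"
    elif ci[0] <= 1.0 <= ci[1]:
        suggested = "identity"
    else:
        suggested = "other"
    return {"lambdas": lambdas, "llf": llf, "ci": ci, "suggested": suggested,
            "degenerate": False}


def collapse_resistance(
    cycles: pd.DataFrame, mouse_id: str = "", session: str = "resistance"
) -> DoseResponseSeries:
    """Mean lung resistance per methacholine dose from 2-sec measurement cycles.

    ``cycles`` needs columns dose_mg_ml and resistance (a time column may be
    present but is ignored — all cycles in the recording window count).
    The result feeds the same percent-control / PC150 machinery as Penh.
    """
    if "dose_mg_ml" not in cycles.columns or "resistance" not in cycles.columns:
        raise ValueError("cycles table needs dose_mg_ml and resistance columns")
    means = (
        cycles.groupby("dose_mg_ml", as_index=False)["resistance"].mean()
        .sort_values("dose_mg_ml")
    )
    if means["dose_mg_ml"].iloc[0] != 0.0:
        raise PhenotypeUndefined("missing dose-0 resistance block")
    return DoseResponseSeries(
        mouse_id=mouse_id,
        session=session,
        doses=means["dose_mg_ml"].to_numpy(),
        responses=means["resistance"].to_numpy(),
    )


class PC150Phenotyper(BaseEstimator, TransformerMixin):
    """Transformer: long-format Penh table -> per-mouse PC150 phenotypes.

    Parameters
    ----------
    threshold : float, default 150
        Percent-control level defining the provocative concentration.
    extrapolation_cap : float, default 2.0
        PC values beyond ``extrapolation_cap x max_dose`` are treated as
        unidentifiable ("unresponsive" animal).
    max_dose : float or None
        Highest protocol dose; inferred from the data when None.

    After :meth:`transform`, ``n_mice_``, ``n_excluded_`` and
    ``exclusion_reasons_`` describe the undefined-phenotype mice.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        extrapolation_cap: float = DEFAULT_EXTRAPOLATION_CAP,
        max_dose: float | None = None,
    ):
        self.threshold = threshold
        self.extrapolation_cap = extrapolation_cap
        self.max_dose = max_dose

    def fit(self, X: pd.DataFrame, y=None) -> "PC150Phenotyper":
        if self.threshold <= 100:
            raise ValueError("threshold must exceed 100")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        table = build_phenotypes(
            X,
            threshold=self.threshold,
            extrapolation_cap=self.extrapolation_cap,
            max_dose=self.max_dose,
        )
        self.n_mice_ = len(table)
        excluded = table[table["status"] != "ok"]
        self.n_excluded_ = len(excluded)
        self.exclusion_reasons_ = excluded["status"].value_counts().to_dict()
        if self.n_excluded_:
            warnings.warn(
                f"{self.n_excluded_} of {self.n_mice_} mice have undefined PC150 "
                "and are excluded from downstream analyses",
                stacklevel=2,
            )
        n_fallback = int(table["fallback_baseline"].sum() + table["fallback_final"].sum())
        if n_fallback:
            warnings.warn(f"linear fallback used for {n_fallback} series", stacklevel=2)
        return table
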
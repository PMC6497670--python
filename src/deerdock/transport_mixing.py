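"""Heterodimer-mixing transport model.

Stochastic (binomial) dimer assembly from mixed protomer pools, the
quadratic rate model rate(f) = f^2 a_WT + 2f(1-f) c a_WT + (1-f)^2 a_IL,
initial-rate estimation from uptake time courses, and least-squares
comparison of discrete heterodimer-activity models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "UptakeTimeCourse",
    "MixingModel",
    "dimer_fractions",
    "predicted_rate",
    "initial_rate",
    "fit_mixing",
    "load_uptake_csv",
    "write_uptake_csv",
]


@dataclass(frozen=True)
class MixingModel:
    """Homodimer specific activities (nmol/mg/min) and relative heterodimer
    activity c_het (fraction of the WT homodimer activity)."""

    a_wt: float
    a_il: float
    c_het: float

    def __post_init__(self):
        if self.a_wt < 0 or self.a_il < 0:
            raise ValueError("specific activities must be non-negative")
        if not 0.0 <= self.c_het <= 1.0:
            raise ValueError("c_het must be in [0, 1]")


@dataclass
class UptakeTimeCourse:
    """Uptake time courses for one mixing fraction.

    data: columns time_min, uptake (nmol substrate per mg protein), replicate.
    """

    data: pd.DataFrame
    f_wt: float

    def __post_init__(self):
        required = {"time_min", "uptake", "replicate"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"uptake data must have columns {sorted(required)}")
        if not 0.0 <= self.f_wt <= 1.0:
            raise ValueError("f_wt must be in [0, 1]")
        for rep, grp in self.data.groupby("replicate"):
            t = grp["time_min"].to_numpy()
            if len(t) < 3:
                raise ValueError(f"replicate {rep} has fewer than 3 time points")
            if (t < 0).any() or (np.diff(t) <= 0).any():
                raise ValueError(f"replicate {rep} times must be non-negative increasing")

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())


def dimer_fractions(f_wt: float) -> tuple[float, float, float]:
    """Binomial dimer-class fractions (WT-WT, WT-IL, IL-IL) at protomer
    fraction f_wt: (f^2, 2f(1-f), (1-f)^2)."""
    if not 0.0 <= f_wt <= 1.0:
        raise ValueError(f"f_wt must be in [0, 1], got {f_wt}")
    f = float(f_wt)
    return (f * f, 2.0 * f * (1.0 - f), (1.0 - f) * (1.0 - f))


def predicted_rate(f_wt: float, model: MixingModel) -> float:
    """Population rate under stochastic assembly; quadratic in f with the
    homodimer activities at the endpoints."""
    f_ww, f_wi, f_ii = dimer_fractions(f_wt)
    return f_ww * model.a_wt + f_wi * model.c_het * model.a_wt + f_ii * model.a_il


def _fit_plateau(t: np.ndarray, u: np.ndarray) -> float:
    """Plateau of a saturating uptake curve A(1 - exp(-k t)); falls back to
    the maximum uptake when the fit fails or the curve is not saturating."""
    u_max = float(u.max())
    if u_max <= 0:
        return max(u_max, 1.0)
    try:
        popt, _ = curve_fit(
            lambda tt, a, k: a * (1.0 - np.exp(-k * tt)),
            t,
            u,
            p0=(u_max, 1.0 / max(t.max(), 1e-9)),
            maxfev=2000,
        )
        if popt[0] > 0 and popt[0] < 10 * u_max:
            return float(popt[0])
    except RuntimeError:
        pass
    return u_max


def initial_rate(
    tc: UptakeTimeCourse,
    window: str = "plateau-fraction",
    plateau_frac: float = 0.3,
    k_points: int = 3,
) -> tuple[float, float]:
    """Initial transport rate (nmol/mg/min) as mean +/- sd over replicates.

    window="plateau-fraction" (default): per replicate, OLS slope of uptake
    vs time over points with uptake <= plateau_frac of the fitted plateau
    (at least 3 points). window="first-k": slope over the first k_points.
    """
    rates = []
    for _, grp in tc.data.groupby("replicate"):
        t = grp["time_min"].to_numpy(dtype=float)
        u = grp["uptake"].to_numpy(dtype=float)
        if window == "plateau-fraction":
            plateau = _fit_plateau(t, u)
            mask = u <= plateau_frac * plateau
            if mask.sum() < 3:
                mask = np.zeros(len(t), dtype=bool)
                mask[:3] = True
        elif window == "first-k":
            if k_points < 3:
                raise ValueError("need at least 3 points in the linear window")
            mask = np.zeros(len(t), dtype=bool)
            mask[:k_points] = True
        else:
            raise ValueError(f"unknown window policy {window!r}")
        if mask.sum() < 3:
            raise ValueError("fewer than 3 points in the linear window")
        slope = np.polyfit(t[mask], u[mask], 1)[0]
        rates.append(float(slope))
    rates = np.asarray(rates)
    return float(rates.mean()), float(rates.std(ddof=0))


def fit_mixing(
    rates: pd.DataFrame,
    a_wt: float,
    a_il: float,
    discrete_models: tuple = (0.0, 0.5, 1.0),
) -> dict:
    """Fit the heterodimer activity fraction with fixed homodimer activities.

    rates: DataFrame with columns f_wt, rate. The model is linear in c_het,
    so the least-squares estimate is closed form (clipped to [0, 1]). Also
    reports the SSE of each discrete candidate model; the best discrete
    model breaks ties toward the smaller c_het (fewer active species).
    """
    required = {"f_wt", "rate"}
    if not required.issubset(rates.columns):
        raise ValueError("rates table must have columns f_wt and rate")
    f = rates["f_wt"].to_numpy(dtype=float)
    r = rates["rate"].to_numpy(dtype=float)
    if len(np.unique(f)) < 3:
        raise ValueError("need rates at >= 3 distinct mixing fractions")
    base = f**2 * a_wt + (1.0 - f) ** 2 * a_il
    g = 2.0 * f * (1.0 - f) * a_wt
    denom = float(g @ g)
    c_hat = float(np.clip((g @ (r - base)) / denom, 0.0, 1.0)) if denom > 0 else 0.0
    sse = {}
    for c in discrete_models:
        pred = base + c * g
        sse[c] = float(((r - pred) ** 2).sum())
    best = min(sse, key=lambda c: (sse[c], c))
    return {"c_het": c_hat, "sse": sse, "best_model": best}


def load_uptake_csv(path) -> list[UptakeTimeCourse]:
    """Read uptake CSV (time_min, uptake_nmol_per_mg, replicate, f_wt),
    grouped by mixing fraction."""
    df = pd.read_csv(path)
    df = df.rename(columns={"uptake_nmol_per_mg": "uptake"})
    out = []
    for f_wt, grp in df.groupby("f_wt"):
        out.append(
            UptakeTimeCourse(
                grp[["time_min", "uptake", "replicate"]].reset_index(drop=True),
                float(f_wt),
            )
        )
    return out


def write_uptake_csv(courses: list[UptakeTimeCourse], path) -> None:
    frames = []
    for tc in courses:
        df = tc.data.copy()
        df["f_wt"] = tc.f_wt
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    combined = combined.rename(columns={"uptake": "uptake_nmol_per_mg"})
    combined.to_csv(path, index=False, float_format="%.6g")
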
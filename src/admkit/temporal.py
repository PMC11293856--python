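"""Temporal response of projected associations under a climate scenario.

For each association projected at a series of time points we track two
summaries: the proportion of valid cells predicted co-present (from its
cADM) and the reconstructed global rho* (from its rADM). Ordinary
least-squares slopes of both series against calendar year classify each
association into one of five response groups —

    (+c)(+r)  co-presence and strength both increasing,
    (+c)(-r)  range expanding, strength weakening,
    (-c)(+r)  range shrinking, strength gaining,
    (-c)(-r)  both declining,
    neutral   both slopes inside a band around zero.

The neutral band is +/- ``band_fraction`` of the largest absolute slope of
each metric (default 10%), or alternatively the central ``band_fraction``
quantile span of the slope distribution (``band_mode='quantile'``). Only
associations keeping at least ``min_copresence`` co-presence at every time
point are classified, so that the trends concern associations that actually
persist in the projected area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Trajectory",
    "ResponseClassification",
    "filter_persistent",
    "fit_slopes",
    "classify_response",
    "summarize_groups",
    "RESPONSE_GROUPS",
]

RESPONSE_GROUPS = ("pp", "pm", "mp", "mm", "neutral")


@dataclass(eq=False)
class Trajectory:
    """Co-presence proportion and rho* of one association over time."""

    association_id: str
    years: np.ndarray
    copresence_proportion: np.ndarray
    rho_star: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.copresence_proportion = np.asarray(self.copresence_proportion, dtype=float)
        self.rho_star = np.asarray(self.rho_star, dtype=float)
        n = self.years.shape[0]
        if self.copresence_proportion.shape[0] != n or self.rho_star.shape[0] != n:
            raise ValueError("trajectory vectors must share one length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")


@dataclass
class ResponseClassification:
    """Slopes, fit diagnostics and the assigned response group."""

    association_id: str
    slope_c: float
    slope_r: float
    group: str
    diagnostics: dict = field(default_factory=dict)


def filter_persistent(
    trajectories: list[Trajectory], min_copresence: float = 0.30
) -> list[Trajectory]:
    """Keep trajectories with co-presence >= threshold at EVERY time point."""
    if not trajectories:
        raise ValueError("no trajectories given")
    return [
        t for t in trajectories if np.all(t.copresence_proportion >= min_copresence)
    ]


def _ols(years: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, Pearson r and R^2 of y against calendar year (OLS)."""
    if np.ptp(years) == 0:
        raise ValueError("constant time vector")
    if np.ptp(y) == 0:
        return 0.0, float("nan"), float("nan")
    res = stats.linregress(years, y)
    return float(res.slope), float(res.rvalue), float(res.rvalue**2)


def fit_slopes(trajectory: Trajectory) -> tuple[float, float, dict]:
    """Per-year OLS slopes of co-presence and rho* with fit diagnostics."""
    if trajectory.years.shape[0] < 3:
        raise ValueError("need at least three time points")
    slope_c, pearson_c, r2_c = _ols(trajectory.years, trajectory.copresence_proportion)
    slope_r, pearson_r, r2_r = _ols(trajectory.years, trajectory.rho_star)
    diagnostics = {
        "pearson_c": pearson_c, "r2_c": r2_c,
        "pearson_r": pearson_r, "r2_r": r2_r,
    }
    return slope_c, slope_r, diagnostics


def _neutral_band(slopes: np.ndarray, band_fraction: float, band_mode: str):
    if band_mode == "max_fraction":
        half = band_fraction * np.max(np.abs(slopes)) if slopes.size else 0.0
        return -half, half
    if band_mode == "quantile":
        lo = float(np.quantile(slopes, 0.5 - band_fraction / 2))
        hi = float(np.quantile(slopes, 0.5 + band_fraction / 2))
        return min(lo, 0.0), max(hi, 0.0)
    raise ValueError(f"unknown band_mode {band_mode!r}")


def classify_response(
    slopes: dict[str, tuple[float, float]],
    band_fraction: float = 0.10,
    band_mode: str = "max_fraction",
    diagnostics: dict[str, dict] | None = None,
) -> list[ResponseClassification]:
    """Assign each association to one of the five response groups.

    ``slopes`` maps association id -> (slope_c, slope_r). A slope inside its
    metric's neutral band counts as neutral for that metric; the group is
    'neutral' only when BOTH metrics are neutral. Otherwise the label uses
    the raw sign of each slope (an exactly-zero slope is labelled '+' by
    convention in that mixed case). Pure function of the inputs.
    """
    if not slopes:
        raise ValueError("no slopes given")
    ids = list(slopes)
    sc = np.array([slopes[a][0] for a in ids], dtype=float)
    sr = np.array([slopes[a][1] for a in ids], dtype=float)
    lo_c, hi_c = _neutral_band(sc, band_fraction, band_mode)
    lo_r, hi_r = _neutral_band(sr, band_fraction, band_mode)
    out = []
    for a, c, r in zip(ids, sc, sr):
        neutral_c = lo_c <= c <= hi_c
        neutral_r = lo_r <= r <= hi_r
        if neutral_c and neutral_r:
            group = "neutral"
        else:
            group = ("p" if c >= 0 else "m") + ("p" if r >= 0 else "m")
        out.append(
            ResponseClassification(
                association_id=a, slope_c=float(c), slope_r=float(r), group=group,
                diagnostics=(diagnostics or {}).get(a, {}),
            )
        )
    return out


def summarize_groups(
    classifications: list[ResponseClassification],
    cluster_labels: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Contingency table of response group x cluster (or group counts)."""
    if cluster_labels is None:
        counts = pd.Series([c.group for c in classifications], dtype=object).value_counts()
        return counts.reindex(RESPONSE_GROUPS, fill_value=0).to_frame("count")
    missing = [c.association_id for c in classifications if c.association_id not in cluster_labels]
    if missing:
        raise KeyError(f"associations without a cluster label: {missing[:5]}")
    df = pd.DataFrame(
        {
            "group": [c.group for c in classifications],
            "cluster": [cluster_labels[c.association_id] for c in classifications],
        }
    )
    table = pd.crosstab(df["group"], df["cluster"])
    return table.reindex(RESPONSE_GROUPS, fill_value=0)
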
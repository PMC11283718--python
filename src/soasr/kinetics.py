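"""Rate estimation and inference for incubation time series.

Rates of analyte production or consumption are estimated by ordinary
least squares on concentration-versus-time points.  Replicate series of
the same (site, treatment) are pooled for the headline estimate; per-
replicate slopes feed the hypothesis tests, keeping estimation and
inference separate.  "Maximum" rates use a sliding-window OLS over a
short window (default three timepoints), the standard way to extract the
linear phase of a lag-then-linear depletion curve.

Site-level process potential (e.g. the maximum arsenate reduction rate
in sulfur-amended incubations, μM per g dry weight per day) can then be
correlated against geochemical covariates with Pearson's r, two-sided
t-distribution p-values and Fisher-z confidence intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IncubationSeries",
    "RateEstimate",
    "CorrelationResult",
    "fit_linear_rate",
    "max_rate",
    "rate_ratio",
    "compare_treatments",
    "correlate_potential",
]


@dataclass
class IncubationSeries:
    """One replicate's concentration time series for one treatment at one site.

    ``timepoints`` are days, strictly increasing; ``concentrations`` maps
    analyte name to a vector aligned with ``timepoints``.  ``basis`` is
    ``"volume"`` (μM) or ``"dry_weight"`` (μM per g dw).
    """

    site: str
    treatment: str
    replicate: str
    timepoints: np.ndarray
    concentrations: dict[str, np.ndarray]
    basis: str = "volume"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.timepoints.size < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.basis not in ("volume", "dry_weight"):
            raise ValueError(f"unknown basis {self.basis!r}")
        self.concentrations = {
            k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()
        }
        for analyte, vec in self.concentrations.items():
            if vec.shape != self.timepoints.shape:
                raise ValueError(f"{analyte}: length mismatch with timepoints")
            if np.any(vec < 0):
                raise ValueError(f"{analyte}: concentrations must be >= 0")

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations)


@dataclass(frozen=True)
class RateEstimate:
    """An OLS slope with its standard error and provenance."""

    analyte: str
    rate: float  # μM/d or μM/g dw/d; sign convention depends on method
    stderr: float
    window: tuple[int, int]  # inclusive start/end timepoint indices
    n_replicates: int
    method: str
    basis: str = "volume"

    def __post_init__(self) -> None:
        if self.window[0] > self.window[1]:
            raise ValueError("window indices must be ordered")
        if not (self.stderr >= 0 or math.isnan(self.stderr)):
            raise ValueError("stderr must be >= 0")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of a site-level potential with one covariate."""

    parameter: str
    r: float
    p: float
    ci: tuple[float, float]
    n: int
    undefined: bool = False


def _as_series_list(series: IncubationSeries | Iterable[IncubationSeries]) -> list[IncubationSeries]:
    if isinstance(series, IncubationSeries):
        return [series]
    out = list(series)
    if not out:
        raise ValueError("no series supplied")
    bases = {s.basis for s in out}
    if len(bases) > 1:
        raise ValueError(f"mixed bases {sorted(bases)} cannot be pooled")
    return out


def _pooled_points(
    series: Sequence[IncubationSeries], analyte: str, window: tuple[int, int] | None
) -> tuple[np.ndarray, np.ndarray]:
    ts, cs = [], []
    for s in series:
        if analyte not in s.concentrations:
            raise KeyError(
                f"analyte {analyte!r} not in series ({s.site}/{s.treatment}/{s.replicate}); "
                f"available: {sorted(s.concentrations)}"
            )
        lo, hi = (0, s.timepoints.size - 1) if window is None else window
        if not (0 <= lo <= hi < s.timepoints.size):
            raise ValueError(f"window {window} invalid for series of length {s.timepoints.size}")
        ts.append(s.timepoints[lo : hi + 1])
        cs.append(s.concentrations[analyte][lo : hi + 1])
    return np.concatenate(ts), np.concatenate(cs)


def fit_linear_rate(
    series: IncubationSeries | Iterable[IncubationSeries],
    analyte: str,
    window: tuple[int, int] | None = None,
) -> RateEstimate:
    """OLS slope of concentration versus time over a window.

    Replicates are pooled: all (time, value) points enter one regression
    and the standard error comes from that pooled fit.  A positive slope
    is production, a negative slope consumption; the signed slope is
    returned.
    """
    slist = _as_series_list(series)
    t, c = _pooled_points(slist, analyte, window)
    if t.size < 2:
        raise ValueError("need at least 2 points to fit a rate")
    if np.ptp(t) == 0:
        raise ValueError("all timepoints identical; slope undefined")
    res = stats.linregress(t, c)
    stderr = 0.0 if math.isnan(res.stderr) else float(res.stderr)
    lo, hi = window if window is not None else (0, slist[0].timepoints.size - 1)
    return RateEstimate(
        analyte=analyte,
        rate=float(res.slope),
        stderr=stderr,
        window=(lo, hi),
        n_replicates=len(slist),
        method="pooled_ols",
        basis=slist[0].basis,
    )


def rate_confidence_interval(est: RateEstimate, n_points: int, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for an OLS slope fitted on ``n_points``."""
    df = n_points - 2
    if df <= 0:
        return (math.nan, math.nan)
    half = stats.t.ppf(0.5 + level / 2, df) * est.stderr
    return (est.rate - half, est.rate + half)


def max_rate(
    series: IncubationSeries | Iterable[IncubationSeries],
    analyte: str,
    window_size: int = 3,
    direction: str = "consumption",
    mode: str = "window",
) -> RateEstimate:
    """Largest-magnitude sliding-window rate in the stated direction.

    All replicate series must share the same timepoint grid; within each
    window the replicates are pooled for the slope.  The returned rate is
    the unsigned magnitude (the direction is recorded in ``method``), so
    a depletion phase of slope −38 yields ``rate == 38`` with
    ``direction="consumption"``.

    ``mode="diff"`` replaces window OLS with adjacent-timepoint
    difference quotients (window size 2), an alternative reading of a
    "maximum rate" between samplings.
    """
    if direction not in ("production", "consumption"):
        raise ValueError("direction must be 'production' or 'consumption'")
    slist = _as_series_list(series)
    grid = slist[0].timepoints
    for s in slist[1:]:
        if not np.array_equal(s.timepoints, grid):
            raise ValueError("max_rate requires replicates on a common timepoint grid")
    if mode == "diff":
        window_size = 2
    elif mode != "window":
        raise ValueError("mode must be 'window' or 'diff'")
    if not (2 <= window_size <= grid.size):
        raise ValueError(f"window_size {window_size} invalid for series of length {grid.size}")

    sign = 1.0 if direction == "production" else -1.0
    best: RateEstimate | None = None
    for lo in range(grid.size - window_size + 1):
        hi = lo + window_size - 1
        est = fit_linear_rate(slist, analyte, window=(lo, hi))
        if best is None or est.rate * sign > best.rate * sign:
            best = est
    assert best is not None
    return RateEstimate(
        analyte=analyte,
        rate=best.rate * sign,  # magnitude in the stated direction
        stderr=best.stderr,
        window=best.window,
        n_replicates=best.n_replicates,
        method=f"max_{mode}_{direction}",
        basis=best.basis,
    )


def rate_ratio(a: RateEstimate, b: RateEstimate) -> float:
    """Ratio of two rates, a/b.  Units and basis must match."""
    if a.basis != b.basis:
        raise ValueError(f"basis mismatch: {a.basis} vs {b.basis}")
    if b.rate == 0:
        raise ZeroDivisionError("denominator rate is zero")
    return a.rate / b.rate


def compare_treatments(
    series_set: Iterable[IncubationSeries],
    analyte: str,
    window: tuple[int, int] | None = None,
    p_adjust: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group rates per (site, treatment) and Welch tests between groups.

    Returns ``(estimates, tests)``.  ``estimates`` has one row per group
    with the pooled-OLS rate and the per-replicate slope spread;
    ``tests`` has one row per group pair with a two-sided Welch
    (unequal-variance) t-test on the per-replicate slopes.  Groups with a
    single replicate keep their estimate but their tests are marked
    unavailable (NaN p).  ``p_adjust="bh"`` applies Benjamini–Hochberg
    across the pairwise tests.
    """
    groups: dict[tuple[str, str], list[IncubationSeries]] = {}
    for s in series_set:
        groups.setdefault((s.site, s.treatment), []).append(s)
    if not groups:
        raise ValueError("no series supplied")

    est_rows = []
    rep_slopes: dict[tuple[str, str], np.ndarray] = {}
    for key, slist in groups.items():
        pooled = fit_linear_rate(slist, analyte, window=window)
        slopes = np.array([fit_linear_rate(s, analyte, window=window).rate for s in slist])
        rep_slopes[key] = slopes
        est_rows.append(
            {
                "site": key[0],
                "treatment": key[1],
                "analyte": analyte,
                "rate": pooled.rate,
                "stderr": pooled.stderr,
                "n_replicates": len(slist),
                "replicate_mean": slopes.mean(),
                "replicate_sd": slopes.std(ddof=1) if slopes.size > 1 else math.nan,
            }
        )
    estimates = pd.DataFrame(est_rows).sort_values(["site", "treatment"]).reset_index(drop=True)

    test_rows = []
    for (ka, kb) in itertools.combinations(sorted(rep_slopes), 2):
        sa, sb = rep_slopes[ka], rep_slopes[kb]
        if sa.size < 2 or sb.size < 2:
            p = math.nan
            stat = math.nan
        elif np.ptp(sa) == 0 and np.ptp(sb) == 0 and sa[0] == sb[0]:
            stat, p = 0.0, 1.0  # identical constant groups: no evidence
        else:
            stat, p = stats.ttest_ind(sa, sb, equal_var=False)
        test_rows.append(
            {
                "group_a": "/".join(ka),
                "group_b": "/".join(kb),
                "t": float(stat) if stat == stat else math.nan,
                "p": float(p) if p == p else math.nan,
                "available": not math.isnan(p) if isinstance(p, float) else True,
            }
        )
    tests = pd.DataFrame(test_rows)
    if p_adjust == "bh" and len(tests):
        mask = tests["p"].notna()
        if mask.any():
            tests.loc[mask, "p_adjusted"] = stats.false_discovery_control(
                tests.loc[mask, "p"].to_numpy()
            )
    return estimates, tests


def correlate_potential(
    potentials: Mapping[str, float],
    geochem: pd.DataFrame,
    level: float = 0.95,
) -> list[CorrelationResult]:
    """Pearson correlation of site potentials against each geochemical parameter.

    ``geochem`` is long-form with columns ``site``, ``parameter``,
    ``value``; sites missing a value are dropped pairwise.  For each
    parameter with ≥3 overlapping sites the result carries Pearson's r,
    a two-sided t-distribution p-value and a Fisher-z confidence interval
    at ``level``.  Zero variance on either side flags the result
    undefined instead of silently returning 0.
    """
    for col in ("site", "parameter", "value"):
        if col not in geochem.columns:
            raise ValueError(f"geochem table is missing column {col!r}")
    out: list[CorrelationResult] = []
    for parameter, sub in geochem.groupby("parameter", sort=True):
        sub = sub.dropna(subset=["value"])
        sites = [s for s in sub["site"] if s in potentials and potentials[s] == potentials[s]]
        if len(sites) < 3:
            continue
        x = sub.set_index("site").loc[sites, "value"].to_numpy(dtype=float)
        y = np.array([potentials[s] for s in sites], dtype=float)
        n = len(sites)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(CorrelationResult(parameter, math.nan, math.nan, (math.nan, math.nan), n, True))
            continue
        r, p = stats.pearsonr(x, y)
        if n > 3 and abs(r) < 1:
            z = math.atanh(r)
            half = stats.norm.ppf(0.5 + level / 2) / math.sqrt(n - 3)
            ci = (math.tanh(z - half), math.tanh(z + half))
        else:
            ci = (math.nan, math.nan)
        out.append(CorrelationResult(parameter, float(r), float(p), ci, n))
    return out
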
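"""Observer threshold statistics.

Summaries of "last hole you can still reliably visualize" readings: mean,
interobserver SD, t-based 95% CI, the exact paired Wilcoxon signed-rank test
between phantoms, and conversion of threshold depths to CNR and SC through
the calibration chain.

The Wilcoxon variant matches the small-sample convention: zero differences
are dropped, tied absolute differences receive mid-ranks, and the two-sided
p-value is computed by exact enumeration of all sign assignments (no normal
approximation, no continuity correction).  With five observers the attainable
p-values are coarse multiples of 1/16, which is why reported values like
13/16 = 0.8125 arise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel, LinearFit, sc_equivalent

__all__ = [
    "ObserverReading",
    "ThresholdSummary",
    "PairedTestResult",
    "ThresholdConversion",
    "summarize",
    "summarize_groups",
    "wilcoxon_exact",
    "thresholds_to_cnr_sc",
    "simulate_observer_readings",
    "readings_to_frame",
    "readings_from_csv",
]


@dataclass(frozen=True)
class ObserverReading:
    observer_id: str
    unit: str
    beam: str
    phantom: str
    limiting_depth: float

    def __post_init__(self) -> None:
        if self.limiting_depth <= 0:
            raise ValueError("limiting depth must be positive")


@dataclass(frozen=True)
class ThresholdSummary:
    mean_depth: float
    sd_depth: float
    ci95: tuple[float, float]
    n_observers: int


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float   # smaller of the signed-rank sums
    p_value: float     # two-sided, exact
    n_effective: int   # nonzero differences


@dataclass(frozen=True)
class ThresholdConversion:
    cnr_mean: float
    cnr_sd: float
    sc_mean: float
    sc_sd: float


def summarize(depths) -> ThresholdSummary:
    """Mean, sample SD and t-based 95% CI of a group of limiting depths."""
    d = np.asarray(
        [r.limiting_depth if isinstance(r, ObserverReading) else r for r in depths],
        dtype=float,
    )
    if d.size < 2:
        raise ValueError("need at least 2 readings per group")
    d = np.sort(d)  # reduction order fixed: exactly permutation-invariant
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = float(stats.t.ppf(0.975, d.size - 1)) * sd / np.sqrt(d.size)
    return ThresholdSummary(
        mean_depth=mean, sd_depth=sd, ci95=(mean - half, mean + half), n_observers=d.size
    )


def summarize_groups(readings, keys=("unit", "beam", "phantom")) -> pd.DataFrame:
    """Per-group threshold summaries as a table."""
    df = readings_to_frame(readings)
    rows = []
    for group, sub in df.groupby(list(keys), sort=True):
        s = summarize(sub["limiting_depth_mm"].tolist())
        rows.append(
            dict(
                zip(keys, group if isinstance(group, tuple) else (group,)),
                mean_depth_mm=s.mean_depth,
                sd_depth_mm=s.sd_depth,
                ci95_low_mm=s.ci95[0],
                ci95_high_mm=s.ci95[1],
                n_observers=s.n_observers,
            )
        )
    return pd.DataFrame(rows)


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact counts of W+ (on the doubled-rank integer scale) over all
    2^n sign assignments, by subset-sum dynamic programming."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_exact(paired_a, paired_b) -> PairedTestResult:
    """Exact two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties in |d| are mid-ranked; the null
    distribution is enumerated exactly over all sign assignments.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equally long")
    if a.size > 25:
        raise ValueError("exact enumeration supported for n <= 25")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return PairedTestResult(statistic=0.0, p_value=1.0, n_effective=0)
    ranks = stats.rankdata(np.abs(d))          # mid-ranks on ties
    doubled = np.rint(2 * ranks).astype(int)   # integers even with .5 ranks
    w_plus = float(doubled[d > 0].sum()) / 2.0
    w_minus = float(doubled[d < 0].sum()) / 2.0
    w = min(w_plus, w_minus)

    counts = _signed_rank_distribution(doubled)
    total = 2.0**n
    scale = int(round(2 * w))
    s2 = int(counts.size - 1)
    lower = counts[: scale + 1].sum() / total
    upper = counts[s2 - scale:].sum() / total
    return PairedTestResult(
        statistic=w, p_value=float(min(1.0, lower + upper)), n_effective=n
    )


def thresholds_to_cnr_sc(
    summary: ThresholdSummary, cnr_depth_fit: LinearFit, model: CalibrationModel
) -> ThresholdConversion:
    """Convert a depth threshold summary to CNR and SC summaries.

    Both maps are affine, so means map directly and SDs scale by the
    absolute slopes.
    """
    cnr_mean = float(cnr_depth_fit(summary.mean_depth))
    cnr_sd = abs(cnr_depth_fit.slope) * summary.sd_depth
    sc_mean = float(sc_equivalent(cnr_mean, model))
    chain_slope = model.sc_cnr_fit.slope / model.cross_fit.slope
    sc_sd = abs(chain_slope) * cnr_sd
    return ThresholdConversion(
        cnr_mean=cnr_mean, cnr_sd=cnr_sd, sc_mean=sc_mean, sc_sd=sc_sd
    )


def simulate_observer_readings(
    phantom_name: str,
    depth_series,
    cnr_depth_fit: LinearFit,
    *,
    beam: str,
    unit: str = "SIM",
    criterion_cnr: float = 1.2,
    n_observers: int = 5,
    jitter_sd_mm: float = 0.15,
    seed: int = 0,
) -> list[ObserverReading]:
    """Simulated-observer stand-in for visual threshold readings.

    The common threshold is the depth where the fitted CNR-depth line crosses
    the visibility criterion; each observer adds Gaussian jitter and reports
    the nearest discrete hole depth.  This is a synthetic stand-in for human
    scoring, not a psychophysical model.
    """
    depths = np.asarray(sorted(float(d) for d in depth_series))
    base = float(cnr_depth_fit.invert(criterion_cnr))
    rng = np.random.default_rng(seed)
    readings = []
    for k in range(n_observers):
        raw = base + rng.normal(0.0, jitter_sd_mm)
        snapped = float(depths[np.argmin(np.abs(depths - raw))])
        readings.append(
            ObserverReading(
                observer_id=f"obs{k + 1}",
                unit=unit,
                beam=beam,
                phantom=phantom_name,
                limiting_depth=snapped,
            )
        )
    return readings


def readings_to_frame(readings) -> pd.DataFrame:
    if isinstance(readings, pd.DataFrame):
        return readings
    return pd.DataFrame(
        {
            "observer_id": [r.observer_id for r in readings],
            "unit": [r.unit for r in readings],
            "beam": [r.beam for r in readings],
            "phantom": [r.phantom for r in readings],
            "limiting_depth_mm": [r.limiting_depth for r in readings],
        }
    )


def readings_from_csv(path, depth_series=None) -> list[ObserverReading]:
    """Load observer readings; optionally validate depths against a series."""
    df = pd.read_csv(path, comment="#")
    required = {"observer_id", "unit", "beam", "phantom", "limiting_depth_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"readings CSV missing columns: {sorted(missing)}")
    if depth_series is not None:
        allowed = {round(float(d), 6) for d in depth_series}
        bad = [
            v for v in df["limiting_depth_mm"] if round(float(v), 6) not in allowed
        ]
        if bad:
            raise ValueError(f"readings not in the configured depth series: {bad}")
    return [
        ObserverReading(
            observer_id=str(r.observer_id),
            unit=str(r.unit),
            beam=str(r.beam),
            phantom=str(r.phantom),
            limiting_depth=float(r.limiting_depth_mm),
        )
        for r in df.itertuples()
    ]
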
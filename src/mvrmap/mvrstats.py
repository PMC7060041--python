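"""Pair-level MVR spatiotemporal statistics and condition contrasts.

A resolved MVR event is a pair of co-frame fusions in the same bouton.
This module derives each pair's geometry (separation, midpoint distance to
the AZ center, which member is proximal) and amplitude asymmetry
(percentage amplitude difference relative to the larger member), and runs
the population-level analyses: the linear regression of amplitude
difference on separation (the frame-integration signature of intra-pair
desynchronization), the ANOCOVA-style slope comparison between conditions,
the chi-square test of whether the larger member preferentially sits
proximal to the AZ center, the stimulus-train trend control for
double-event probability, and the synchronous-vs-asynchronous (strontium)
amplitude-distribution control.

All two-group tests are two-sided; p-values are reported raw (no
multiple-testing correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "MvrPair",
    "RegressionFit",
    "TestResult",
    "characterize_mvr_pair",
    "amp_diff_vs_separation_fit",
    "compare_regression_slopes",
    "separation_fraction_below",
    "larger_event_position_test",
    "double_event_train_trend",
    "asynchronous_amplitude_control",
    "pairs_to_table",
]


@dataclass(frozen=True)
class MvrPair:
    """Geometry and amplitude asymmetry of one resolved MVR pair."""

    pair_id: str
    bouton_id: str
    stimulus_index: int
    xy_a: tuple[float, float]
    xy_b: tuple[float, float]
    amp_a: float
    amp_b: float
    separation: float  # nm
    amp_diff_pct: float  # 100 * |amp_a - amp_b| / max(amp_a, amp_b)
    proximal_index: int  # 0 -> member a, 1 -> member b
    larger_is_proximal: bool
    midpoint_dist_to_center: float
    distance_tie: bool = False
    amplitude_tie: bool = False


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line with slope inference."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n: int

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = sps.t.ppf(0.5 + level / 2, max(self.n - 2, 1))
        return (self.slope - z * self.slope_se, self.slope + z * self.slope_se)


@dataclass(frozen=True)
class TestResult:
    """A named hypothesis-test outcome."""

    test_name: str  # {ks2, chi2, paired_t, two_sample_t, anocova_slopes}
    statistic: float
    p_value: float
    df: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError("p_value must lie in [0, 1]")


def characterize_mvr_pair(
    pair_id: str,
    bouton_id: str,
    stimulus_index: int,
    xy_a: Sequence[float],
    xy_b: Sequence[float],
    amp_a: float,
    amp_b: float,
    az_center: Sequence[float],
    bouton_id_b: str | None = None,
) -> MvrPair:
    """Derive all pair-level quantities from the two member localizations.

    Proximal/distal assignment follows distance to the AZ center; an exact
    distance tie is broken by labeling the larger-amplitude member proximal
    and flagging the tie. Equal amplitudes flag ``amplitude_tie`` (such
    pairs are excluded from the larger-event position test).
    """
    if bouton_id_b is not None and bouton_id_b != bouton_id:
        raise ParameterError("MVR pair members must come from the same bouton")
    a = np.asarray(xy_a, dtype=float)
    b = np.asarray(xy_b, dtype=float)
    c = np.asarray(az_center, dtype=float)
    sep = float(np.hypot(*(a - b)))
    big, small = max(amp_a, amp_b), min(amp_a, amp_b)
    if big <= 0:
        raise ParameterError("amplitudes must be positive")
    amp_diff_pct = 100.0 * (big - small) / big
    d_a, d_b = float(np.hypot(*(a - c))), float(np.hypot(*(b - c)))
    tie = math.isclose(d_a, d_b, rel_tol=0.0, abs_tol=1e-9)
    if tie:
        proximal = 0 if amp_a >= amp_b else 1
    else:
        proximal = 0 if d_a < d_b else 1
    amp_tie = amp_a == amp_b
    larger = 0 if amp_a >= amp_b else 1
    mid = (a + b) / 2.0
    return MvrPair(
        pair_id=pair_id,
        bouton_id=bouton_id,
        stimulus_index=int(stimulus_index),
        xy_a=(float(a[0]), float(a[1])),
        xy_b=(float(b[0]), float(b[1])),
        amp_a=float(amp_a),
        amp_b=float(amp_b),
        separation=sep,
        amp_diff_pct=float(amp_diff_pct),
        proximal_index=proximal,
        larger_is_proximal=(larger == proximal),
        midpoint_dist_to_center=float(np.hypot(*(mid - c))),
        distance_tie=tie,
        amplitude_tie=amp_tie,
    )


def _ols(y: np.ndarray, x: np.ndarray) -> RegressionFit:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(len(y)),
    )


def amp_diff_vs_separation_fit(pairs: Sequence[MvrPair]) -> RegressionFit:
    """OLS of within-pair amplitude difference (%) on separation (nm)."""
    if len(pairs) < 3:
        raise ParameterError("regression needs at least 3 pairs")
    x = np.array([p.separation for p in pairs])
    y = np.array([p.amp_diff_pct for p in pairs])
    if np.ptp(x) == 0:
        raise ParameterError("all separations identical; slope undefined")
    return _ols(y, x)


def compare_regression_slopes(
    pairs_a: Sequence[MvrPair], pairs_b: Sequence[MvrPair]
) -> TestResult:
    """ANOCOVA-style slope-homogeneity test between two conditions.

    Fits one linear model of amplitude difference on separation with a
    group term and a group x separation interaction; the interaction's
    two-sided t-test is the slope comparison.
    """
    if len(pairs_a) < 3 or len(pairs_b) < 3:
        raise ParameterError("both groups need at least 3 pairs")
    x = np.concatenate([[p.separation for p in pairs_a],
                        [p.separation for p in pairs_b]])
    y = np.concatenate([[p.amp_diff_pct for p in pairs_a],
                        [p.amp_diff_pct for p in pairs_b]])
    g = np.concatenate([np.zeros(len(pairs_a)), np.ones(len(pairs_b))])
    if np.ptp(x) == 0:
        raise ParameterError("singular design: separations are constant")
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    fit = sm.OLS(y, X).fit()
    return TestResult(
        test_name="anocova_slopes",
        statistic=float(fit.tvalues[3]),
        p_value=float(fit.pvalues[3]),
        df=float(fit.df_resid),
        extra={
            "slope_a": float(fit.params[1]),
            "slope_b": float(fit.params[1] + fit.params[3]),
            "slope_difference": float(fit.params[3]),
        },
    )


def separation_fraction_below(
    pairs: Sequence[MvrPair], thresholds_nm: Sequence[float]
) -> list[float]:
    """Empirical CDF of pair separations at the given thresholds (strict <)."""
    if not len(pairs):
        raise ParameterError("needs at least one pair")
    sep = np.array([p.separation for p in pairs])
    return [float(np.mean(sep < t)) for t in thresholds_nm]


def larger_event_position_test(pairs: Sequence[MvrPair]) -> TestResult:
    """Chi-square test of 'larger member is proximal' against a 50/50 null.

    Amplitude- or distance-tied pairs are excluded; fewer than 10 untied
    pairs is an error.
    """
    untied = [p for p in pairs if not (p.amplitude_tie or p.distance_tie)]
    if len(untied) < 10:
        raise ParameterError("needs at least 10 untied pairs")
    n_prox = sum(p.larger_is_proximal for p in untied)
    n = len(untied)
    chi2, p = sps.chisquare([n_prox, n - n_prox])
    return TestResult(
        test_name="chi2", statistic=float(chi2), p_value=float(p), df=1.0,
        extra={"n_larger_proximal": int(n_prox), "n_pairs": int(n),
               "fraction_larger_proximal": n_prox / n},
    )


def double_event_train_trend(events: pd.DataFrame,
                             n_boutons: int | None = None) -> RegressionFit:
    """Regression of per-stimulus double-event probability on stimulus index.

    ``events`` must carry bouton_id, stimulus_index and pair_id columns
    (pair_id empty/NaN for UVR). For each stimulus index the double-event
    probability is the number of boutons showing an MVR pair at that
    stimulus divided by the number of boutons observed (``n_boutons``,
    default: the number of distinct boutons in the table).
    """
    for col in ("bouton_id", "stimulus_index", "pair_id"):
        if col not in events.columns:
            raise ParameterError(f"events table lacks column {col!r}")
    idx = np.sort(events["stimulus_index"].unique())
    if len(idx) < 2:
        raise ParameterError("needs events at >= 2 distinct stimulus indices")
    nb = n_boutons or events["bouton_id"].nunique()
    paired = events[events["pair_id"].notna() & (events["pair_id"] != "")]
    doubles = (
        paired.groupby("stimulus_index")["pair_id"].nunique()
        .reindex(idx, fill_value=0)
    )
    p = doubles.to_numpy(dtype=float) / nb
    return _ols(p, idx.astype(float))


def asynchronous_amplitude_control(
    sync_amplitudes: np.ndarray, async_amplitudes: np.ndarray
) -> TestResult:
    """Two-sample KS test of synchronous vs asynchronous event amplitudes.

    Asynchronous (strontium-evoked) fusions occur at random times within
    the frame, so their amplitude distribution is left-shifted and skewed
    relative to stimulus-locked release; medians are reported alongside.
    """
    sync = np.asarray(sync_amplitudes, dtype=float)
    asyn = np.asarray(async_amplitudes, dtype=float)
    if sync.size < 20 or asyn.size < 20:
        raise ParameterError("both samples need n >= 20")
    ks = sps.ks_2samp(sync, asyn)
    return TestResult(
        test_name="ks2",
        statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        extra={"median_sync": float(np.median(sync)),
               "median_async": float(np.median(asyn))},
    )


_PAIR_COLUMNS = [
    "pair_id", "bouton_id", "stimulus_index", "x_a", "y_a", "x_b", "y_b",
    "amp_a", "amp_b", "separation_nm", "amp_diff_pct", "larger_is_proximal",
    "midpoint_dist_to_center_nm",
]


def pairs_to_table(pairs: Sequence[MvrPair]) -> pd.DataFrame:
    rows = [
        {
            "pair_id": p.pair_id,
            "bouton_id": p.bouton_id,
            "stimulus_index": p.stimulus_index,
            "x_a": p.xy_a[0], "y_a": p.xy_a[1],
            "x_b": p.xy_b[0], "y_b": p.xy_b[1],
            "amp_a": p.amp_a, "amp_b": p.amp_b,
            "separation_nm": p.separation,
            "amp_diff_pct": p.amp_diff_pct,
            "larger_is_proximal": p.larger_is_proximal,
            "midpoint_dist_to_center_nm": p.midpoint_dist_to_center,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=_PAIR_COLUMNS)
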
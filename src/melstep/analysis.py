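"""Spike-train analysis: detection, rate summaries, latencies, thresholds.

The analysis mirrors standard practice for step-response experiments on
sorted single units:

* units are called light-responsive by a paired two-tailed t-test of
  baseline-window versus step-window firing rates across trials;
* response magnitude is the delta firing rate (mean step-window rate minus
  mean baseline-window rate);
* onset/offset latencies are threshold crossings of the trial-averaged rate
  against the line one baseline standard deviation above the baseline mean;
* grouped comparisons use two-way repeated-measures ANOVA (unit as the
  blocking factor) with Bonferroni-corrected pairwise phase comparisons;
* irradiance trackers are called by a positive, significant Spearman rank
  correlation between per-segment firing rate and log background flux;
* threshold irradiance is the dimmest level with a significant (Bonferroni
  across levels) step response, reported separately for the rising and
  falling arms of a ramp.

Latency estimation uses 100-ms PSTH bins smoothed with a 3-bin moving
average; coarser trial-bin-count bins (5 s) are kept for display matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RateEstimate",
    "LatencyResult",
    "RMAnovaResult",
    "ScanResult",
    "psth",
    "trial_bin_count",
    "normalise_tbc",
    "window_rates",
    "aligned_step_rates",
    "classify_responsive",
    "delta_firing_rate",
    "response_latencies",
    "latency_rate",
    "rm_anova",
    "isoluminance_scan",
    "irradiance_tracking",
    "threshold_irradiance",
    "adaptation_shift",
]

ALPHA_DEFAULT = 0.05
LATENCY_BIN_S = 0.1
LATENCY_SMOOTH_BINS = 3


@dataclass(frozen=True)
class RateEstimate:
    """A binned firing-rate estimate (mean and SEM across trials)."""

    bin_centres: np.ndarray
    rate: np.ndarray
    sem: np.ndarray
    bin_s: float
    smoothing: str = "none"


@dataclass(frozen=True)
class LatencyResult:
    onset_s: float | None
    offset_s: float | None
    threshold_hz: float
    degenerate_threshold: bool = False


@dataclass(frozen=True)
class RMAnovaResult:
    table: pd.DataFrame  # per-effect F, df, p
    posthoc: pd.DataFrame  # per-condition paired phase comparison, Bonferroni

    def f(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


@dataclass(frozen=True)
class ScanResult:
    amplitudes: Mapping[str, float]
    p_values: Mapping[str, float]
    null_setting: str | None
    excluded: bool


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def _event_counts(
    trains: Sequence[np.ndarray],
    event_times: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    """Counts matrix over (trial x event) rows and time bins, event-aligned."""
    rows = []
    for train in trains:
        train = np.asarray(train, dtype=float)
        for ev in np.atleast_1d(event_times):
            rows.append(np.histogram(train - ev, bins=edges)[0])
    return np.asarray(rows, dtype=float)


def psth(
    trains: Sequence[np.ndarray],
    event_times: np.ndarray,
    window: tuple[float, float] = (-30.0, 60.0),
    bin_s: float = LATENCY_BIN_S,
) -> RateEstimate:
    """Peri-event rate histogram: mean +/- SEM across aligned trials.

    ``trains`` holds one continuous spike-time array per recording trial;
    every (trial, event) pair contributes one aligned sweep.
    """
    if len(trains) == 0 or np.size(event_times) == 0:
        raise ValueError("psth needs at least one trial and one event")
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts = _event_counts(trains, np.atleast_1d(event_times), edges)
    rates = counts / bin_s
    mean = rates.mean(axis=0)
    sem = rates.std(axis=0, ddof=1) / np.sqrt(rates.shape[0]) if rates.shape[0] > 1 else np.zeros_like(mean)
    centres = edges[:-1] + bin_s / 2.0
    return RateEstimate(centres, mean, sem, bin_s)


def trial_bin_count(
    trains: Sequence[np.ndarray],
    event_times: np.ndarray,
    window: tuple[float, float],
    bin_s: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trials x time-bins firing-rate matrix (Hz), event-aligned.

    Returns (matrix, bin_centres); rows are (trial, event) sweeps.
    """
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts = _event_counts(trains, np.atleast_1d(event_times), edges)
    return counts / bin_s, edges[:-1] + bin_s / 2.0


def normalise_tbc(matrix: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale a trial-bin-count matrix to maximum 1; flags an all-zero matrix."""
    peak = float(matrix.max(initial=0.0))
    if peak <= 0:
        return matrix.copy(), True
    return matrix / peak, False


def window_rates(
    trains: Sequence[np.ndarray],
    event_times: np.ndarray,
    window: tuple[float, float],
) -> np.ndarray:
    """Mean rate (Hz) in an event-relative window per (trial, event) sweep."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive length")
    events = np.atleast_1d(event_times)
    out = np.empty(len(trains) * events.size)
    k = 0
    for train in trains:
        train = np.asarray(train, dtype=float)
        i0 = np.searchsorted(train, events + lo)
        i1 = np.searchsorted(train, events + hi)
        out[k : k + events.size] = (i1 - i0) / (hi - lo)
        k += events.size
    return out


def aligned_step_rates(
    trains: Sequence[np.ndarray],
    event_times: np.ndarray,
    baseline_s: float = 30.0,
    step_s: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(baseline, step) window rates aligned to step onsets, per sweep."""
    baseline = window_rates(trains, event_times, (-baseline_s, 0.0))
    step = window_rates(trains, event_times, (0.0, step_s))
    return baseline, step


# ---------------------------------------------------------------------------
# detection and magnitude
# ---------------------------------------------------------------------------


def classify_responsive(
    baseline: np.ndarray, step: np.ndarray, alpha: float = ALPHA_DEFAULT
) -> tuple[float, bool]:
    """Paired two-tailed t-test of baseline vs step rates across trials.

    Returns (p, responsive). With zero variance in the paired differences the
    test is degenerate: p is 1.0 for a zero mean difference (not responsive)
    and 0.0 for a consistent non-zero difference.
    """
    baseline = np.asarray(baseline, dtype=float)
    step = np.asarray(step, dtype=float)
    if baseline.shape != step.shape or baseline.size < 2:
        raise ValueError("need >= 2 paired trials")
    diffs = step - baseline
    if np.ptp(diffs) == 0:
        p = 1.0 if diffs[0] == 0 else 0.0
    else:
        p = float(stats.ttest_rel(step, baseline).pvalue)
    return p, bool(p < alpha)


def delta_firing_rate(baseline: np.ndarray, step: np.ndarray) -> float:
    """Mean step-window rate minus mean baseline-window rate (Hz)."""
    return float(np.mean(step) - np.mean(baseline))


# ---------------------------------------------------------------------------
# latency
# ---------------------------------------------------------------------------


def latency_rate(
    trains: Sequence[np.ndarray],
    event_times: np.ndarray,
    window: tuple[float, float],
    bin_s: float = LATENCY_BIN_S,
    smooth_bins: int = LATENCY_SMOOTH_BINS,
) -> RateEstimate:
    """Trial-averaged rate on a fine grid for latency estimation.

    100-ms bins with a centred 3-bin moving average by default: fine enough
    to resolve sub-second latencies, smoothed enough to stabilise the
    baseline-SD threshold.
    """
    est = psth(trains, event_times, window, bin_s)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        sm = np.convolve(est.rate, kernel, mode="same")
        est = RateEstimate(est.bin_centres, sm, est.sem, bin_s, f"boxcar{smooth_bins}")
    return est


def response_latencies(
    est: RateEstimate,
    baseline_window: tuple[float, float],
    step_onset_s: float,
    step_offset_s: float,
) -> LatencyResult:
    """Onset/offset latency from the 1-SD-above-baseline threshold line.

    Onset: first bin centre after stimulus onset with rate above
    ``mean(baseline) + SD(baseline)``; offset: first bin centre after
    stimulus offset with rate back below the line. Baseline statistics are
    taken across the baseline time bins of the averaged rate. Missing
    crossings are reported as None, never fabricated; a zero baseline SD is
    flagged and the mean alone is used as the line.
    """
    lo, hi = baseline_window
    if not lo < hi <= step_onset_s:
        raise ValueError("baseline window must precede the step onset")
    t = est.bin_centres
    base = est.rate[(t >= lo) & (t < hi)]
    if base.size < 2:
        raise ValueError("baseline window contains fewer than two bins")
    sd = float(np.std(base, ddof=1))
    degenerate = sd == 0.0
    threshold = float(np.mean(base)) + sd

    onset = None
    after_on = (t > step_onset_s) & (t <= step_offset_s)
    above = after_on & (est.rate > threshold)
    if np.any(above):
        onset = float(t[above][0] - step_onset_s)

    offset = None
    after_off = t > step_offset_s
    below = after_off & (est.rate < threshold)
    if np.any(below):
        offset = float(t[below][0] - step_offset_s)

    return LatencyResult(onset, offset, threshold, degenerate)


# ---------------------------------------------------------------------------
# grouped statistics
# ---------------------------------------------------------------------------


def rm_anova(
    data: pd.DataFrame,
    dv: str = "rate",
    subject: str = "unit",
    phase: str = "phase",
    condition: str = "condition",
) -> RMAnovaResult:
    """Two-way repeated-measures ANOVA with Bonferroni phase post-hocs.

    ``data`` is a long-format table with one observation per
    (subject, phase, condition) cell; a complete balanced table is required
    (no imputation). The post-hoc compares the two phases within each
    condition by paired t-test, multiplying p by the number of conditions
    (capped at 1).
    """
    from statsmodels.stats.anova import AnovaRM

    counts = data.groupby([subject, phase, condition]).size()
    if (counts != 1).any():
        raise ValueError("table must contain exactly one observation per cell")
    n_cells = data[phase].nunique() * data[condition].nunique()
    per_subject = data.groupby(subject).size()
    if (per_subject != n_cells).any():
        raise ValueError("table must be complete and balanced across subjects")

    fit = AnovaRM(data, depvar=dv, subject=subject, within=[phase, condition]).fit()
    tab = fit.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"}
    )

    conditions = sorted(data[condition].unique())
    phases = sorted(data[phase].unique())
    if len(phases) != 2:
        raise ValueError("post-hoc comparisons require exactly two phases")
    rows = []
    for cond in conditions:
        sub = data[data[condition] == cond].pivot(index=subject, columns=phase, values=dv)
        a, b = sub[phases[0]].to_numpy(), sub[phases[1]].to_numpy()
        if np.ptp(b - a) == 0:
            p = 1.0 if (b - a)[0] == 0 else 0.0
            tval = np.inf if p == 0.0 else 0.0
        else:
            res = stats.ttest_rel(b, a)
            tval, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "condition": cond,
                "t": tval,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * len(conditions)),
            }
        )
    return RMAnovaResult(tab, pd.DataFrame(rows).set_index("condition"))


# ---------------------------------------------------------------------------
# calibration scan, tracking, thresholds
# ---------------------------------------------------------------------------


def isoluminance_scan(
    setting_responses: Mapping[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = ALPHA_DEFAULT,
) -> ScanResult:
    """Locate the effective rod-isoluminant setting in a flicker scan.

    ``setting_responses`` maps each blue-LED setting label to
    (background rates, flash rates) across flicker cycles. The flicker
    response amplitude is the absolute mean flash-background rate
    difference. The null setting is the amplitude minimum, provided its
    response is non-significant; a unit significant at every setting is
    excluded (no isoluminant point found).
    """
    amplitudes: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for label, (bg, flash) in setting_responses.items():
        amplitudes[label] = abs(float(np.mean(flash) - np.mean(bg)))
        p_values[label], _ = classify_responsive(bg, flash, alpha)
    best = min(amplitudes, key=lambda k: amplitudes[k])
    excluded = all(p < alpha for p in p_values.values())
    null_setting = None if excluded else best if p_values[best] >= alpha else None
    if null_setting is None and not excluded:
        # minimum significant but some other setting is not: take the
        # non-significant setting with the smallest amplitude
        candidates = [k for k, p in p_values.items() if p >= alpha]
        null_setting = min(candidates, key=lambda k: amplitudes[k])
    return ScanResult(amplitudes, p_values, null_setting, excluded)


def irradiance_tracking(
    segment_rates: np.ndarray,
    log_flux: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[bool, float, float, float]:
    """Does firing rate track log background irradiance across ramp segments?

    Returns (tracker, rho, p, slope): ``tracker`` is True when the Spearman
    rank correlation between per-segment mean rate and log flux is
    significant at ``alpha`` with positive slope (Hz per log unit, by least
    squares).
    """
    segment_rates = np.asarray(segment_rates, dtype=float)
    log_flux = np.asarray(log_flux, dtype=float)
    if segment_rates.size != log_flux.size or segment_rates.size < 4:
        raise ValueError("need >= 4 matched segments")
    if np.ptp(segment_rates) == 0:
        return False, 0.0, 1.0, 0.0
    rho, p = stats.spearmanr(log_flux, segment_rates)
    slope = float(np.polyfit(log_flux, segment_rates, 1)[0])
    return bool(p < alpha and slope > 0), float(rho), float(p), slope


def threshold_irradiance(
    levels: Mapping[float, tuple[np.ndarray, np.ndarray]],
    alpha: float = ALPHA_DEFAULT,
    bonferroni: bool = True,
) -> tuple[float | None, pd.DataFrame]:
    """Dimmest level (log flux) with a significant step response.

    ``levels`` maps each background log flux to (baseline, step) rate arrays
    pooled over trials (and, for population-level estimates, units). The
    per-level p-value is Bonferroni-multiplied by the number of levels when
    ``bonferroni`` is set. Returns (threshold or None, per-level table).
    """
    n = len(levels)
    rows = []
    for log_f in sorted(levels):
        baseline, step = levels[log_f]
        p, _ = classify_responsive(baseline, step, alpha)
        p_adj = min(1.0, p * n) if bonferroni else p
        rows.append(
            {
                "log_flux": log_f,
                "delta_hz": delta_firing_rate(baseline, step),
                "p": p,
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha and delta_firing_rate(baseline, step) > 0),
            }
        )
    table = pd.DataFrame(rows).set_index("log_flux")
    sig = table.index[table["significant"]]
    return (float(sig.min()) if len(sig) else None), table


def adaptation_shift(threshold_up: float | None, threshold_down: float | None) -> float | None:
    """Down-arm minus up-arm threshold, in log units; None if either is undefined."""
    if threshold_up is None or threshold_down is None:
        return None
    return float(threshold_down - threshold_up)
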
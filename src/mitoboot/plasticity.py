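"""Scoring of extracellular field-potential (FP) plasticity experiments.

A recording consists of evoked FP peak amplitudes sampled at a nominal
0.1 Hz through three phases: a 10-min pre-conditioning baseline, a
conditioning period (high-frequency stimulation; no evoked samples
analysed), and a 60-min post-conditioning period.  Scoring follows the
standard slice-electrophysiology workflow:

* baseline gate — a recording is discarded when the OLS line through all
  pre-conditioning amplitudes has r^2 > 0.2 (an unstable baseline);
* post/pre ratio — mean amplitude of the last 5 min of post-conditioning
  divided by the mean of the last 5 min of pre-conditioning;
* classification — LTD when the ratio is a significant decrease > 10%
  (ratio < 0.90, p < 0.05), LTP when a significant increase > 10%
  (ratio > 1.10, p < 0.05), otherwise no change.  Significance is a
  Welch two-sample comparison of the two 5-min windows.
* time plots — amplitudes normalised to the pre-phase mean and averaged
  in 1-min blocks (6 samples at 0.1 Hz).

Input/output curves are summarised by the half-maximal response and the
stimulation intensity at which linear interpolation first crosses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FPTrace",
    "PlasticityOutcome",
    "IOCurve",
    "baseline_ok",
    "post_pre_ratio",
    "classify_outcome",
    "bin_timeplot",
    "halfmax_io",
    "score_trace",
]

PHASE_PRE = "pre"
PHASE_COND = "conditioning"
PHASE_POST = "post"
_PHASE_ORDER = {PHASE_PRE: 0, PHASE_COND: 1, PHASE_POST: 2}

LTD = "LTD"
LTP = "LTP"
NO_CHANGE = "no_change"

#: classification thresholds: +/-10% around baseline, alpha 0.05
RATIO_LOW = 0.90
RATIO_HIGH = 1.10
ALPHA = 0.05


@dataclass
class FPTrace:
    """Evoked FP peak-amplitude series with per-sample phase markers."""

    time_s: np.ndarray
    amplitude_uv: np.ndarray
    phase: np.ndarray
    slice_id: str = "slice"
    genotype: str = ""
    pathway: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.amplitude_uv = np.asarray(self.amplitude_uv, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time_s) == len(self.amplitude_uv) == len(self.phase)):
            raise ValueError("time, amplitude and phase must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.amplitude_uv < 0):
            raise ValueError("amplitudes must be non-negative")
        unknown = set(self.phase) - set(_PHASE_ORDER)
        if unknown:
            raise ValueError(f"unknown phase markers: {sorted(unknown)}")
        codes = np.array([_PHASE_ORDER[p] for p in self.phase])
        if np.any(np.diff(codes) < 0):
            raise ValueError("phases must be ordered pre -> conditioning -> post")

    def samples(self, phase: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.phase == phase
        return self.time_s[mask], self.amplitude_uv[mask]


@dataclass
class PlasticityOutcome:
    """Post/pre ratio, its significance, and (optionally) the label."""

    post_pre_ratio: float
    p_value: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.post_pre_ratio <= 0:
            raise ValueError("post/pre ratio must be positive")


@dataclass
class IOCurve:
    """Stimulus-response (input/output) curve of evoked FP amplitudes."""

    intensity_ua: np.ndarray
    amplitude_uv: np.ndarray

    def __post_init__(self) -> None:
        self.intensity_ua = np.asarray(self.intensity_ua, dtype=float)
        self.amplitude_uv = np.asarray(self.amplitude_uv, dtype=float)
        if len(self.intensity_ua) != len(self.amplitude_uv):
            raise ValueError("intensity and amplitude must have equal length")
        if np.any(np.diff(self.intensity_ua) <= 0):
            raise ValueError("intensities must be strictly increasing")


def baseline_ok(trace: FPTrace, r2_threshold: float = 0.2) -> tuple[bool, float]:
    """Gate on baseline stability: OLS r^2 over all pre samples <= threshold.

    A perfectly constant baseline has zero total variance; its r^2 is
    defined as 0 (pass).  Requires at least 10 pre-phase samples.
    """
    t, amp = trace.samples(PHASE_PRE)
    if len(t) < 10:
        raise ValueError(f"need >= 10 pre-conditioning samples, got {len(t)}")
    if np.ptp(amp) == 0:
        return True, 0.0
    result = stats.linregress(t, amp)
    r2 = float(result.rvalue**2)
    return r2 <= r2_threshold, r2


def _last_window(t: np.ndarray, amp: np.ndarray, window_s: float) -> np.ndarray:
    span = t[-1] - t[0]
    # sampling is 0.1 Hz, so a full 5-min window spans 290 s between its
    # first and last sample; require the phase to cover the window
    if span < window_s - (t[1] - t[0] if len(t) > 1 else 0.0):
        raise ValueError(
            f"phase spans {span:.0f}s; need >= {window_s:.0f}s for the window"
        )
    return amp[t > t[-1] - window_s]


def post_pre_ratio(trace: FPTrace, window_s: float = 300.0) -> PlasticityOutcome:
    """Ratio of mean amplitudes: last ``window_s`` of post over last of pre.

    The p-value is a Welch two-sample comparison of the two windows
    (about 30 samples each at 0.1 Hz).
    """
    t_pre, amp_pre = trace.samples(PHASE_PRE)
    t_post, amp_post = trace.samples(PHASE_POST)
    if len(t_pre) == 0 or len(t_post) == 0:
        raise ValueError("trace must contain pre and post samples")
    w_pre = _last_window(t_pre, amp_pre, window_s)
    w_post = _last_window(t_post, amp_post, window_s)
    ratio = float(w_post.mean() / w_pre.mean())
    if np.ptp(w_pre) == 0 and np.ptp(w_post) == 0:
        # degenerate noiseless windows: identical -> no evidence of change
        p = 1.0 if w_pre.mean() == w_post.mean() else 0.0
    else:
        p = float(stats.ttest_ind(w_post, w_pre, equal_var=False).pvalue)
    return PlasticityOutcome(post_pre_ratio=ratio, p_value=p)


def classify_outcome(outcome: PlasticityOutcome) -> str:
    """Apply the LTD / no-change / LTP rule and set the label in place."""
    significant = outcome.p_value < ALPHA
    if significant and outcome.post_pre_ratio < RATIO_LOW:
        outcome.label = LTD
    elif significant and outcome.post_pre_ratio > RATIO_HIGH:
        outcome.label = LTP
    else:
        outcome.label = NO_CHANGE
    return outcome.label


def score_trace(trace: FPTrace) -> dict:
    """Full per-slice scoring: baseline gate, ratio, p-value, label."""
    ok, r2 = baseline_ok(trace)
    row = {
        "slice_id": trace.slice_id,
        "genotype": trace.genotype,
        "pathway": trace.pathway,
        "r2_baseline": r2,
        "discarded": not ok,
        "ratio": np.nan,
        "p_value": np.nan,
        "label": "",
    }
    if ok:
        outcome = post_pre_ratio(trace)
        classify_outcome(outcome)
        row.update(
            ratio=outcome.post_pre_ratio,
            p_value=outcome.p_value,
            label=outcome.label,
        )
    return row


def _block_means(x: np.ndarray, block: int) -> np.ndarray:
    """Means of consecutive blocks; a trailing partial block is averaged
    over the samples it has."""
    n_full = len(x) // block
    out = []
    if n_full:
        out.append(x[: n_full * block].reshape(n_full, block).mean(axis=1))
    if len(x) % block:
        out.append([x[n_full * block :].mean()])
    return np.concatenate(out) if out else np.array([])


def bin_timeplot(trace: FPTrace, samples_per_bin: int = 6) -> pd.DataFrame:
    """1-min binned, baseline-normalised time plot.

    Amplitudes are divided by the mean of the whole pre-conditioning phase
    and averaged in consecutive blocks of ``samples_per_bin`` samples
    (6 samples = 1 min at 0.1 Hz), separately within the pre and post
    phases so the conditioning gap does not blur bins.
    """
    _, amp_pre = trace.samples(PHASE_PRE)
    if len(amp_pre) == 0:
        raise ValueError("trace has no pre-conditioning samples")
    baseline = amp_pre.mean()
    if baseline <= 0:
        raise ValueError("pre-conditioning mean must be positive")
    frames = []
    for phase in (PHASE_PRE, PHASE_POST):
        t, amp = trace.samples(phase)
        if len(t) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "time_s": _block_means(t, samples_per_bin),
                    "norm_amplitude": _block_means(amp / baseline, samples_per_bin),
                    "phase": phase,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def halfmax_io(curve: IOCurve) -> tuple[float, float]:
    """Half-maximal amplitude and the intensity of its first crossing.

    The half-max amplitude is max(response)/2; the crossing intensity is
    found by piecewise-linear interpolation between the first bracketing
    pair of sampled points (or an exact sample hit).
    """
    if len(curve.intensity_ua) < 3:
        raise ValueError("need >= 3 intensity points")
    amp = curve.amplitude_uv
    inten = curve.intensity_ua
    half = float(amp.max() / 2.0)
    for i in range(len(amp)):
        if amp[i] == half:
            return half, float(inten[i])
        if i + 1 < len(amp) and (amp[i] - half) * (amp[i + 1] - half) < 0:
            frac = (half - amp[i]) / (amp[i + 1] - amp[i])
            return half, float(inten[i] + frac * (inten[i + 1] - inten[i]))
    raise ValueError("response never crosses half-max between sampled points")
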
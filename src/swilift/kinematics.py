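"""Reach and lift kinematics from raw tracker streams.

Processing chain per trial: dual-pass zero-phase Butterworth low-pass on
each position axis, numerical differentiation to velocity, threshold-based
segmentation of the reach (hand speed) and the lift (hand + object speed up
to the object's apex), then peak-velocity metrics:

* MRV — maximum resultant hand speed within the reach phase, and its timing
  as a percentage of reach movement time;
* MLV — maximum resultant object speed within the lift phase, and its
  timing as a percentage of lift movement time.

Trials whose speed profile never satisfies the segmentation rule are
flagged invalid with a reason rather than raising, so batch processing can
report exclusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ORDER = 2
DEFAULT_THRESHOLD_MM_S = 50.0
DEFAULT_CONSECUTIVE = 3

STREAM_COLUMNS = [
    "trial_id",
    "time_s",
    "wrist_x_mm",
    "wrist_y_mm",
    "wrist_z_mm",
    "obj_x_mm",
    "obj_y_mm",
    "obj_z_mm",
]

_WRIST = ["wrist_x_mm", "wrist_y_mm", "wrist_z_mm"]
_OBJ = ["obj_x_mm", "obj_y_mm", "obj_z_mm"]


@dataclass
class KinematicMetrics:
    """Per-trial reach/lift outcome; timings are % of phase movement time."""

    trial_id: str
    valid: bool
    failure_reason: str | None = None
    reach_onset_idx: int | None = None
    reach_offset_idx: int | None = None
    lift_onset_idx: int | None = None
    lift_end_idx: int | None = None
    mrv_mm_s: float = np.nan
    t_mrv_pct: float = np.nan
    mlv_mm_s: float = np.nan
    t_mlv_pct: float = np.nan


def sampling_rate(time_s: np.ndarray) -> float:
    """Median sampling rate (Hz) of a time vector."""
    dt = np.diff(np.asarray(time_s, dtype=float))
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError("time vector must be strictly increasing")
    return 1.0 / float(np.median(dt))


def lowpass_dual_pass(
    positions: np.ndarray,
    fs_hz: float,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order_per_pass: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass: one forward and one backward Butterworth pass.

    ``order_per_pass`` is the order of each single pass (default 2, so the
    combined response is 4th-order-equivalent in magnitude).  No cutoff
    correction is applied for the double pass.  Edges are padded by
    reflection, pad length three times the per-pass order.
    """
    if cutoff_hz >= fs_hz / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {fs_hz / 2.0} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    x = np.asarray(positions, dtype=float)
    b, a = butter(order_per_pass, cutoff_hz, btype="low", fs=fs_hz)
    padlen = min(3 * order_per_pass, x.shape[0] - 1)
    return filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def filter_stream(
    stream: pd.DataFrame,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order_per_pass: int = DEFAULT_ORDER,
) -> pd.DataFrame:
    """Apply the dual-pass low-pass to all six position columns of one trial."""
    out = stream.copy()
    fs = sampling_rate(out["time_s"].to_numpy())
    for col in _WRIST + _OBJ:
        out[col] = lowpass_dual_pass(out[col].to_numpy(), fs, cutoff_hz, order_per_pass)
    return out


def differentiate(positions: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    """Velocity by differencing position w.r.t. time.

    Central differences in the interior, one-sided at the edges (numpy
    gradient).  ``positions`` may be (n,) or (n, 3); returns same shape.
    """
    t = np.asarray(time_s, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    return np.gradient(np.asarray(positions, dtype=float), t, axis=0)


def resultant_speed(velocity: np.ndarray) -> np.ndarray:
    """Euclidean norm of a (n, 3) velocity array, mm/s."""
    return np.linalg.norm(np.atleast_2d(velocity), axis=-1)


def _first_run_start(mask: np.ndarray, k: int, start: int = 0) -> int | None:
    """First index i >= start at which ``mask`` holds for k consecutive samples."""
    count = 0
    for i in range(start, len(mask)):
        count = count + 1 if mask[i] else 0
        if count == k:
            return i - k + 1
    return None


def segment_reach(
    hand_speed: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MM_S,
    k: int = DEFAULT_CONSECUTIVE,
) -> tuple[int | None, int | None, str | None]:
    """Reach onset/offset by the consecutive-frames velocity rule.

    Onset: start of the first run of >= k samples strictly above threshold.
    Offset: start of the first run of >= k samples strictly below threshold
    beginning after the onset.  Returns (onset, offset, failure_reason);
    indices are 0-based, reason is None on success.
    """
    speed = np.asarray(hand_speed, dtype=float)
    onset = _first_run_start(speed > threshold, k)
    if onset is None:
        return None, None, "no_reach_onset"
    offset = _first_run_start(speed < threshold, k, start=onset + 1)
    if offset is None:
        return onset, None, "no_reach_offset"
    return onset, offset, None


def segment_lift(
    hand_speed: np.ndarray,
    object_speed: np.ndarray,
    object_z: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD_MM_S,
    k: int = DEFAULT_CONSECUTIVE,
    search_from: int = 0,
) -> tuple[int | None, int | None, str | None]:
    """Lift onset and end.

    Onset: the later of the first >= k-sample above-threshold run starts of
    hand and object speed (searched from ``search_from``).  End: first
    index of the maximum object height at or after the onset.
    """
    hand = np.asarray(hand_speed, dtype=float)
    obj = np.asarray(object_speed, dtype=float)
    z = np.asarray(object_z, dtype=float)
    h_start = _first_run_start(hand > threshold, k, start=search_from)
    o_start = _first_run_start(obj > threshold, k, start=search_from)
    if h_start is None or o_start is None:
        return None, None, "no_lift_onset"
    onset = max(h_start, o_start)
    if int(np.argmax(z)) < onset:
        return onset, None, "apex_before_lift_onset"
    end = onset + int(np.argmax(z[onset:]))
    return onset, end, None


def _peak_in_window(
    speed: np.ndarray, time_s: np.ndarray, i0: int, i1: int
) -> tuple[float, float]:
    """Max speed in [i0, i1] and its timing as % of window duration (earliest tie)."""
    window = speed[i0 : i1 + 1]
    j = int(np.argmax(window))
    peak = float(window[j])
    span = time_s[i1] - time_s[i0]
    pct = 100.0 * (time_s[i0 + j] - time_s[i0]) / span if span > 0 else 0.0
    return peak, float(pct)


def compute_metrics(
    stream: pd.DataFrame,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order_per_pass: int = DEFAULT_ORDER,
    threshold: float = DEFAULT_THRESHOLD_MM_S,
    k: int = DEFAULT_CONSECUTIVE,
    prefiltered: bool = False,
) -> KinematicMetrics:
    """Full per-trial chain: filter, differentiate, segment, peak metrics.

    The lift onset is searched from the reach offset onwards, so the reach
    itself cannot double as the lift's above-threshold hand run.
    """
    trial_id = str(stream["trial_id"].iloc[0]) if "trial_id" in stream else ""
    if len(stream) < 30:
        return KinematicMetrics(trial_id, False, "too_few_samples")
    s = stream if prefiltered else filter_stream(stream, cutoff_hz, order_per_pass)
    t = s["time_s"].to_numpy()
    hand_v = differentiate(s[_WRIST].to_numpy(), t)
    obj_v = differentiate(s[_OBJ].to_numpy(), t)
    hand_speed = resultant_speed(hand_v)
    obj_speed = resultant_speed(obj_v)

    r_on, r_off, reason = segment_reach(hand_speed, threshold, k)
    if reason is not None:
        return KinematicMetrics(trial_id, False, reason, r_on, r_off)
    l_on, l_end, reason = segment_lift(
        hand_speed, obj_speed, s["obj_z_mm"].to_numpy(), threshold, k, search_from=r_off
    )
    if reason is not None:
        return KinematicMetrics(trial_id, False, reason, r_on, r_off, l_on, l_end)
    if l_end == l_on:
        return KinematicMetrics(
            trial_id, False, "degenerate_lift_window", r_on, r_off, l_on, l_end
        )

    mrv, t_mrv = _peak_in_window(hand_speed, t, r_on, r_off)
    mlv, t_mlv = _peak_in_window(obj_speed, t, l_on, l_end)
    return KinematicMetrics(
        trial_id, True, None, r_on, r_off, l_on, l_end, mrv, t_mrv, mlv, t_mlv
    )


def metrics_table(
    streams: pd.DataFrame,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order_per_pass: int = DEFAULT_ORDER,
    threshold: float = DEFAULT_THRESHOLD_MM_S,
    k: int = DEFAULT_CONSECUTIVE,
) -> pd.DataFrame:
    """Compute metrics for every trial in a long-format streams table."""
    rows = []
    for tid, group in streams.groupby("trial_id", sort=True):
        m = compute_metrics(
            group.reset_index(drop=True), cutoff_hz, order_per_pass, threshold, k
        )
        rows.append(
            {
                "trial_id": tid,
                "mrv_mm_s": m.mrv_mm_s,
                "t_mrv_pct": m.t_mrv_pct,
                "mlv_mm_s": m.mlv_mm_s,
                "t_mlv_pct": m.t_mlv_pct,
                "valid": m.valid,
                "failure_reason": m.failure_reason or "",
            }
        )
    return pd.DataFrame(rows)
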
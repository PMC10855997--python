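"""Saccade detection and task scoring.

Velocity-threshold saccade detection on horizontal gaze traces, task-specific
trial scoring (latency, directional errors, final eye position) and the
binocular versional dysconjugacy index (VDI) computed from prosaccade
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import EyeTrace, TaskSpec

#: Saccades starting sooner than this after the go signal are treated as
#: anticipatory and ignored for VG/AS/MG.  The endogenously cued task has no
#: lower cutoff: the predictive cue legitimately permits very short latencies.
ANTICIPATORY_CUTOFF_MS = 80.0


@dataclass(frozen=True)
class DetectionParams:
    """Velocity-threshold detection settings (video-oculography defaults)."""

    velocity_threshold: float = 30.0       # deg/s
    min_duration_ms: float = 8.0
    min_amplitude_deg: float = 0.5
    merge_gap_ms: float = 20.0
    smoothing_halfwidth_samples: int = 2   # 5-sample moving average
    offset_floor: float = 10.0             # deg/s; stops the event extension

    def __post_init__(self):
        if self.velocity_threshold <= 0 or self.min_duration_ms <= 0 \
                or self.min_amplitude_deg <= 0 or self.merge_gap_ms <= 0:
            raise ValueError("detection parameters must be positive")
        if self.smoothing_halfwidth_samples < 0:
            raise ValueError("smoothing halfwidth must be >= 0")


@dataclass(frozen=True)
class SaccadeEvent:
    """One detected saccade."""

    onset_ms: float
    offset_ms: float
    amplitude: float        # signed, degrees
    peak_velocity: float    # deg/s, unsigned
    direction: str          # "left" | "right"

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")


@dataclass
class TrialScore:
    """Outcome of one scored trial."""

    trial: int
    is_error: bool = False
    no_response: bool = False
    latency_ms: float = float("nan")
    fep: float = float("nan")


def velocity_trace(pos: np.ndarray, dt_ms: float,
                   halfwidth: int = 2) -> np.ndarray:
    """Smoothed central-difference velocity in deg/s.

    Position is first smoothed with a ``2*halfwidth + 1`` moving average
    (edges use shrinking windows), then differentiated centrally; the two
    boundary samples use one-sided differences.
    """
    p = np.asarray(pos, dtype=float)
    n = len(p)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if halfwidth > 0:
        w = 2 * halfwidth + 1
        kern = np.ones(w) / w
        padded = np.concatenate([np.full(halfwidth, p[0]), p,
                                 np.full(halfwidth, p[-1])])
        p = np.convolve(padded, kern, mode="valid")
    v = np.empty(n)
    v[1:-1] = (p[2:] - p[:-2]) / (2 * dt_ms) * 1000.0
    v[0] = (p[1] - p[0]) / dt_ms * 1000.0
    v[-1] = (p[-1] - p[-2]) / dt_ms * 1000.0
    return v


def _extend_to_minimum(speed: np.ndarray, i0: int, i1: int,
                       floor: float = 10.0) -> tuple[int, int]:
    """Extend the sample run [i0, i1] outward to the nearest local minima
    of the speed profile.

    Extension stops early once speed drops below ``floor`` so that slow
    post-saccadic drift (e.g. the adduction glissade of a dysconjugate
    saccade) is not absorbed into the event.
    """
    while i0 > 0 and speed[i0 - 1] < speed[i0] and speed[i0] >= floor:
        i0 -= 1
    n = len(speed)
    while i1 < n - 1 and speed[i1 + 1] < speed[i1] and speed[i1] >= floor:
        i1 += 1
    return i0, i1


def detect_saccades(time_ms: np.ndarray, pos: np.ndarray,
                    params: DetectionParams | None = None) -> list[SaccadeEvent]:
    """Detect saccades in one eye channel by velocity thresholding.

    Consecutive samples with speed at or above the threshold form candidate
    events, each extended outward to the nearest local speed minima;
    events separated by less than ``merge_gap_ms`` are merged; events
    shorter than ``min_duration_ms`` or smaller than ``min_amplitude_deg``
    are dropped.  Events are returned ordered by onset.
    """
    params = params or DetectionParams()
    time_ms = np.asarray(time_ms, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if len(time_ms) < 3:
        raise ValueError("need at least 3 samples")
    steps = np.diff(time_ms)
    dt = steps[0]
    if not np.allclose(steps, dt):
        raise ValueError("trace must be uniformly sampled")

    speed = np.abs(velocity_trace(pos, dt, params.smoothing_halfwidth_samples))
    above = speed >= params.velocity_threshold
    if not above.any():
        return []

    # contiguous runs of supra-threshold samples
    runs = []
    idx = np.flatnonzero(above)
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    # extend to local speed minima
    runs = [_extend_to_minimum(speed, a, b, params.offset_floor)
            for a, b in runs]

    # merge events closer than merge_gap
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if (a - pb) * dt < params.merge_gap_ms:
            merged[-1] = (pa, max(pb, b))
        else:
            merged.append((a, b))

    events = []
    for a, b in merged:
        dur = (b - a) * dt
        amp = pos[b] - pos[a]
        if dur < params.min_duration_ms or abs(amp) < params.min_amplitude_deg:
            continue
        events.append(SaccadeEvent(
            onset_ms=float(time_ms[a]), offset_ms=float(time_ms[b]),
            amplitude=float(amp),
            peak_velocity=float(speed[a:b + 1].max()),
            direction="right" if amp > 0 else "left"))
    return events


def detect_saccades_trace(trace: EyeTrace, eye: str = "right",
                          params: DetectionParams | None = None,
                          ) -> list[SaccadeEvent]:
    """Detect saccades on one eye channel of a binocular trace."""
    pos = trace.right_pos if eye == "right" else trace.left_pos
    return detect_saccades(trace.time, pos, params)


# --------------------------------------------------------------------------
# Trial scoring
# --------------------------------------------------------------------------

def _first_event(events, t_from, t_to):
    for ev in events:
        if t_from < ev.onset_ms <= t_to:
            return ev
    return None


def _gaze_at(time_ms, pos, t):
    i = int(np.clip(np.searchsorted(time_ms, t), 0, len(time_ms) - 1))
    return float(pos[i])


def score_trial(task_id: str, annotation, events: list[SaccadeEvent],
                time_ms: np.ndarray | None = None,
                pos: np.ndarray | None = None) -> TrialScore:
    """Score one trial from its detected saccades.

    ``annotation`` is a mapping/row with ``trial``, ``target_deg``,
    ``go_ms``, ``stim_onset_ms``, ``fix_off_ms`` and ``response_end_ms``.
    Scoring rules:

    * **VG** -- latency of the first target-directed saccade after target
      onset; a wrong-direction first saccade invalidates the trial.
    * **AS** -- error if the first post-target saccade is toward the
      peripheral cross; otherwise latency of the first mirror-direction
      saccade, with final eye position measured against the mirror target.
    * **MG** -- error if any saccade larger than 2 degrees toward the
      target occurs before fixation offset; otherwise latency of the first
      post-offset saccade toward the remembered location, with final eye
      position against the remembered target.
    * **EC** -- error if the first post-target saccade is opposite the
      target; otherwise latency of the first target-directed saccade (no
      anticipatory cutoff).

    A trial with no saccade in the response window is flagged
    ``no_response`` (excluded from both latency and the error numerator,
    counted in the trial total).  Final eye position is the relative
    landing error, ``100 * |gaze(end) - goal| / |target amplitude|``, on
    correct AS/MG trials when the raw channel is supplied.
    """
    target = float(annotation["target_deg"])
    go = float(annotation["go_ms"])
    resp_end = float(annotation["response_end_ms"])
    trial = int(annotation["trial"])
    tsign = 1.0 if target > 0 else -1.0
    cutoff = 0.0 if task_id == "EC" else ANTICIPATORY_CUTOFF_MS

    score = TrialScore(trial=trial)

    if task_id == "MG":
        stim_on = float(annotation["stim_onset_ms"])
        fix_off = float(annotation["fix_off_ms"])
        for ev in events:
            if stim_on < ev.onset_ms <= fix_off and abs(ev.amplitude) > 2.0 \
                    and np.sign(ev.amplitude) == tsign:
                score.is_error = True
                break

    first = _first_event(events, go + cutoff, resp_end)
    if first is None:
        if not score.is_error:
            score.no_response = True
        return score

    goal = -target if task_id == "AS" else target
    gsign = 1.0 if goal > 0 else -1.0
    toward_goal = np.sign(first.amplitude) == gsign

    if task_id == "VG":
        if toward_goal:
            score.latency_ms = first.onset_ms - go
        else:
            score.is_error = True
    elif task_id == "AS":
        if np.sign(first.amplitude) == tsign:
            score.is_error = True
        else:
            score.latency_ms = first.onset_ms - go
    elif task_id == "EC":
        if np.sign(first.amplitude) == -tsign:
            score.is_error = True
        else:
            score.latency_ms = first.onset_ms - go
    else:  # MG
        if score.is_error:
            pass
        elif toward_goal:
            score.latency_ms = first.onset_ms - go
        else:
            score.is_error = True

    if task_id in ("AS", "MG") and not score.is_error \
            and not score.no_response and time_ms is not None:
        final = _gaze_at(time_ms, pos, resp_end)
        score.fep = 100.0 * abs(final - goal) / abs(target)
    return score


def score_task(trace: EyeTrace, spec_or_id, eye: str = "right",
               params: DetectionParams | None = None) -> pd.DataFrame:
    """Detect and score every trial of a task recording.

    Detection runs per trial segment so refixation movements of one trial
    never bleed into the next.  Returns one row per trial.
    """
    task_id = spec_or_id.task_id if isinstance(spec_or_id, TaskSpec) \
        else str(spec_or_id)
    pos = trace.right_pos if eye == "right" else trace.left_pos
    rows = []
    for ann in trace.annotations.to_dict("records"):
        sel = (trace.time >= ann["trial_start_ms"]) & \
              (trace.time < ann["trial_end_ms"])
        t = trace.time[sel]
        p = pos[sel]
        events = detect_saccades(t, p, params) if len(t) >= 3 else []
        s = score_trial(task_id, ann, events, time_ms=t, pos=p)
        rows.append({"task": task_id, "trial": s.trial,
                     "is_error": s.is_error, "no_response": s.no_response,
                     "latency_ms": s.latency_ms, "fep": s.fep})
    return pd.DataFrame(rows)


def summarize_participant(scored: pd.DataFrame) -> dict[str, float]:
    """Aggregate per-trial scores into the ocular-motor indicator subset.

    Error rates are percentages of total administered trials; latency is
    the mean over correct trials; final eye position the mean over trials
    with a measured landing.  Tasks with zero administered trials yield no
    entries (missing, not zero).
    """
    out: dict[str, float] = {}
    for task, grp in scored.groupby("task"):
        n = len(grp)
        if n == 0:
            continue
        lat = grp.loc[~grp.is_error & ~grp.no_response, "latency_ms"].dropna()
        if len(lat):
            out[f"{task}_LATENCY"] = float(lat.mean())
        if task in ("AS", "MG", "EC"):
            out[f"{task}_ERROR"] = 100.0 * float(grp.is_error.sum()) / n
        if task in ("AS", "MG"):
            fep = grp.fep.dropna()
            if len(fep):
                out[f"{task}_FEP"] = float(fep.mean())
    return out


# --------------------------------------------------------------------------
# Versional dysconjugacy index
# --------------------------------------------------------------------------

def compute_vdi(trace: EyeTrace, params: DetectionParams | None = None,
                basis: str = "velocity") -> tuple[float, float]:
    """Dysconjugacy ratios from a binocular prosaccade recording.

    For every rightward primary saccade the ratio of the abducting (right)
    eye's peak velocity to the adducting (left) eye's is taken; ``VDI_R``
    is the mean ratio over rightward trials, ``VDI_L`` the symmetric
    leftward index with the eyes' roles swapped.  ``basis="amplitude"``
    uses amplitude ratios instead.  A direction with no valid saccades
    yields ``nan`` for its index.
    """
    if basis not in ("velocity", "amplitude"):
        raise ValueError("basis must be 'velocity' or 'amplitude'")
    ratios: dict[str, list[float]] = {"R": [], "L": []}
    for ann in trace.annotations.to_dict("records"):
        sel = (trace.time >= ann["trial_start_ms"]) & \
              (trace.time < ann["trial_end_ms"])
        if sel.sum() < 3:
            continue
        t = trace.time[sel]
        go = ann["go_ms"]
        resp_end = ann["response_end_ms"]
        tsign = np.sign(ann["target_deg"])
        per_eye = {}
        for eye, pos in (("left", trace.left_pos[sel]),
                         ("right", trace.right_pos[sel])):
            evs = detect_saccades(t, pos, params)
            ev = _first_event(evs, go + ANTICIPATORY_CUTOFF_MS, resp_end)
            if ev is not None and np.sign(ev.amplitude) == tsign:
                per_eye[eye] = ev
        if len(per_eye) < 2:
            continue
        lv, rv = per_eye["left"], per_eye["right"]
        if basis == "velocity":
            num, den = rv.peak_velocity, lv.peak_velocity
        else:
            num, den = abs(rv.amplitude), abs(lv.amplitude)
        if tsign > 0:          # rightward: right eye abducts
            ratios["R"].append(num / den)
        else:                  # leftward: left eye abducts
            ratios["L"].append(den / num)
    vdi_r = float(np.mean(ratios["R"])) if ratios["R"] else float("nan")
    vdi_l = float(np.mean(ratios["L"])) if ratios["L"] else float("nan")
    return vdi_r, vdi_l


def extract_participant_metrics(traces: dict[str, EyeTrace],
                                eye: str = "right",
                                params: DetectionParams | None = None,
                                ) -> dict[str, float]:
    """Full ocular-motor indicator set for one participant.

    Scores every administered task monocularly (``eye``; the right eye by
    convention) and adds the binocular dysconjugacy indices from the
    visually guided task when present.
    """
    frames = [score_task(tr, tid, eye=eye, params=params)
              for tid, tr in traces.items()]
    out = summarize_participant(pd.concat(frames)) if frames else {}
    if "VG" in traces:
        vdi_r, vdi_l = compute_vdi(traces["VG"], params=params)
        out["VDI_R"] = vdi_r
        out["VDI_L"] = vdi_l
    return out
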
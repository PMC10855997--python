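"""Synthetic visuo-cognitive cohort generator.

Generates phenotype-labelled cohorts of early multiple-sclerosis patients and
healthy controls with the statistical structure the downstream phenotyping
pipeline assumes: four ocular-motor task designs (visually guided, antisaccade,
memory-guided and endogenously cued saccades), a main-sequence saccade
generator with controllable latency, directional errors, final-eye-position
error and binocular dysconjugacy, an afferent table (global RNFL thickness,
Snellen acuity) and phenotype-conditional z-score shifts for the 12 analysis
indicators.

Two generation paths are provided:

* **trace path** -- per-trial binocular horizontal gaze traces at 500 Hz,
  consumed by :mod:`oculopheno.saccades` exactly as recorded data would be;
* **indicator path** -- the 12 indicators drawn directly on the raw scale
  (``control_anchor mean + z_shift * control_anchor SD`` per phenotype),
  used for large-sample factor-structure and mixture-recovery runs where
  sample-level trace synthesis adds nothing.

Both paths honour the same phenotype calibration: per-profile standardized
mean shifts on every indicator, with mixing proportions 100:12:12:16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Indicator catalogue and phenotype calibration
# --------------------------------------------------------------------------

#: The 12 analysis indicators, in canonical column order.
INDICATORS = [
    "RNFL",
    "VG_LATENCY",
    "EC_LATENCY",
    "AS_LATENCY",
    "MG_LATENCY",
    "EC_ERROR",
    "AS_ERROR",
    "MG_ERROR",
    "AS_FEP",
    "MG_FEP",
    "VDI_R",
    "VDI_L",
]

#: Ocular-motor indicators (z-scored against the control sample).
OM_INDICATORS = INDICATORS[1:]

#: The 10 ocular-motor indicators entering the factor analysis
#: (RNFL and the two VDI variables excluded).
EFA_INDICATORS = [
    "VG_LATENCY", "EC_LATENCY", "AS_LATENCY", "MG_LATENCY",
    "EC_ERROR", "AS_ERROR", "MG_ERROR", "AS_FEP", "MG_FEP",
]

#: Indicators masked together when the memory-guided task is not administered.
MG_INDICATORS = ["MG_LATENCY", "MG_ERROR", "MG_FEP"]

#: Published per-profile standardized mean shifts for the four phenotypes
#: (indicator order = ``INDICATORS``), with profile sizes 100:12:12:16.
PROFILE_Z_SHIFTS: dict[str, list[float]] = {
    "early_visual_changes": [
        -0.809, 0.676, -0.097, -0.144, -0.387,
        0.997, 0.739, 0.723, 0.830, -0.241, -0.234, 0.175,
    ],
    "efferent_cognitive": [
        -0.921, 1.347, 0.089, 0.290, -0.273,
        1.362, 3.681, 1.953, 2.941, 0.496, 6.519, 0.999,
    ],
    "cognitive_control": [
        -0.921, 0.818, 0.261, 0.650, 0.681,
        2.770, 7.415, 3.826, 3.231, -0.116, -0.797, -0.122,
    ],
    "afferent_processing_speed": [
        -1.085, 1.440, 2.609, 1.156, 1.116,
        0.670, 0.393, 0.717, 2.286, 0.239, 0.261, -0.096,
    ],
}

PROFILE_COUNTS = {
    "early_visual_changes": 100,
    "efferent_cognitive": 12,
    "cognitive_control": 12,
    "afferent_processing_speed": 16,
}

#: Raw-scale control anchors (mean, SD) used to map z-space shifts onto raw
#: metrics.  Calibrated so healthy-control medians land near published
#: control descriptives (e.g. VG latency ~170 ms, VDI ~1.03); these are
#: generator plumbing, not normative ground truth.
DEFAULT_ANCHORS: dict[str, tuple[float, float]] = {
    "RNFL": (97.0, 10.0),
    "VG_LATENCY": (172.0, 25.0),
    "EC_LATENCY": (245.0, 60.0),
    "AS_LATENCY": (290.0, 80.0),
    "MG_LATENCY": (330.0, 90.0),
    "EC_ERROR": (6.0, 3.0),
    "AS_ERROR": (8.0, 3.0),
    "MG_ERROR": (12.0, 5.0),
    "AS_FEP": (21.0, 6.0),
    "MG_FEP": (14.0, 5.0),
    "VDI_R": (1.03, 0.06),
    "VDI_L": (1.04, 0.06),
}

#: Phenotype-conditional mean age / SDMT used for demographic post-hocs.
_PROFILE_AGE = {
    "early_visual_changes": 38.72,
    "efferent_cognitive": 47.78,
    "cognitive_control": 46.73,
    "afferent_processing_speed": 41.48,
}
_PROFILE_SDMT = {
    "early_visual_changes": 63.0,
    "efferent_cognitive": 50.0,
    "cognitive_control": 50.0,
    "afferent_processing_speed": 62.0,
}
_PROFILE_FEMALE = {
    "early_visual_changes": 0.82,
    "efferent_cognitive": 0.83,
    "cognitive_control": 0.83,
    "afferent_processing_speed": 0.88,
}
_PROFILE_CDMS = {
    "early_visual_changes": 0.56,
    "efferent_cognitive": 0.92,
    "cognitive_control": 0.83,
    "afferent_processing_speed": 0.81,
}

#: Snellen acuity categories, phenotype-independent (no acuity differences
#: between profiles are simulated).
_SNELLEN_LEVELS = [(6, 4.8), (6, 6), (6, 7.5), (6, 9.5), (6, 12)]
_SNELLEN_PROBS = [0.15, 0.55, 0.18, 0.08, 0.04]

# Main-sequence constants: peak velocity = VMAX * (1 - exp(-A / AMP_C)).
VMAX = 500.0    # deg/s
AMP_C = 14.0    # deg


# --------------------------------------------------------------------------
# Task specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskTiming:
    """Per-task event schedule, all durations in milliseconds."""

    fixation_ms: float = 800.0
    cue_ms: float = 0.0
    delay_ms: tuple[float, ...] = ()
    response_ms: float = 800.0
    feedback_ms: float = 0.0
    refixation_ms: float = 500.0

    def __post_init__(self):
        for name in ("fixation_ms", "response_ms", "refixation_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TaskSpec:
    """Design of one ocular-motor task.

    ``VG``: prosaccade to a target at 5 or 10 deg left/right (24 trials).
    ``AS``: antisaccade away from the peripheral cross (48 trials).
    ``MG``: saccade to the remembered location after a 1500/2500 ms delay.
    ``EC``: saccade to a target predicted by a central arrow cue valid on
    75% of trials (48 trials).
    """

    task_id: str
    n_trials: int
    eccentricities: tuple[float, ...] = (5.0, 10.0)
    directions: tuple[str, ...] = ("left", "right")
    timing: TaskTiming = field(default_factory=TaskTiming)
    cue_validity: float | None = None

    def __post_init__(self):
        if self.task_id not in {"VG", "AS", "MG", "EC"}:
            raise ValueError(f"unknown task_id {self.task_id!r}")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if self.cue_validity is not None and not 0 <= self.cue_validity <= 1:
            raise ValueError("cue_validity must lie in [0, 1]")


def default_task_specs() -> dict[str, TaskSpec]:
    """The four task designs with their published trial counts.

    The memory-guided trial count is not fixed by the task diagrams; 24
    trials is the package default (configurable).
    """
    return {
        "VG": TaskSpec("VG", 24),
        "AS": TaskSpec("AS", 48),
        "MG": TaskSpec(
            "MG", 24,
            timing=TaskTiming(fixation_ms=800.0, cue_ms=500.0,
                              delay_ms=(1500.0, 2500.0), feedback_ms=500.0),
        ),
        "EC": TaskSpec(
            "EC", 48, cue_validity=0.75,
            timing=TaskTiming(fixation_ms=850.0, cue_ms=500.0),
        ),
    }


# --------------------------------------------------------------------------
# Cohort configuration
# --------------------------------------------------------------------------

@dataclass
class PhenotypeParams:
    """Generating parameters of one latent phenotype."""

    phenotype_id: str
    prevalence: float
    z_shift: dict[str, float]
    error_prob: dict[str, float] = field(default_factory=dict)
    dysconjugacy_gain: float = 1.0
    rnfl_mean: float = 97.0
    rnfl_sd: float = 10.0

    def __post_init__(self):
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        for task, p in self.error_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"error_prob[{task}] outside [0, 1]")
        if self.dysconjugacy_gain < 1:
            raise ValueError("dysconjugacy_gain must be >= 1")


@dataclass
class CohortConfig:
    """Full configuration of a synthetic cohort."""

    n_patients: int
    n_controls: int
    phenotypes: list[PhenotypeParams]
    sampling_rate: float = 500.0
    control_anchors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS))
    noise_sd: float = 0.1
    seed: int = 0
    tasks: dict[str, TaskSpec] = field(default_factory=default_task_specs)

    def __post_init__(self):
        if self.n_patients < 0 or self.n_controls < 0:
            raise ValueError("participant counts must be non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for name, (mu, sd) in self.control_anchors.items():
            if sd <= 0:
                raise ValueError(f"control anchor SD for {name} must be > 0")
        total = sum(p.prevalence for p in self.phenotypes)
        if self.phenotypes and abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"phenotype prevalences sum to {total!r}, expected 1")


def make_default_config(n_patients: int, n_controls: int,
                        seed: int) -> CohortConfig:
    """Cohort configuration calibrated to the four published phenotypes.

    The four z-shift vectors equal the published per-profile standardized
    mean estimates; prevalences follow the published profile sizes
    100/140, 12/140, 12/140 and 16/140.
    """
    if n_patients < 0 or n_controls < 0:
        raise ValueError("participant counts must be non-negative")
    total = sum(PROFILE_COUNTS.values())
    phenos = []
    for name, zs in PROFILE_Z_SHIFTS.items():
        z = dict(zip(INDICATORS, zs))
        rnfl_mu, rnfl_sd = DEFAULT_ANCHORS["RNFL"]
        phenos.append(PhenotypeParams(
            phenotype_id=name,
            prevalence=PROFILE_COUNTS[name] / total,
            z_shift=z,
            error_prob={
                "AS": _clip01((DEFAULT_ANCHORS["AS_ERROR"][0]
                               + z["AS_ERROR"] * DEFAULT_ANCHORS["AS_ERROR"][1]) / 100),
                "MG": _clip01((DEFAULT_ANCHORS["MG_ERROR"][0]
                               + z["MG_ERROR"] * DEFAULT_ANCHORS["MG_ERROR"][1]) / 100),
                "EC": _clip01((DEFAULT_ANCHORS["EC_ERROR"][0]
                               + z["EC_ERROR"] * DEFAULT_ANCHORS["EC_ERROR"][1]) / 100),
            },
            dysconjugacy_gain=max(
                1.0, DEFAULT_ANCHORS["VDI_R"][0]
                + z["VDI_R"] * DEFAULT_ANCHORS["VDI_R"][1]),
            rnfl_mean=rnfl_mu + z["RNFL"] * rnfl_sd,
            rnfl_sd=rnfl_sd,
        ))
    return CohortConfig(n_patients=n_patients, n_controls=n_controls,
                        phenotypes=phenos, seed=seed)


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


# --------------------------------------------------------------------------
# Eye traces
# --------------------------------------------------------------------------

@dataclass
class EyeTrace:
    """Binocular horizontal gaze recording of one task run.

    ``time`` is uniformly sampled in ms; positions are horizontal gaze
    angles in degrees, positive rightward.  ``annotations`` carries one row
    per trial: target position, event onsets and the response window, plus
    the planted ground truth (``true_*`` columns) used by round-trip tests.
    """

    time: np.ndarray
    left_pos: np.ndarray
    right_pos: np.ndarray
    annotations: pd.DataFrame
    task_id: str
    sampling_rate: float = 500.0
    participant_id: str = ""

    def __post_init__(self):
        if len(self.left_pos) != len(self.right_pos) or \
                len(self.time) != len(self.left_pos):
            raise ValueError("time/left/right lengths differ")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if not np.allclose(steps, 1000.0 / self.sampling_rate):
                raise ValueError("time must be uniform at 1000/sampling_rate")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (one row per sample)."""
        n = len(self.time)
        trial = np.full(n, -1)
        for row in self.annotations.itertuples():
            sel = (self.time >= row.trial_start_ms) & (self.time < row.trial_end_ms)
            trial[sel] = row.trial
        return pd.DataFrame({
            "time_ms": self.time,
            "left_deg": self.left_pos,
            "right_deg": self.right_pos,
            "task": self.task_id,
            "trial": trial,
            "participant_id": self.participant_id,
        })


@dataclass
class TraceParams:
    """Per-participant planted behaviour for one task run.

    Scalars apply to every trial; ``trial_overrides`` may pin per-trial
    latency (ms), error flags or target amplitudes for oracle tests.
    """

    latency_ms: float = 180.0
    latency_sd: float = 20.0
    error_prob: float = 0.0
    no_response_prob: float = 0.0
    fep_frac_sd: float = 0.05     # SD of relative landing error
    vdi_r_gain: float = 1.0       # adducting-eye slowing, rightward saccades
    vdi_l_gain: float = 1.0       # adducting-eye slowing, leftward saccades
    noise_sd: float = 0.0         # positional noise SD, degrees
    reflexive_latency_ms: float = 160.0
    trial_overrides: dict | None = None

    def __post_init__(self):
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be >= 0")
        if not 0 <= self.error_prob <= 1:
            raise ValueError("error_prob outside [0, 1]")
        if min(self.vdi_r_gain, self.vdi_l_gain) < 1:
            raise ValueError("dysconjugacy gains must be >= 1")


def main_sequence_peak_velocity(amplitude: float) -> float:
    """Saccadic peak velocity (deg/s) for a given amplitude (deg)."""
    return VMAX * (1.0 - np.exp(-abs(amplitude) / AMP_C))


def _saccade_duration_ms(amplitude: float) -> float:
    # raised-cosine profile: vpeak = pi * A / (2 D)
    vp = main_sequence_peak_velocity(amplitude)
    return 1000.0 * np.pi * abs(amplitude) / (2.0 * vp)


def _add_command(pos: np.ndarray, t: np.ndarray, t0: float, delta: float,
                 duration: float, gain: float = 1.0,
                 drift_tau_ms: float = 100.0) -> None:
    """Superimpose one saccade command on ``pos`` in place.

    The primary movement is a raised-cosine step of size ``delta / gain``
    over ``duration`` ms (so peak velocity scales with 1/gain); when
    ``gain > 1`` the residual ``delta * (1 - 1/gain)`` is completed by an
    exponential post-saccadic drift, emulating the slowed adducting eye of
    internuclear ophthalmoplegia.
    """
    x = (t - t0) / duration
    prim = np.where(x <= 0, 0.0,
                    np.where(x >= 1, 1.0, 0.5 * (1 - np.cos(np.pi * np.clip(x, 0, 1)))))
    pos += (delta / gain) * prim
    if gain > 1:
        rem = delta * (1 - 1 / gain)
        td = t - (t0 + duration)
        pos += rem * np.where(td <= 0, 0.0, 1 - np.exp(-np.clip(td, 0, None) / drift_tau_ms))


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  window: int = 10) -> np.ndarray:
    """Temporally correlated positional noise (boxcar-filtered white noise)."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    raw = rng.normal(size=n + window)
    kernel = np.ones(window) / window
    sm = np.convolve(raw, kernel, mode="valid")[:n]
    return sm * (sd / np.std(sm)) if np.std(sm) > 0 else np.zeros(n)


def simulate_saccade_trace(spec: TaskSpec, params: TraceParams,
                           seed: int, sampling_rate: float = 500.0,
                           participant_id: str = "") -> EyeTrace:
    """Generate a binocular gaze trace for one task run.

    Per trial, the primary saccade onset equals stimulus (or go-signal)
    onset plus the planted latency; its amplitude is the planted target
    amplitude times (1 + landing error).  With ``noise_sd = 0`` the planted
    values are recovered exactly by the detection oracle.  Error trials are
    simulated mechanistically: a reflexive look at the forbidden target
    (AS), a look at the cue during the delay (MG) or a cue-congruent
    wrong-direction saccade (EC), each followed by a corrective movement.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_rate
    tm = spec.timing
    overrides = params.trial_overrides or {}

    seg_left, seg_right, rows = [], [], []
    t_cursor = 0.0
    ecc = np.array(spec.eccentricities, dtype=float)
    for k in range(spec.n_trials):
        ov = overrides.get(k, {})
        amp = float(ov.get("eccentricity", rng.choice(ecc)))
        sign = float(ov.get("direction", rng.choice([-1.0, 1.0])))
        target = sign * amp

        is_error = bool(ov.get("is_error",
                               rng.random() < params.error_prob))
        if spec.task_id == "VG":
            is_error = False      # the prosaccade task has no error rule
        no_resp = bool(ov.get("no_response",
                              rng.random() < params.no_response_prob))
        lat = float(ov.get("latency_ms", max(
            90.0, rng.normal(params.latency_ms, params.latency_sd))))
        refl = max(90.0, rng.normal(params.reflexive_latency_ms, 15.0))
        fep_eps = float(ov.get("fep_frac", rng.normal(0.0, params.fep_frac_sd)))

        # -- event schedule -------------------------------------------------
        if spec.task_id in ("VG", "AS"):
            stim_on = tm.fixation_ms
            go = stim_on
            fix_off = stim_on
            resp_end = go + tm.response_ms
            trial_dur = resp_end + tm.refixation_ms
        elif spec.task_id == "EC":
            cue_on = tm.fixation_ms
            stim_on = cue_on + tm.cue_ms
            go = stim_on
            fix_off = stim_on
            resp_end = go + tm.response_ms
            trial_dur = resp_end + tm.refixation_ms
        else:  # MG
            cue_on = tm.fixation_ms
            delay = float(ov.get("delay_ms", rng.choice(np.array(tm.delay_ms))))
            stim_on = cue_on                      # remembered cue
            fix_off = cue_on + tm.cue_ms + delay  # go signal
            go = fix_off
            resp_end = go + tm.response_ms
            trial_dur = resp_end + tm.feedback_ms + tm.refixation_ms

        n = int(round(trial_dur / dt))
        t = np.arange(n) * dt
        left = np.zeros(n)
        right = np.zeros(n)

        def cmd(t0, frm, to):
            """Conjugate saccade from position ``frm`` to ``to`` at ``t0``."""
            delta = to - frm
            if abs(delta) < 1e-9:
                return
            dur = _saccade_duration_ms(delta)
            if delta > 0:     # rightward: left eye adducts
                gl, gr = params.vdi_r_gain, 1.0
            else:             # leftward: right eye adducts
                gl, gr = 1.0, params.vdi_l_gain
            _add_command(left, t, t0, delta, dur, gain=gl)
            _add_command(right, t, t0, delta, dur, gain=gr)

        landing = target * (1 + fep_eps)
        cur = 0.0
        true_lat = np.nan
        if spec.task_id == "VG":
            if not no_resp:
                cmd(go + lat, 0.0, landing)
                cur = landing
                true_lat = lat
        elif spec.task_id == "AS":
            mirror = -target * (1 + fep_eps)
            if no_resp:
                pass
            elif is_error:
                cmd(go + refl, 0.0, target)
                cmd(go + refl + 300.0, target, mirror)
                cur = mirror
            else:
                cmd(go + lat, 0.0, mirror)
                cur = mirror
                true_lat = lat
        elif spec.task_id == "EC":
            valid = bool(ov.get("cue_valid",
                                rng.random() < (spec.cue_validity or 1.0)))
            if no_resp:
                pass
            elif is_error:
                cmd(go + refl, 0.0, -target)
                cmd(go + refl + 300.0, -target, landing)
                cur = landing
            else:
                cmd(go + lat, 0.0, landing)
                cur = landing
                true_lat = lat
        else:  # MG
            if is_error:
                # forbidden look at the cue during the delay
                peek_t = cue_on + refl
                cmd(peek_t, 0.0, target)
                cmd(peek_t + 400.0, target, 0.0)
            if not no_resp:
                cmd(go + lat, 0.0, landing)
                cur = landing
                if not is_error:
                    true_lat = lat

        if abs(cur) > 1e-9:   # refixation saccade back to centre
            cmd(resp_end + 150.0, cur, 0.0)

        left += _smooth_noise(rng, n, params.noise_sd)
        right += _smooth_noise(rng, n, params.noise_sd)

        rows.append({
            "trial": k,
            "target_deg": target,
            "stim_onset_ms": t_cursor + stim_on,
            "go_ms": t_cursor + go,
            "fix_off_ms": t_cursor + fix_off,
            "response_end_ms": t_cursor + resp_end,
            "trial_start_ms": t_cursor,
            "trial_end_ms": t_cursor + trial_dur,
            "true_latency_ms": true_lat,
            "true_error": is_error,
            "true_no_response": no_resp,
            "true_fep_frac": abs(fep_eps),
        })
        seg_left.append(left)
        seg_right.append(right)
        t_cursor += trial_dur

    n_total = int(round(t_cursor / dt))
    time = np.arange(n_total) * dt
    left_all = np.concatenate(seg_left) if seg_left else np.zeros(0)
    right_all = np.concatenate(seg_right) if seg_right else np.zeros(0)
    # rounding of per-trial sample counts can differ by one sample in total
    m = min(len(time), len(left_all))
    return EyeTrace(time=time[:m], left_pos=left_all[:m],
                    right_pos=right_all[:m],
                    annotations=pd.DataFrame(rows), task_id=spec.task_id,
                    sampling_rate=sampling_rate,
                    participant_id=participant_id)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass
class Cohort:
    """A labelled synthetic cohort.

    ``metrics`` carries the per-participant indicator table on the raw
    scale plus demographics; ``labels`` the true generating phenotype
    (``control`` for controls); ``traces`` (optional) maps participant id
    to its four task traces.
    """

    metrics: pd.DataFrame
    labels: pd.Series
    config: CohortConfig
    traces: dict[str, dict[str, EyeTrace]] = field(default_factory=dict)


def _draw_participant_raw(rng, anchors, z_shift):
    """Raw indicator values for one participant.

    Every indicator has expectation ``anchor mean + z_shift * anchor SD``
    and within-phenotype standard deviation ``anchor SD`` (unit SD on the
    z scale).  Values are Gaussian with physiological bounds placed far
    from the bulk of every generating distribution, so the z-space
    structure is preserved essentially undistorted.
    """
    raw = {}
    for name in INDICATORS:
        mu, sd = anchors[name]
        val = mu + (z_shift.get(name, 0.0) + rng.normal()) * sd
        if name.endswith("ERROR") or name.endswith("FEP"):
            val = float(np.clip(val, 0.0, 100.0))
        elif name.endswith("LATENCY"):
            val = float(max(90.0, val))
        elif name.startswith("VDI"):
            val = float(max(0.5, val))
        else:  # RNFL
            val = float(max(30.0, val))
        raw[name] = val
    return raw


def simulate_cohort(config: CohortConfig, include_traces: bool = False,
                    trace_participants: int | None = None) -> Cohort:
    """Draw a phenotype-labelled cohort under ``config``.

    Each patient is assigned a phenotype by prevalence; per-indicator raw
    expectations equal ``anchor mean + z_shift * anchor SD``; controls are
    drawn with zero shift.  Deterministic under a fixed ``config.seed``.

    When ``include_traces`` is set, binocular task traces are synthesized
    whose planted behaviour matches each participant's drawn indicator
    values (``trace_participants`` caps how many participants get traces;
    default all).
    """
    total = sum(p.prevalence for p in config.phenotypes)
    if config.phenotypes and abs(total - 1.0) > 1e-9:
        raise ValueError("phenotype prevalences must sum to 1")
    rng = np.random.default_rng(config.seed)
    anchors = config.control_anchors

    rows, labels = [], []
    prev = np.array([p.prevalence for p in config.phenotypes])
    names = [p.phenotype_id for p in config.phenotypes]
    assignment = rng.choice(len(names), size=config.n_patients, p=prev) \
        if config.n_patients else np.zeros(0, dtype=int)

    for i in range(config.n_patients):
        pheno = config.phenotypes[assignment[i]]
        raw = _draw_participant_raw(rng, anchors, pheno.z_shift)
        pid = f"P{i:04d}"
        rows.append(_demographics(rng, pid, pheno.phenotype_id, raw))
        labels.append(pheno.phenotype_id)
    for i in range(config.n_controls):
        raw = _draw_participant_raw(rng, anchors, {})
        pid = f"C{i:04d}"
        row = _demographics(rng, pid, None, raw)
        rows.append(row)
        labels.append("control")

    if rows:
        metrics = pd.DataFrame(rows).set_index("participant_id")
    else:
        metrics = pd.DataFrame(
            columns=INDICATORS + ["group", "age", "sex", "SDMT", "BDI",
                                  "NART", "EDSS", "symptom_duration",
                                  "snellen_num", "snellen_den"])
        metrics.index.name = "participant_id"
    labels = pd.Series(labels, index=metrics.index, name="phenotype")

    traces: dict[str, dict[str, EyeTrace]] = {}
    if include_traces:
        cap = trace_participants if trace_participants is not None \
            else len(metrics)
        child_seeds = np.random.SeedSequence(config.seed).spawn(len(metrics))
        for j, (pid, row) in enumerate(metrics.iterrows()):
            if j >= cap:
                break
            traces[pid] = _participant_traces(
                config, row, child_seeds[j])
    return Cohort(metrics=metrics, labels=labels, config=config,
                  traces=traces)


def _demographics(rng, pid, pheno_id, raw):
    row = {"participant_id": pid}
    row.update(raw)
    if pheno_id is None:
        row["group"] = "control"
        row["age"] = float(np.clip(rng.normal(34.2, 13.1), 19, 66))
        row["sex"] = "F" if rng.random() < 0.64 else "M"
        row["SDMT"] = float(rng.normal(65.7, 12.1))
        row["BDI"] = float(max(0.0, rng.normal(3.1, 2.3)))
        row["NART"] = float(rng.normal(118.2, 3.5))
        row["EDSS"] = np.nan
        row["symptom_duration"] = np.nan
        row["RNFL"] = np.nan          # OCT not administered to controls
    else:
        cdms = rng.random() < _PROFILE_CDMS.get(pheno_id, 0.6)
        row["group"] = "CDMS" if cdms else "CIS"
        row["age"] = float(np.clip(
            rng.normal(_PROFILE_AGE.get(pheno_id, 40.0), 10.0), 19, 66))
        row["sex"] = "F" if rng.random() < _PROFILE_FEMALE.get(pheno_id, 0.8) \
            else "M"
        row["SDMT"] = float(rng.normal(_PROFILE_SDMT.get(pheno_id, 60.0),
                                       10.0))
        row["BDI"] = float(max(0.0, rng.normal(7.1, 6.5)))
        row["NART"] = float(rng.normal(114.5, 5.8))
        row["EDSS"] = float(np.clip(rng.normal(0.8, 1.0), 0, 6.5))
        row["symptom_duration"] = float(max(
            0.0, rng.gamma(1.2, 60.0 if cdms else 15.0)))
    num, den = _SNELLEN_LEVELS[rng.choice(len(_SNELLEN_LEVELS),
                                          p=_SNELLEN_PROBS)]
    row["snellen_num"] = num
    row["snellen_den"] = den
    return row


def _participant_traces(config, row, seed_seq):
    """Build the four task traces planting this participant's raw metrics."""
    seeds = seed_seq.generate_state(4)
    out = {}
    for s, (task_id, spec) in zip(seeds, config.tasks.items()):
        p = TraceParams(
            latency_ms={"VG": row["VG_LATENCY"], "AS": row["AS_LATENCY"],
                        "MG": row["MG_LATENCY"], "EC": row["EC_LATENCY"]}[task_id],
            latency_sd=20.0,
            error_prob={"VG": 0.0, "AS": row["AS_ERROR"] / 100,
                        "MG": row["MG_ERROR"] / 100,
                        "EC": row["EC_ERROR"] / 100}[task_id],
            fep_frac_sd={"VG": 0.05,
                         "AS": row["AS_FEP"] / 100 / np.sqrt(2 / np.pi),
                         "MG": row["MG_FEP"] / 100 / np.sqrt(2 / np.pi),
                         "EC": 0.05}[task_id],
            vdi_r_gain=max(1.0, row["VDI_R"]),
            vdi_l_gain=max(1.0, row["VDI_L"]),
            noise_sd=config.noise_sd,
        )
        out[task_id] = simulate_saccade_trace(
            spec, p, seed=int(s % (2 ** 31)),
            sampling_rate=config.sampling_rate,
            participant_id=str(row.name))
    return out


# --------------------------------------------------------------------------
# MAR missingness of the memory-guided task
# --------------------------------------------------------------------------

def apply_mar_missingness(metrics: pd.DataFrame, fraction: float,
                          seed: int) -> pd.DataFrame:
    """Mask all MG indicators for a contiguous enrolment block of patients.

    Emulates a temporary protocol change during which the memory-guided
    task was not administered: exactly ``round(fraction * n_patients)``
    patients, contiguous in enrolment (row) order, lose MG_LATENCY,
    MG_ERROR and MG_FEP.  The masking depends only on enrolment position,
    never on the values themselves (missing at random).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    out = metrics.copy()
    is_patient = out["group"] != "control" if "group" in out else \
        pd.Series(True, index=out.index)
    patient_idx = out.index[is_patient]
    n_mask = int(round(fraction * len(patient_idx)))
    if n_mask == 0:
        return out
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, len(patient_idx) - n_mask + 1))
    block = patient_idx[start:start + n_mask]
    out.loc[block, MG_INDICATORS] = np.nan
    return out


# --------------------------------------------------------------------------
# I/O helpers
# --------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    """Write metrics, labels and any traces as tidy CSV files."""
    import pathlib
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.metrics.to_csv(outdir / "metrics.csv")
    cohort.labels.to_frame().to_csv(outdir / "labels.csv")
    if cohort.traces:
        tdir = outdir / "traces"
        tdir.mkdir(exist_ok=True)
        for pid, tasks in cohort.traces.items():
            frames = [tr.to_frame() for tr in tasks.values()]
            pd.concat(frames).to_csv(tdir / f"{pid}.csv", index=False)
            ann = pd.concat([tr.annotations.assign(task=tid)
                             for tid, tr in tasks.items()])
            ann.to_csv(tdir / f"{pid}_annotations.csv", index=False)
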
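"""Seeded generator of synthetic resting wrist-PPG cohorts.

Each beat is a sum of three smooth, log-concave components on the beat
window: a gamma-shaped systolic wave, an optional Gaussian mid-systolic
bump (which produces beats with multiple peaks of variable intensity), and
a Gaussian dicrotic/diastolic wave.  The dicrotic component's centre,
width and height are solved in closed form so that the waveform has an
exact stationary local minimum at the requested dicrotic-notch time: the
notch landmark is therefore analytic, which makes the generator a usable
oracle for segmentation and feature-extraction tests.

A recording concatenates beats whose intervals follow a per-subject heart
rate, applies per-beat multiplicative shape jitter, sinusoidal respiratory
amplitude/baseline modulation, occasional irregular beats (shape
parameters redrawn from a widened distribution; all "subjects" stay in
sinus rhythm), and additive Gaussian sensor noise.  Every beat onset and
landmark is recorded as ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BeatShapeParams",
    "CohortParams",
    "GroundTruth",
    "SynthRecording",
    "synth_beat_waveform",
    "synth_recording",
    "synth_cohort",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeatShapeParams:
    """Morphology of a single pulse wave.

    Times are in seconds from the beat foot; amplitudes in arbitrary
    sensor units.  ``notch_ratio`` is the notch height over the systolic
    peak height, ``diastolic_peak_ratio`` the diastolic-wave height over
    the peak height.  ``component_widths`` are (systolic width, bump
    width) in seconds; the dicrotic width is solved from the notch
    constraints.
    """

    crest_time: float = 0.18
    notch_time: float = 0.30
    pulse_amplitude: float = 1.0
    notch_ratio: float = 0.50
    diastolic_peak_ratio: float = 0.40
    mid_systolic_bump_amplitude: float = 0.05
    component_widths: tuple[float, float] = (0.07, 0.035)

    def validate(self) -> None:
        if not (0.0 < self.crest_time < self.notch_time):
            raise ValueError("require 0 < crest_time < notch_time")
        if self.pulse_amplitude <= 0:
            raise ValueError("pulse_amplitude must be > 0")
        if not (0.0 < self.notch_ratio < 1.0):
            raise ValueError("notch_ratio must lie in (0, 1)")
        if not (0.0 <= self.diastolic_peak_ratio < 1.0):
            raise ValueError("diastolic_peak_ratio must lie in [0, 1)")
        if self.mid_systolic_bump_amplitude < 0:
            raise ValueError("mid_systolic_bump_amplitude must be >= 0")
        if any(w <= 0 for w in self.component_widths):
            raise ValueError("component widths must be > 0")


@dataclass(frozen=True)
class CohortParams:
    """One synthetic cohort (a diagnostic class).

    ``hr_mean``/``hr_sd`` give the between-subject heart-rate
    distribution in bpm.  ``beat_to_beat_cv`` is the per-beat
    multiplicative jitter applied to shape parameters;
    ``between_subject_cv`` the analogous subject-level jitter around the
    class-mean shape.  ``ibi_cv`` is the per-beat inter-beat-interval
    jitter.  Respiratory modulation is sinusoidal at ``resp_rate`` Hz:
    ``resp_amplitude_mod`` multiplies beat amplitudes,
    ``resp_baseline_mod`` adds a baseline wander component.
    """

    n_subjects: int = 64
    hr_mean: float = 59.0
    hr_sd: float = 9.0
    recordings_per_subject: tuple[int, int] = (1, 5)
    recording_duration: float = 300.0
    sampling_rate: float = 64.0
    beat_shape: BeatShapeParams = field(default_factory=BeatShapeParams)
    beat_to_beat_cv: float = 0.04
    between_subject_cv: float = 0.05
    ibi_cv: float = 0.03
    resp_rate: float = 0.25
    resp_amplitude_mod: float = 0.10
    resp_baseline_mod: float = 0.05
    irregular_beat_prob: float = 0.01
    noise_sd: float = 0.01
    label: str = "healthy"
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.hr_mean <= 0 or self.hr_sd < 0:
            raise ValueError("heart-rate parameters invalid")
        lo, hi = self.recordings_per_subject
        if not (1 <= lo <= hi <= 5):
            raise ValueError("recordings_per_subject must be a range within [1, 5]")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be > 0")
        if not (25.0 <= self.sampling_rate <= 250.0):
            raise ValueError("sampling_rate must lie in [25, 250] Hz")
        for p, name in [
            (self.irregular_beat_prob, "irregular_beat_prob"),
            (self.resp_amplitude_mod, "resp_amplitude_mod"),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.beat_to_beat_cv, self.between_subject_cv, self.ibi_cv,
               self.resp_baseline_mod, self.noise_sd, self.resp_rate) < 0:
            raise ValueError("rates/levels must be >= 0")
        self.beat_shape.validate()


@dataclass
class GroundTruth:
    """Per-recording oracle: beat onsets and analytic landmark times."""

    beat_onset_times: np.ndarray  # seconds, strictly increasing
    peak_times: np.ndarray        # absolute seconds, one per beat
    notch_times: np.ndarray       # absolute seconds; NaN when no dicrotic wave
    shapes: list[BeatShapeParams]

    def validate(self, duration: float) -> None:
        t = self.beat_onset_times
        if np.any(np.diff(t) <= 0):
            raise ValueError("beat onsets must be strictly increasing")
        if np.any((t < 0) | (t > duration)):
            raise ValueError("beat onsets outside the recording")
        ends = np.append(t[1:], duration)
        if np.any((self.peak_times < t) | (self.peak_times > ends)):
            raise ValueError("peak landmark outside its beat interval")
        ok = ~np.isnan(self.notch_times)
        if np.any((self.notch_times[ok] < t[ok]) | (self.notch_times[ok] > ends[ok])):
            raise ValueError("notch landmark outside its beat interval")


@dataclass
class SynthRecording:
    """A generated waveform plus its metadata (one classification bag)."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str
    recording_id: str
    label: str
    seed: int


# ---------------------------------------------------------------------------
# single-beat model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _BeatComponents:
    # gamma systolic: amp * (t/tc)^(k-1) * exp(-(t-tc)/theta), peak value amp at t=tc
    sys_amp: float
    sys_k: float
    sys_theta: float
    crest_time: float
    # gaussian bump
    bump_amp: float
    bump_center: float
    bump_width: float
    # gaussian dicrotic wave (amp 0 => absent)
    dic_amp: float
    dic_center: float
    dic_width: float
    notch_time: float


def _gamma_width_to_shape(crest_time: float, width: float) -> tuple[float, float]:
    """Solve gamma shape/scale so mode = crest_time and SD = width."""
    r = width / crest_time
    u = (1.0 / r + np.sqrt(1.0 / r**2 + 4.0)) / 2.0  # u = sqrt(k)
    k = u * u
    theta = crest_time / (k - 1.0)
    return k, theta


def _solve_components(shape: BeatShapeParams, strict: bool = True,
                      period: float | None = None) -> _BeatComponents:
    """Place the dicrotic Gaussian so the waveform's local minimum sits
    exactly at ``notch_time`` with the requested notch height.

    With ``strict=False`` (used during recording synthesis, where jittered
    shapes can wander outside the solvable region) the notch height gap
    and dicrotic amplitude are nudged just enough to keep a genuine local
    minimum at the notch; the notch *time* is preserved exactly.
    """
    shape.validate()
    a = shape.pulse_amplitude
    tc, tn = shape.crest_time, shape.notch_time
    w_sys, w_bump = shape.component_widths
    k, theta = _gamma_width_to_shape(tc, w_sys)

    def sys_val(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = a * (t[pos] / tc) ** (k - 1.0) * np.exp(-(t[pos] - tc) / theta)
        return out

    def sys_slope(t):
        v = sys_val(np.asarray([t]))[0]
        return v * ((k - 1.0) / t - 1.0 / theta)

    b_amp = shape.mid_systolic_bump_amplitude * a
    # the bump sits at 60% of the crest-to-notch span: late enough that the
    # systolic tail has fallen, so a strong bump forms a genuine second peak
    b_ctr = tc + 0.6 * (tn - tc)
    # the bump must fit between crest and notch, or its curvature can
    # destroy the notch minimum
    w_bump = min(w_bump, (tn - tc) / 3.0)

    def bump_val(t):
        return b_amp * np.exp(-((np.asarray(t, dtype=float) - b_ctr) ** 2) / (2 * w_bump**2))

    def bump_slope(t):
        return bump_val(np.asarray([t]))[0] * (-(t - b_ctr) / w_bump**2)

    if shape.diastolic_peak_ratio <= 0.0:
        return _BeatComponents(a, k, theta, tc, b_amp, b_ctr, w_bump,
                               0.0, 0.0, 1.0, np.nan)

    base_at_notch = sys_val(np.asarray([tn]))[0] + bump_val(np.asarray([tn]))[0]
    slope_at_notch = sys_slope(tn) + bump_slope(tn)
    height_gap = shape.notch_ratio * a - base_at_notch
    dic_amp = shape.diastolic_peak_ratio * a
    if slope_at_notch >= 0.0:
        raise ValueError("systolic components must be falling at notch_time")
    if height_gap <= 0.0:
        if strict:
            raise ValueError(
                "notch_ratio below the systolic tail at notch_time; widen "
                "the notch or narrow the systolic component")
        height_gap = 0.06 * a
    if period is not None:
        # keep the dicrotic wave inside the beat: its centre offset is
        # roughly v^2 * gap / |slope|, so cap the gap accordingly
        height_gap = min(height_gap,
                         max(0.45 * period * abs(slope_at_notch), 0.04 * a))
    # dicrotic visibility guarantee: with v >= 0.8 the waveform rises
    # perceptibly after the notch instead of forming a flat plateau
    dic_amp = max(dic_amp, float(np.exp(0.32)) * height_gap)
    # Stationarity at tn:  dic'(tn) = -slope_at_notch,  dic(tn) = height_gap
    # with dic(t) = A e^{-(t-td)^2 / 2wd^2}:  v := (td - tn)/wd  =>
    #   v = sqrt(2 ln(A / gap)),  wd = v * gap / |slope|.
    eps = 1e-4
    for _ in range(8):
        v = float(np.sqrt(2.0 * np.log(dic_amp / height_gap)))
        w_dic = v * height_gap / abs(slope_at_notch)
        t_dic = tn + v * w_dic
        comp = _BeatComponents(a, k, theta, tc, b_amp, b_ctr, w_bump,
                               dic_amp, t_dic, w_dic, tn)
        # the stationary point must be a genuine minimum
        f = _components_value(comp, np.asarray([tn - eps, tn, tn + eps]))
        if f[0] > f[1] < f[2]:
            return comp
        if strict:
            break
        dic_amp *= 1.6  # deepen the dicrotic wave until the minimum holds
    raise ValueError(
        "notch constraints do not yield a local minimum; adjust "
        "notch_ratio / diastolic_peak_ratio / component widths")


def _components_value(c: _BeatComponents, t: np.ndarray,
                      period: float | None = None) -> np.ndarray:
    """Sum of the three components; when ``period`` is given the dicrotic
    wave is cosine-tapered to zero over the last quarter of the beat so
    that a broad diastolic dome still reaches the next foot at baseline
    (the taper region lies well after the notch, whose landmark solve is
    unaffected)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = c.sys_amp * (tp / c.crest_time) ** (c.sys_k - 1.0) * np.exp(
        -(tp - c.crest_time) / c.sys_theta)
    if c.bump_amp > 0:
        out += c.bump_amp * np.exp(-((t - c.bump_center) ** 2) / (2 * c.bump_width**2))
    if c.dic_amp > 0:
        dic = c.dic_amp * np.exp(-((t - c.dic_center) ** 2) / (2 * c.dic_width**2))
        if period is not None:
            t0 = 0.75 * period
            taper = np.ones_like(t)
            late = t > t0
            taper[late] = np.cos(
                0.5 * np.pi * np.clip((t[late] - t0) / (period - t0), 0, 1)) ** 2
            dic = dic * taper
        out += dic
    return out


def _peak_time(c: _BeatComponents, period: float) -> float:
    """Realized systolic peak of the full sum, refined on a fine grid."""
    lo = max(0.25 * c.crest_time, c.crest_time - 0.1)
    hi = min(period, (c.notch_time if np.isfinite(c.notch_time) else period))
    grid = np.linspace(lo, hi, 2001)
    vals = _components_value(c, grid)
    return float(grid[np.argmax(vals)])


def synth_beat_waveform(
    shape: BeatShapeParams, period: float, rate: float
) -> tuple[np.ndarray, dict]:
    """Generate one beat of ``round(period * rate)`` samples.

    Returns ``(samples, landmarks)`` where landmarks holds the analytic
    ``peak_time`` and ``notch_time`` (NaN when the dicrotic wave is
    absent), in seconds from the beat foot.  The waveform starts and ends
    at the foot level (a linear ramp removes residual component tails at
    the window edges).
    """
    if rate < 25.0:
        raise ValueError("sampling rate must be >= 25 Hz")
    if period <= shape.notch_time:
        raise ValueError("period must exceed notch_time")
    comp = _solve_components(shape, period=period)
    n = int(round(period * rate))
    t = np.arange(n) / rate
    y = _components_value(comp, t, period=period)
    end_val = _components_value(comp, np.asarray([period]), period=period)[0]
    y -= y[0] + (end_val - y[0]) * (t / period)
    landmarks = {
        "peak_time": _peak_time(comp, period),
        "notch_time": comp.notch_time,
    }
    return y, landmarks


# ---------------------------------------------------------------------------
# recordings and cohorts
# ---------------------------------------------------------------------------


_JITTERED_FIELDS = (
    "crest_time",
    "notch_time",
    "pulse_amplitude",
    "notch_ratio",
    "mid_systolic_bump_amplitude",
)


def _jitter_shape(shape: BeatShapeParams, cv: float, rng: np.random.Generator,
                  bump_floor: float = 0.0) -> BeatShapeParams:
    """Multiplicative lognormal-style jitter on the main shape fields,
    clipped to keep the invariants solvable."""
    if cv <= 0:
        return shape
    factors = np.exp(rng.normal(0.0, cv, size=len(_JITTERED_FIELDS)))
    new = {f: getattr(shape, f) * factors[i] for i, f in enumerate(_JITTERED_FIELDS)}
    # the notch and diastolic wave heights move together (the whole
    # diastolic limb scales), which keeps the notch dip visible
    idx = _JITTERED_FIELDS.index("notch_ratio")
    new["diastolic_peak_ratio"] = shape.diastolic_peak_ratio * factors[idx]
    # keep morphology solvable: crest strictly inside (0, notch), with a
    # minimal 0.1 s crest-to-notch separation (systolic ejection shoulder)
    new["crest_time"] = float(np.clip(new["crest_time"], 0.05, 0.9 * new["notch_time"]))
    new["notch_time"] = max(new["notch_time"], new["crest_time"] + 0.1)
    new["notch_ratio"] = float(np.clip(new["notch_ratio"], 0.05, 0.75))
    new["diastolic_peak_ratio"] = float(np.clip(new["diastolic_peak_ratio"], 0.0, 0.9))
    new["mid_systolic_bump_amplitude"] = max(new["mid_systolic_bump_amplitude"], bump_floor)
    return replace(shape, **new)


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def synth_recording(
    cohort: CohortParams, subject_seed: int, *,
    subject_id: str = "S000", recording_id: str = "R000",
    subject_shape: Optional[BeatShapeParams] = None,
    subject_hr: Optional[float] = None,
) -> tuple[SynthRecording, GroundTruth]:
    """Generate one recording for one subject; fully determined by
    ``subject_seed`` and the cohort parameters.

    ``subject_shape``/``subject_hr`` carry subject-level parameters when a
    cohort generates several recordings from the same person; when absent
    they are drawn here from the cohort distributions.
    """
    cohort.validate()
    rng = np.random.default_rng(subject_seed)
    if subject_hr is None:
        subject_hr = float(np.clip(
            rng.normal(cohort.hr_mean, cohort.hr_sd), 40.0, 180.0))
    else:
        rng.normal()  # keep stream layout stable between call modes
    if subject_shape is None:
        subject_shape = _jitter_shape(cohort.beat_shape, cohort.between_subject_cv, rng)

    fs = cohort.sampling_rate
    dur = cohort.recording_duration
    mean_ibi = 60.0 / subject_hr

    onsets: list[float] = []
    shapes: list[BeatShapeParams] = []
    peaks: list[float] = []
    notches: list[float] = []
    n_total = int(round(dur * fs))
    samples = np.zeros(n_total)

    t_on = 0.0
    resp_omega = 2.0 * np.pi * cohort.resp_rate
    while t_on < dur:
        ibi = mean_ibi * (1.0 + cohort.ibi_cv * rng.standard_normal())
        ibi = float(np.clip(ibi, 0.4 * mean_ibi, 2.5 * mean_ibi))
        if rng.random() < cohort.irregular_beat_prob:
            bshape = _jitter_shape(subject_shape, 4.0 * max(cohort.beat_to_beat_cv, 0.05),
                                   rng, bump_floor=0.15 * subject_shape.pulse_amplitude)
        else:
            bshape = _jitter_shape(subject_shape, cohort.beat_to_beat_cv, rng)
        if cohort.resp_amplitude_mod > 0:
            mod = 1.0 + cohort.resp_amplitude_mod * np.sin(resp_omega * t_on)
            bshape = replace(bshape, pulse_amplitude=bshape.pulse_amplitude * mod)
        if bshape.notch_time >= 0.95 * ibi:
            bshape = replace(bshape, notch_time=0.95 * ibi,
                             crest_time=min(bshape.crest_time, 0.85 * ibi))
        try:
            comp = _solve_components(bshape, strict=False, period=ibi)
        except ValueError:
            # extreme jitter can defeat the notch repair: emit the beat
            # without a dicrotic wave (a frankly irregular beat)
            bshape = replace(bshape, diastolic_peak_ratio=0.0)
            comp = _solve_components(bshape, strict=False, period=ibi)
        i0 = int(np.ceil(t_on * fs - 1e-9))
        i1 = min(int(np.ceil((t_on + ibi) * fs - 1e-9)), n_total)
        if i1 > i0:
            tt = np.arange(i0, i1) / fs - t_on
            y = _components_value(comp, tt, period=ibi)
            y -= y[0] + (_components_value(comp, np.asarray([ibi]),
                                           period=ibi)[0] - y[0]) * (tt / ibi)
            samples[i0:i1] = y
        onsets.append(t_on)
        shapes.append(bshape)
        peaks.append(t_on + _peak_time(comp, ibi))
        notches.append(t_on + comp.notch_time)
        t_on += ibi

    tgrid = np.arange(n_total) / fs
    if cohort.resp_baseline_mod > 0:
        samples = samples + cohort.resp_baseline_mod * np.sin(resp_omega * tgrid)
    if cohort.noise_sd > 0:
        samples = samples + rng.normal(0.0, cohort.noise_sd, size=n_total)

    onsets_a = np.asarray(onsets)
    peaks_a = np.asarray(peaks)
    notches_a = np.asarray(notches)
    # the trailing beat may be truncated by the recording end: ground truth
    # only lists beats whose landmarks are fully inside the recording
    keep = (peaks_a <= dur) & (np.isnan(notches_a) | (notches_a <= dur))
    gt = GroundTruth(
        beat_onset_times=onsets_a[keep],
        peak_times=peaks_a[keep],
        notch_times=notches_a[keep],
        shapes=[s for s, k in zip(shapes, keep) if k],
    )
    gt.validate(dur)
    rec = SynthRecording(
        samples=samples, sampling_rate=fs, subject_id=subject_id,
        recording_id=recording_id, label=cohort.label, seed=subject_seed)
    return rec, gt


def synth_cohort(
    healthy: CohortParams, ohcm: CohortParams, seed: int
) -> list[tuple[SynthRecording, GroundTruth]]:
    """Generate the full two-class cohort, fully reproducible from ``seed``.

    Each subject receives a uniformly drawn number of recordings in the
    configured range (1-5 by default); subject-level heart rate and shape
    are shared across that subject's recordings.
    """
    healthy.validate()
    ohcm.validate()
    if healthy.n_subjects == 0 or ohcm.n_subjects == 0:
        warnings.warn("one class has zero subjects: emitting a single-class cohort",
                      stacklevel=2)
    out: list[tuple[SynthRecording, GroundTruth]] = []
    master = np.random.SeedSequence(seed)
    class_seeds = master.spawn(2)
    for cls_idx, cohort in enumerate((healthy, ohcm)):
        prefix = "H" if cls_idx == 0 else "O"
        subj_seqs = class_seeds[cls_idx].spawn(cohort.n_subjects)
        for s_idx, sseq in enumerate(subj_seqs):
            subject_id = f"{prefix}{s_idx:03d}"
            srng = np.random.default_rng(_derive_seed(sseq))
            lo, hi = cohort.recordings_per_subject
            n_rec = int(srng.integers(lo, hi + 1))
            subject_hr = float(np.clip(
                srng.normal(cohort.hr_mean, cohort.hr_sd), 40.0, 180.0))
            subject_shape = _jitter_shape(cohort.beat_shape,
                                          cohort.between_subject_cv, srng)
            rec_seqs = sseq.spawn(n_rec)
            for r_idx, rseq in enumerate(rec_seqs):
                rec, gt = synth_recording(
                    cohort, _derive_seed(rseq),
                    subject_id=subject_id,
                    recording_id=f"{subject_id}_r{r_idx}",
                    subject_shape=subject_shape, subject_hr=subject_hr)
                out.append((rec, gt))
    return out
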
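"""The fixed 42-feature morphometric catalog computed per qualified beat.

Feature families follow standard pulse-wave morphometry: beat timing,
amplitudes, systolic/diastolic slopes, fractional pulse widths, areas,
the a-e waves of the second derivative (acceleration plethysmogram), shape
statistics, and respiratory-context features measured against the +/-5
neighbouring beats.  All amplitudes are taken after per-beat foot-level
subtraction; amplitude-normalised quantities divide by the pulse amplitude
(peak minus foot).  The catalog is versioned and frozen: changing entry
identities or order is a breaking change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .segment import (Beat, PPGRecording, UnusableRecordingError,
                      median_beat_template, segment_recording, _resample_unit)

__all__ = [
    "CATALOG_VERSION",
    "FEATURE_CATALOG",
    "FEATURE_IDS",
    "N_FEATURES",
    "BeatFeatures",
    "RecordingBag",
    "extract_beat_features",
    "extract_recording_bag",
]

CATALOG_VERSION = "1.0"
N_FEATURES = 42

#: (id, name, group, unit) in frozen catalog order
FEATURE_CATALOG: tuple[tuple[str, str, str, str], ...] = (
    ("F01", "inter-beat interval", "timing", "s"),
    ("F02", "instantaneous heart rate", "timing", "bpm"),
    ("F03", "crest time (foot to systolic peak)", "timing", "s"),
    ("F04", "systolic ejection time (foot to notch)", "timing", "s"),
    ("F05", "diastolic time (notch to end)", "timing", "s"),
    ("F06", "systolic/diastolic time ratio", "timing", "1"),
    ("F07", "peak-to-notch time", "timing", "s"),
    ("F08", "crest-time fraction of interval", "timing", "1"),
    ("F09", "pulse amplitude (peak minus foot)", "amplitude", "au"),
    ("F10", "notch height ratio", "amplitude", "1"),
    ("F11", "diastolic-peak ratio", "amplitude", "1"),
    ("F12", "peak-to-notch drop ratio", "amplitude", "1"),
    ("F13", "normalised beat mean", "amplitude", "1"),
    ("F14", "normalised beat RMS", "amplitude", "1"),
    ("F15", "max systolic upslope", "slope", "au/s"),
    ("F16", "mean systolic slope", "slope", "au/s"),
    ("F17", "max diastolic downslope magnitude", "slope", "au/s"),
    ("F18", "mean diastolic slope", "slope", "au/s"),
    ("F19", "upslope/downslope ratio", "slope", "1"),
    ("F20", "normalised max upslope", "slope", "1/s"),
    ("F21", "width at 25% amplitude", "width", "s"),
    ("F22", "width at 50% amplitude", "width", "s"),
    ("F23", "width at 75% amplitude", "width", "s"),
    ("F24", "pre-peak fraction of 50% width", "width", "1"),
    ("F25", "width ratio 75%/25%", "width", "1"),
    ("F26", "normalised pulse area", "area", "1"),
    ("F27", "systolic area fraction", "area", "1"),
    ("F28", "post/pre-notch area ratio", "area", "1"),
    ("F29", "area-to-duration ratio", "area", "1/s"),
    ("F30", "second-derivative a-wave amplitude", "sdppg", "au/s^2"),
    ("F31", "b/a ratio", "sdppg", "1"),
    ("F32", "c/a ratio", "sdppg", "1"),
    ("F33", "d/a ratio", "sdppg", "1"),
    ("F34", "e/a ratio", "sdppg", "1"),
    ("F35", "aging index (b-c-d-e)/a", "sdppg", "1"),
    ("F36", "number of prominent local maxima", "shape", "count"),
    ("F37", "beat skewness", "shape", "1"),
    ("F38", "beat kurtosis", "shape", "1"),
    ("F39", "relative amplitude deviation from +/-5-beat mean", "context", "1"),
    ("F40", "relative IBI deviation from +/-5-beat mean", "context", "1"),
    ("F41", "amplitude CV over +/-5-beat window", "context", "1"),
    ("F42", "correlation with median-beat template", "context", "1"),
)

FEATURE_IDS: tuple[str, ...] = tuple(f[0] for f in FEATURE_CATALOG)

assert len(FEATURE_CATALOG) == N_FEATURES

#: indices (0-based) of features that need the notch landmark
_NOTCH_FEATURES = (3, 4, 5, 6, 9, 11, 17, 26, 27)


@dataclass
class BeatFeatures:
    """The 42-entry feature vector of one beat plus a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    beat: Optional[Beat] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != (N_FEATURES,) or self.valid.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have exactly {N_FEATURES} entries")
        if np.any(np.isinf(self.values[self.valid])):
            raise ValueError("features must be finite where valid")


@dataclass
class BeatContext:
    """Neighbourhood information for the respiratory-context features."""

    amplitudes: np.ndarray     # amplitudes of the +/-5-beat window (incl. self)
    ibis: np.ndarray           # IBIs of the same window
    self_amplitude: float
    self_ibi: float
    template: np.ndarray       # recording median-beat template


@dataclass
class RecordingBag:
    """All qualified-beat feature vectors of one recording (a MIL bag)."""

    features: np.ndarray              # (n_beats, 42), imputed, finite
    subject_id: str
    recording_id: str
    label: str
    n_qualified: int = field(init=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.n_qualified = self.features.shape[0]


def _crossing_times(t: np.ndarray, y: np.ndarray, level: float
                    ) -> tuple[Optional[float], Optional[float]]:
    """First rising and last falling crossing of ``level``, with linear
    sub-sample interpolation."""
    above = y >= level
    if not above.any():
        return None, None
    idx = np.flatnonzero(above)
    first, last = idx[0], idx[-1]
    t_first = t[first]
    if first > 0 and y[first] != y[first - 1]:
        frac = (level - y[first - 1]) / (y[first] - y[first - 1])
        t_first = t[first - 1] + frac * (t[first] - t[first - 1])
    t_last = t[last]
    if last < len(y) - 1 and y[last] != y[last + 1]:
        frac = (y[last] - level) / (y[last] - y[last + 1])
        t_last = t[last] + frac * (t[last + 1] - t[last])
    return float(t_first), float(t_last)


def _sdppg_waves(y: np.ndarray, fs: float, peak: int, search_end: int
                 ) -> Optional[dict]:
    """a-e wave amplitudes of the second derivative.

    The waves are the alternating extrema (+,-,+,-,+) of the
    acceleration signal from the beat onset through early diastole;
    detection walks the local extrema in time order and greedily matches
    the sign pattern.  Missing waves are reported as None.
    """
    win = max(int(round(0.09 * fs)) | 1, 5)
    if len(y) <= win:
        return None
    d2 = sps.savgol_filter(y, win, 3, deriv=2, delta=1.0 / fs,
                           mode="nearest")
    # the d and e waves straddle the dicrotic notch: search through early
    # diastole (notch + ~0.15 s), not only up to the notch
    stop = min(len(y), max(search_end + int(round(0.15 * fs)), peak + 2))
    seg = d2[:stop]
    maxima, _ = sps.find_peaks(seg)
    minima, _ = sps.find_peaks(-seg)
    extrema = sorted([(int(i), +1) for i in maxima] + [(int(i), -1) for i in minima])
    waves: list[float] = []
    want = +1
    for idx, sign in extrema:
        if sign == want:
            waves.append(seg[idx])
            want = -want
        elif waves and sign == -want:
            # deeper extremum of the same phase: keep the more extreme one
            if (sign > 0 and seg[idx] > waves[-1]) or (sign < 0 and seg[idx] < waves[-1]):
                waves[-1] = seg[idx]
        if len(waves) == 5:
            break
    if not waves or waves[0] <= 0:
        return None
    names = ("a", "b", "c", "d", "e")
    return {n: (waves[i] if i < len(waves) else None) for i, n in enumerate(names)}


def extract_beat_features(beat: Beat, rec: PPGRecording,
                          context: Optional[BeatContext] = None) -> BeatFeatures:
    """Compute the catalog for one qualified beat.

    Notch-dependent entries fall back to the second-derivative landmark
    recorded by segmentation; when that is also absent they are flagged
    invalid and later mean-imputed per recording.  Context features are
    invalid when ``context`` is None.
    """
    x = np.asarray(rec.samples, dtype=float)
    fs = rec.sampling_rate
    a, e_, p = beat.onset_index, beat.end_index, beat.peak_index
    y = x[a:e_] - x[a]
    n = len(y)
    t = np.arange(n) / fs
    pk = p - a
    vals = np.zeros(N_FEATURES)
    valid = np.ones(N_FEATURES, dtype=bool)

    ibi = n / fs
    amp = y[pk]
    if amp <= 0 or pk <= 0 or pk >= n - 1:
        return BeatFeatures(np.zeros(N_FEATURES), np.zeros(N_FEATURES, bool), beat)
    yn = y / amp
    dy = np.gradient(y) * fs

    vals[0] = ibi
    vals[1] = 60.0 / ibi
    vals[2] = pk / fs
    nk = (beat.notch_index - a) if beat.notch_index is not None else None
    if nk is not None and pk < nk < n:
        vals[3] = nk / fs
        vals[4] = (n - nk) / fs
        vals[5] = vals[3] / vals[4] if vals[4] > 0 else 0.0
        vals[6] = (nk - pk) / fs
    else:
        valid[list(_NOTCH_FEATURES)] = False
    vals[7] = vals[2] / ibi

    vals[8] = amp
    if nk is not None and valid[3]:
        vals[9] = yn[nk]
        post = yn[nk:]
        vals[10] = float(post.max())
        vals[11] = 1.0 - yn[nk]
    vals[12] = float(yn.mean())
    vals[13] = float(np.sqrt(np.mean(yn**2)))

    vals[14] = float(dy[:pk + 1].max())
    vals[15] = amp / vals[2]
    down = dy[pk:]
    vals[16] = float(-down.min()) if len(down) else 0.0
    if nk is not None and valid[3]:
        vals[17] = (y[nk] - y[-1]) / vals[4]
    vals[18] = vals[14] / vals[16] if vals[16] > 0 else 0.0
    vals[19] = vals[14] / amp

    for j, frac in ((20, 0.25), (21, 0.50), (22, 0.75)):
        t0, t1 = _crossing_times(t, yn, frac)
        vals[j] = (t1 - t0) if t0 is not None else 0.0
    t50 = _crossing_times(t, yn, 0.50)
    if t50[0] is not None and vals[21] > 0:
        vals[23] = (t[pk] - t50[0]) / vals[21]
    vals[24] = vals[22] / vals[20] if vals[20] > 0 else 0.0

    total_area = float(np.trapezoid(yn, t))
    vals[25] = total_area / ibi
    if nk is not None and valid[3]:
        pre = float(np.trapezoid(yn[:nk + 1], t[:nk + 1]))
        post_a = total_area - pre
        vals[26] = pre / total_area if total_area > 0 else 0.0
        vals[27] = post_a / pre if pre > 0 else 0.0
    vals[28] = vals[25] / ibi

    waves = _sdppg_waves(y, fs, pk, nk if nk is not None else int(0.6 * n))
    if waves is None:
        valid[29:35] = False
    else:
        aw = waves["a"]
        vals[29] = aw
        ratios = [waves[c] / aw if waves[c] is not None else 0.0
                  for c in ("b", "c", "d", "e")]
        vals[30:34] = ratios
        vals[34] = ratios[0] - ratios[1] - ratios[2] - ratios[3]

    peaks36, _ = sps.find_peaks(yn, prominence=0.05)
    vals[35] = float(len(peaks36))
    # biased sample skewness / excess kurtosis, computed directly (the
    # generic stats wrappers dominate the per-beat budget otherwise)
    dev = yn - yn.mean()
    m2 = np.mean(dev**2)
    if m2 > 0:
        vals[36] = float(np.mean(dev**3) / m2**1.5)
        vals[37] = float(np.mean(dev**4) / m2**2 - 3.0)

    if context is None:
        valid[38:42] = False
    else:
        wa = np.asarray(context.amplitudes, dtype=float)
        wi = np.asarray(context.ibis, dtype=float)
        ma, mi = wa.mean(), wi.mean()
        vals[38] = (context.self_amplitude - ma) / ma if ma > 0 else 0.0
        vals[39] = (context.self_ibi - mi) / mi if mi > 0 else 0.0
        vals[40] = wa.std() / ma if ma > 0 else 0.0
        tpl = context.template
        seg = _resample_unit(y, len(tpl))
        st, ss = np.std(tpl), np.std(seg)
        vals[41] = float(np.corrcoef(seg, tpl)[0, 1]) if st > 0 and ss > 0 else 0.0

    vals[~valid] = 0.0
    return BeatFeatures(vals, valid, beat)


def extract_recording_bag(rec: PPGRecording,
                          beats: Optional[Sequence[Beat]] = None) -> RecordingBag:
    """One feature vector per qualified beat, with per-recording mean
    imputation of invalid entries.

    When ``beats`` is omitted the full segmentation pipeline runs first
    (band-pass detection, landmark refinement on the baseline-free
    signal).  Unusable recordings raise
    :class:`~ppgmiles.segment.UnusableRecordingError`.
    """
    if beats is None:
        rec, beats = segment_recording(rec)
    qualified = [b for b in beats if b.qualified]
    if len(qualified) < 10:
        raise UnusableRecordingError("fewer than 10 qualified beats")
    x = np.asarray(rec.samples, dtype=float)
    fs = rec.sampling_rate
    template = median_beat_template(x, qualified)
    amps = np.array([x[b.peak_index] - x[b.onset_index] for b in qualified])
    ibis = np.array([(b.end_index - b.onset_index) / fs for b in qualified])

    rows, masks = [], []
    for i, b in enumerate(qualified):
        lo, hi = max(0, i - 5), min(len(qualified), i + 6)
        ctx = BeatContext(amplitudes=amps[lo:hi], ibis=ibis[lo:hi],
                          self_amplitude=amps[i], self_ibi=ibis[i],
                          template=template)
        bf = extract_beat_features(b, rec, ctx)
        rows.append(bf.values)
        masks.append(bf.valid)
    feats = np.vstack(rows)
    valid = np.vstack(masks)

    # per-recording mean imputation over the valid entries of each column
    for j in range(N_FEATURES):
        bad = ~valid[:, j]
        if bad.any():
            good = valid[:, j]
            feats[bad, j] = feats[good, j].mean() if good.any() else 0.0
    return RecordingBag(features=feats, subject_id=rec.subject_id,
                        recording_id=rec.recording_id, label=rec.label)
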
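"""Band-splitting and landmark detection for ablation electrograms.

The distal ablation bipole records a superposition of a sharp, high-frequency
near-field potential (the candidate pathway signal) and a slower, larger
far-field ventricular deflection.  A zero-phase Butterworth split separates
the two, after which three landmarks anchor all timing features:

* the onset of the high-frequency (HF) component,
* the peak of the low-frequency (LF) component,
* the peak of the R wave on surface ECG lead I.

All filtering is applied forward-backward so the components share the raw
trace's time axis with no group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    DetectionError,
    EgmWarning,
    InsufficientDataError,
    NoBeatError,
    ParameterError,
)
from .io import ElectrogramRecording

# amplitude range below which a trace is considered flat (mV)
_NOISE_FLOOR_MV = 1e-12


@dataclass
class FilteredBeat:
    """HF and LF components of one analysis beat on a shared time axis.

    ``beat_window`` is half-open ``[start_ms, end_ms)``; every landmark and
    feature is computed inside it.
    """

    time: np.ndarray          # ms
    hf: np.ndarray            # mV
    lf: np.ndarray            # mV
    beat_window: tuple[float, float]
    sample_rate: float        # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.hf = np.asarray(self.hf, dtype=float)
        self.lf = np.asarray(self.lf, dtype=float)
        if not (len(self.time) == len(self.hf) == len(self.lf)):
            raise ParameterError("time, hf and lf must have equal length")
        start, end = self.beat_window
        if not (start < end):
            raise ParameterError("beat_window must satisfy start < end")
        if start < self.time[0] - 1e-9 or end > self.time[-1] + 1000.0 / self.sample_rate:
            raise ParameterError("beat_window must lie within the time axis")

    def window_mask(self, window: tuple[float, float] | None = None) -> np.ndarray:
        start, end = window if window is not None else self.beat_window
        return (self.time >= start - 1e-9) & (self.time < end - 1e-9)


@dataclass
class Landmarks:
    """Times (ms) of the three anchors of one beat.

    ``lf_peak_ms >= hf_onset_ms`` is *not* enforced: their order depends on
    the pathway's activation pattern.
    """

    hf_onset_ms: float
    lf_peak_ms: float
    r_peak_ms: float
    flags: list = field(default_factory=list)


def _sos(split_freq_hz: float, order: int, sample_rate: float, btype: str):
    nyq = sample_rate / 2.0
    if not (0 < split_freq_hz < nyq):
        raise ParameterError(
            f"split frequency {split_freq_hz} Hz must lie in (0, {nyq}) Hz"
        )
    return sps.butter(order, split_freq_hz / nyq, btype=btype, output="sos")


def _settling_samples(sos, tol: float = 1e-12) -> int:
    # samples for the slowest pole's transient to decay below tol
    _, poles, _ = sps.sos2zpk(sos)
    radius = float(np.abs(poles).max())
    return int(np.ceil(np.log(tol) / np.log(radius)))


def _zero_phase(sos, x: np.ndarray, pad: int) -> np.ndarray:
    # odd-reflection padding long enough for edge transients to decay below
    # the 1e-9 zero-phase symmetry tolerance
    return sps.sosfiltfilt(sos, x, padtype="odd", padlen=pad)


def band_split(
    recording: ElectrogramRecording,
    split_freq_hz: float = 100.0,
    filter_order: int = 4,
    beat_window: tuple[float, float] | None = None,
) -> FilteredBeat:
    """Split the ablation bipole into LF and HF components.

    Zero-phase (forward-backward) Butterworth low-pass and high-pass at
    ``split_freq_hz``; the input is odd-reflection padded past the filter's
    settling length so edge transients decay below the symmetry tolerance.

    Parameters
    ----------
    recording : ElectrogramRecording
        Validated recording; ``abl_distal`` is filtered.
    split_freq_hz : float
        Cut frequency; must be below Nyquist.
    filter_order : int
        Butterworth order (each pass; the effective order doubles).
    beat_window : (float, float), optional
        Analysis window in ms; defaults to the full recorded span.
    """
    fs = recording.sample_rate
    x = recording.abl_distal
    sos_lp = _sos(split_freq_hz, filter_order, fs, "lowpass")
    sos_hp = _sos(split_freq_hz, filter_order, fs, "highpass")
    pad = max(
        3 * int(np.ceil(fs / split_freq_hz)),
        _settling_samples(sos_lp),
        _settling_samples(sos_hp),
    )
    if len(x) <= pad:
        raise InsufficientDataError(
            f"recording of {len(x)} samples is shorter than the filter "
            f"settling length ({pad} samples at {split_freq_hz} Hz split)"
        )
    lf = _zero_phase(sos_lp, x, pad)
    hf = _zero_phase(sos_hp, x, pad)
    if beat_window is None:
        step = 1000.0 / fs
        beat_window = (float(recording.time[0]), float(recording.time[-1]) + step)
    return FilteredBeat(
        time=recording.time, hf=hf, lf=lf,
        beat_window=beat_window, sample_rate=fs,
    )


def find_r_peaks(
    recording: ElectrogramRecording,
    min_rr_ms: float = 250.0,
    rel_height: float = 0.5,
) -> np.ndarray:
    """Times (ms) of R peaks on lead I over the whole recording.

    Peaks of ``|lead I|`` at least ``rel_height`` of the global maximum and
    separated by at least ``min_rr_ms``.
    """
    x = np.abs(recording.lead_i)
    rng = float(x.max() - x.min())
    if rng < _NOISE_FLOOR_MV:
        raise DetectionError("lead I is flat; no R peaks detectable")
    distance = max(1, int(round(min_rr_ms * recording.sample_rate / 1000.0)))
    idx, _ = sps.find_peaks(x, height=rel_height * x.max(), distance=distance)
    if idx.size == 0:
        raise DetectionError("no R peaks found on lead I")
    return recording.time[idx]


def select_beat(
    recording: ElectrogramRecording,
    energy_onset_ms: float,
    beat_shift_ms: float = 100.0,
    min_rr_ms: float = 250.0,
) -> tuple[float, float]:
    """Window of the last complete beat before energy delivery.

    The analyzed beat is the one whose lead-I R peak ``R_j`` is the last
    strictly before ``energy_onset_ms`` (half-open convention: an onset
    exactly on an R peak selects the prior beat).  Its window is the
    R-peak-bounded cycle ``[R_{j-1}, R_j)`` shifted right by
    ``beat_shift_ms`` so the beat's own R peak and its pre-R activity — the
    HF onset typically precedes the R peak by ~125 ms — both fall inside;
    the end is capped at the energy onset so no post-delivery samples enter
    the analysis.
    """
    r = find_r_peaks(recording, min_rr_ms=min_rr_ms)
    ok = np.nonzero(r < energy_onset_ms - 1e-9)[0]
    if ok.size < 2:
        raise NoBeatError(
            f"no complete beat precedes energy onset at {energy_onset_ms} ms"
        )
    j = int(ok[-1])
    start = float(max(r[j - 1] + beat_shift_ms, recording.time[0]))
    end = float(min(r[j] + beat_shift_ms, energy_onset_ms))
    return (start, end)


def _peak_time(time: np.ndarray, x: np.ndarray, mask: np.ndarray, what: str) -> float:
    if not mask.any():
        raise DetectionError(f"beat window contains no samples ({what})")
    seg = np.abs(x[mask])
    if float(seg.max() - seg.min()) < _NOISE_FLOOR_MV:
        raise DetectionError(f"{what} trace is flat within the beat window")
    # argmax returns the first (earliest) index on ties
    return float(time[mask][int(np.argmax(seg))])


def detect_r_peak(
    recording: ElectrogramRecording, beat_window: tuple[float, float]
) -> float:
    """Time of max |lead I| within the window (ties -> earliest sample)."""
    mask = (recording.time >= beat_window[0] - 1e-9) & (
        recording.time < beat_window[1] - 1e-9
    )
    return _peak_time(recording.time, recording.lead_i, mask, "lead I")


def detect_lf_peak(beat: FilteredBeat) -> float:
    """Time of max |LF| within the beat window (ties -> earliest sample)."""
    return _peak_time(beat.time, beat.lf, beat.window_mask(), "LF")


def detect_hf_onset(
    beat: FilteredBeat,
    onset_k_sd: float = 3.0,
    onset_sustain_ms: float = 5.0,
    baseline_frac: float = 0.2,
) -> float:
    """Start of the HF signal: earliest sustained envelope exceedance.

    The HF amplitude envelope (magnitude of the analytic signal) must
    exceed ``onset_k_sd x baseline SD`` continuously for
    ``onset_sustain_ms``; the envelope, not the raw rectified trace, is
    thresholded because a narrow-band burst crosses zero twice per cycle.
    The baseline is the earliest ``baseline_frac`` of the beat window; its
    SD estimates the noise level.  If the detected onset falls inside the
    baseline segment the estimate is contaminated and an
    :class:`EgmWarning` is emitted.
    """
    mask = beat.window_mask()
    if not mask.any():
        raise DetectionError("beat window contains no samples")
    t = beat.time[mask]
    x = np.abs(sps.hilbert(beat.hf))[mask]
    if float(x.max() - x.min()) < _NOISE_FLOOR_MV:
        raise DetectionError("HF trace is flat within the beat window")

    n = len(t)
    n_base = max(2, int(np.floor(baseline_frac * n)))
    sd = float(np.std(beat.hf[mask][:n_base]))
    threshold = max(onset_k_sd * sd, _NOISE_FLOOR_MV)

    n_sustain = max(1, int(round(onset_sustain_ms * beat.sample_rate / 1000.0)))
    above = x > threshold
    if n_sustain > 1:
        # run of n_sustain consecutive exceedances starting at each index
        window = np.lib.stride_tricks.sliding_window_view(above, n_sustain)
        starts = np.nonzero(window.all(axis=1))[0]
    else:
        starts = np.nonzero(above)[0]
    if starts.size == 0:
        raise DetectionError(
            f"HF envelope never exceeds {onset_k_sd} x baseline SD "
            f"for {onset_sustain_ms} ms"
        )
    onset = float(t[int(starts[0])])
    if int(starts[0]) < n_base:
        warnings.warn(
            "HF onset lies inside the noise-baseline segment; "
            "baseline SD may be contaminated by signal",
            EgmWarning,
            stacklevel=2,
        )
    return onset


def detect_landmarks(
    recording: ElectrogramRecording,
    beat: FilteredBeat,
    onset_k_sd: float = 3.0,
    onset_sustain_ms: float = 5.0,
    baseline_frac: float = 0.2,
) -> Landmarks:
    """Detect all three landmarks of the beat in ``beat.beat_window``."""
    return Landmarks(
        hf_onset_ms=detect_hf_onset(
            beat, onset_k_sd=onset_k_sd, onset_sustain_ms=onset_sustain_ms,
            baseline_frac=baseline_frac,
        ),
        lf_peak_ms=detect_lf_peak(beat),
        r_peak_ms=detect_r_peak(recording, beat.beat_window),
    )
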
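"""Synthetic electrograms and feature cohorts with known ground truth.

Two generators make every other module testable without clinical data:

* :func:`simulate_waveform` builds single-catheter traces — a low-frequency
  far-field ventricular deflection, a sharp high-frequency near-field
  deflection, a surface-lead QRS and additive Gaussian noise — and returns
  the true landmark times of every beat.
* :func:`simulate_cohort` draws per-signal feature records with the
  per-patient clustering and right-skewed class-conditional distributions
  seen in the validation cohort: each feature is log-normal (LF-to-R time
  normal) with median and IQR matched per class to the published summary,
  and signals within a patient share a random effect on the log composite
  score.

Both are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dsp import Landmarks
from .errors import ParameterError, ValidationError
from .features import SUCCESSFUL, UNSUCCESSFUL, SignalFeatures
from .io import ElectrogramRecording, SignalRecord, write_signal_export

__all__ = [
    "WaveformParams",
    "CohortParams",
    "simulate_waveform",
    "simulate_cohort",
    "write_signal_export",
    "COHORT_ANCHORS",
    "LF_TO_R_NORMAL",
    "class_lognormal_params",
]

_Z75 = norm.ppf(0.75)  # quantile spacing of the IQR on the log scale


@dataclass
class Deflection:
    """A Gaussian-envelope cosine burst.

    The envelope ``exp(-((t-c)/(duration/3))^2 / 2)`` is truncated at
    ``|t-c| = duration/2`` (1.5 sigma), so the burst switches on at ~32% of
    its peak — the abrupt take-off characteristic of near-field potentials —
    and the cosine phase puts the true amplitude peak exactly at the center.
    """

    amplitude_mv: float
    center_freq_hz: float
    duration_ms: float

    def render(self, time_ms: np.ndarray, center_ms: float) -> np.ndarray:
        dt = time_ms - center_ms
        sigma = self.duration_ms / 3.0
        envelope = np.exp(-0.5 * (dt / sigma) ** 2)
        envelope[np.abs(dt) > self.duration_ms / 2.0] = 0.0
        return self.amplitude_mv * envelope * np.cos(
            2.0 * np.pi * self.center_freq_hz * dt / 1000.0
        )


@dataclass
class WaveformParams:
    """Parameters of a simulated multi-beat recording.

    Timing anchors per beat: the R peak sits ``r_first_ms + k*rr``; the LF
    peak precedes it by ``|lf_peak_rel_r_ms|``; the HF burst switches on
    ``hf_onset_rel_lf_ms`` before/after the LF peak.  Defaults place the
    landmarks at the typical observed intervals (HF onset 125 ms and LF
    peak 70 ms before the R peak).
    """

    sample_rate: float = 1000.0
    beat_count: int = 5
    rr_interval_ms: float = 600.0
    lf: Deflection = field(
        default_factory=lambda: Deflection(0.30, 60.0, 60.0)
    )
    hf: Deflection = field(
        default_factory=lambda: Deflection(0.50, 200.0, 70.0)
    )
    qrs_amplitude_mv: float = 1.0
    qrs_width_ms: float = 80.0
    lf_peak_rel_r_ms: float = -70.0
    hf_onset_rel_lf_ms: float = -55.0
    r_first_ms: float = 350.0
    noise_sd_mv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.lf, self.hf):
            if d.amplitude_mv > 0 and not (30.0 < d.center_freq_hz < 500.0):
                raise ParameterError(
                    "deflection center frequencies must lie in (30, 500) Hz"
                )
            if d.amplitude_mv < 0 or d.duration_ms <= 0:
                raise ParameterError("deflection amplitude/duration invalid")
        if self.noise_sd_mv < 0:
            raise ParameterError("noise_sd_mv must be >= 0")
        if self.beat_count < 1 or self.rr_interval_ms <= 0:
            raise ParameterError("need beat_count >= 1 and rr_interval_ms > 0")
        if self.sample_rate < 2 * 500.0:
            raise ParameterError("sample_rate must cover twice the 500 Hz band edge")


def simulate_waveform(
    params: WaveformParams,
) -> tuple[ElectrogramRecording, list[Landmarks]]:
    """Render a recording and the true landmarks of each beat.

    The ablation channel is the sum of the LF and HF bursts of every beat
    plus white noise; lead I carries a smooth Gaussian QRS per beat.  The
    ground-truth HF onset is the burst's truncation point (envelope
    switch-on), the LF peak its envelope center, and the R peak the QRS
    apex.
    """
    p = params
    duration = p.r_first_ms + (p.beat_count - 1) * p.rr_interval_ms + max(
        p.rr_interval_ms - p.r_first_ms, 250.0
    )
    n = int(round(duration * p.sample_rate / 1000.0))
    time = np.arange(n) * (1000.0 / p.sample_rate)
    rng = np.random.default_rng(p.seed)

    abl = np.zeros(n)
    lead = np.zeros(n)
    truth = []
    qrs_sigma = p.qrs_width_ms / 6.0
    for k in range(p.beat_count):
        r_peak = p.r_first_ms + k * p.rr_interval_ms
        lf_peak = r_peak + p.lf_peak_rel_r_ms
        hf_onset = lf_peak + p.hf_onset_rel_lf_ms
        hf_center = hf_onset + p.hf.duration_ms / 2.0
        abl += p.lf.render(time, lf_peak)
        abl += p.hf.render(time, hf_center)
        lead += p.qrs_amplitude_mv * np.exp(
            -0.5 * ((time - r_peak) / qrs_sigma) ** 2
        )
        truth.append(Landmarks(
            hf_onset_ms=hf_onset, lf_peak_ms=lf_peak, r_peak_ms=r_peak
        ))
    if p.noise_sd_mv > 0:
        abl = abl + rng.normal(0.0, p.noise_sd_mv, n)
        lead = lead + rng.normal(0.0, p.noise_sd_mv, n)
    recording = ElectrogramRecording(
        sample_rate=p.sample_rate, time=time, abl_distal=abl, lead_i=lead,
        meta={"seed": str(p.seed)},
    )
    return recording, truth


# ---------------------------------------------------------------------------
# feature cohorts

#: class-conditional (median, q25, q75) anchors for the skewed features,
#: matching the validation cohort's per-class summary; features are drawn
#: log-normal with these medians/IQRs.
COHORT_ANCHORS: dict[str, dict[str, tuple[float, float, float]]] = {
    "hf_amplitude": {
        SUCCESSFUL: (0.53, 0.30, 0.91), UNSUCCESSFUL: (0.31, 0.17, 0.67)},
    "lf_amplitude": {
        SUCCESSFUL: (0.30, 0.21, 0.44), UNSUCCESSFUL: (0.19, 0.13, 0.28)},
    "hf_to_lf_time": {
        SUCCESSFUL: (52.0, 44.0, 62.0), UNSUCCESSFUL: (57.0, 45.0, 70.0)},
    "hf_to_r_time": {
        SUCCESSFUL: (126.0, 107.0, 143.0), UNSUCCESSFUL: (129.0, 109.0, 143.0)},
    "hf_integral_total": {
        SUCCESSFUL: (11.6, 7.5, 16.2), UNSUCCESSFUL: (6.8, 5.1, 11.3)},
    "hf_integral_windowed": {
        SUCCESSFUL: (7.7, 5.8, 10.9), UNSUCCESSFUL: (3.9, 2.9, 5.8)},
    "lf_integral": {
        SUCCESSFUL: (10.8, 6.8, 16.1), UNSUCCESSFUL: (7.3, 4.5, 10.6)},
    "composite_score": {
        SUCCESSFUL: (5.4, 3.7, 8.3), UNSUCCESSFUL: (2.3, 1.6, 3.2)},
}

#: LF-to-R time is approximately symmetric: (mean, SD) per class
LF_TO_R_NORMAL: dict[str, tuple[float, float]] = {
    SUCCESSFUL: (71.0, 27.0), UNSUCCESSFUL: (70.0, 22.0),
}

#: accessory-pathway location codes on the two AV rings
LEFT_AP_LOCATIONS = ("LAL", "LL", "LPL", "LPS")
RIGHT_AP_LOCATIONS = ("RA", "RAL", "RAS", "RMS", "RL", "RP", "RPL", "MCV", "RAA")


def class_lognormal_params(feature: str, outcome: str) -> tuple[float, float]:
    """(mu, sigma) of ``log(feature)`` implied by the class anchors."""
    med, q25, q75 = COHORT_ANCHORS[feature][outcome]
    return float(np.log(med)), float((np.log(q75) - np.log(q25)) / (2 * _Z75))


@dataclass
class CohortParams:
    """Parameters of a simulated feature cohort.

    ``lesion_count_probs`` is the per-patient distribution of lesions
    delivered (median 2, a ~23% tail of difficult procedures, mean ~2.3
    signals per patient); each lesion contributes one signal and the final
    lesion is the successful one with probability ``success_rate``.
    ``patient_effect_sd`` is the SD of the patient-level random effect on
    the log composite score; the residual SD shrinks so the marginal
    class distributions keep their anchored medians/IQRs.
    """

    n_patients: int = 144
    lesion_count_probs: dict[int, float] = field(default_factory=lambda: {
        1: 0.40, 2: 0.37, 3: 0.08, 4: 0.05, 5: 0.04, 7: 0.03, 10: 0.02,
        15: 0.01,
    })
    success_rate: float = 0.97
    patient_effect_sd: float = 0.2
    male_prevalence: float = 0.67
    left_ap_prevalence: float = 0.46
    chd_prevalence: float = 0.05
    cryo_prevalence: float = 0.06
    transseptal_prevalence: float = 0.67  # among left-sided pathways
    atrial_pacing_prevalence: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if not (0.0 <= self.success_rate <= 1.0):
            raise ParameterError("success_rate must lie in [0, 1]")
        total = sum(self.lesion_count_probs.values())
        if abs(total - 1.0) > 1e-9 or min(self.lesion_count_probs) < 1:
            raise ParameterError(
                "lesion_count_probs must sum to 1 with counts >= 1"
            )
        if self.patient_effect_sd < 0:
            raise ParameterError("patient_effect_sd must be >= 0")
        for outcome in (SUCCESSFUL, UNSUCCESSFUL):
            _, sigma = class_lognormal_params("composite_score", outcome)
            if self.patient_effect_sd >= sigma:
                raise ParameterError(
                    "patient_effect_sd exceeds the marginal log-score SD; "
                    "the class calibration would be infeasible"
                )


def simulate_cohort(params: CohortParams) -> list[SignalRecord]:
    """Draw a per-patient clustered cohort of labelled signal records.

    Signals are generated patient by patient: a lesion count is drawn, the
    final lesion is successful with probability ``success_rate``, and each
    signal's features are drawn from its class-conditional distribution.
    The composite score carries a shared patient-level random effect on the
    log scale.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    counts = np.array(sorted(p.lesion_count_probs))
    probs = np.array([p.lesion_count_probs[c] for c in counts])

    records = []
    for i in range(p.n_patients):
        patient_id = f"P{i:04d}"
        n_lesions = int(rng.choice(counts, p=probs))
        final_success = rng.random() < p.success_rate
        male = rng.random() < p.male_prevalence
        left = rng.random() < p.left_ap_prevalence
        chd = rng.random() < p.chd_prevalence
        cryo = rng.random() < p.cryo_prevalence
        paced = rng.random() < p.atrial_pacing_prevalence
        if left:
            location = str(rng.choice(LEFT_AP_LOCATIONS))
            approach = (
                "transseptal" if rng.random() < p.transseptal_prevalence
                else "retrograde"
            )
        else:
            location = str(rng.choice(RIGHT_AP_LOCATIONS))
            approach = None
        patient_effect = rng.normal(0.0, p.patient_effect_sd)

        for k in range(n_lesions):
            outcome = (
                SUCCESSFUL if (k == n_lesions - 1 and final_success)
                else UNSUCCESSFUL
            )
            values: dict[str, float] = {}
            for name in COHORT_ANCHORS:
                mu, sigma = class_lognormal_params(name, outcome)
                if name == "composite_score":
                    resid = float(np.sqrt(sigma**2 - p.patient_effect_sd**2))
                    values[name] = float(np.exp(
                        mu + patient_effect + rng.normal(0.0, resid)
                    ))
                else:
                    values[name] = float(np.exp(mu + rng.normal(0.0, sigma)))
            mean, sd = LF_TO_R_NORMAL[outcome]
            values["lf_to_r_time"] = float(rng.normal(mean, sd))
            # honour the feature invariants: windowed areas cannot exceed
            # the total rectified HF area
            values["hf_integral_total"] = max(
                values["hf_integral_total"], values["composite_score"],
                values["hf_integral_windowed"],
            )
            values["hf_ratio"] = (
                values["composite_score"] / values["hf_integral_total"]
            )
            records.append(SignalRecord(
                signal_id=f"{patient_id}-{k + 1}",
                patient_id=patient_id,
                outcome=outcome,
                features=SignalFeatures(**values),
                gender="male" if male else "female",
                ap_side="left" if left else "right",
                ap_location=location,
                chd=chd,
                catheter_type="cryo-6mm" if cryo else "rf-4mm",
                energy="cryo" if cryo else "RF",
                approach=approach,
                atrial_paced=paced,
                lesions_in_case=n_lesions,
            ))
    if not records:
        raise ValidationError("simulated cohort is empty")
    return records
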
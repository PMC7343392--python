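"""Synthetic study-shaped datasets with known ground truth.

Every downstream stage of the pipeline is testable without external data:

* behavioral trial tables drawn from the equal-variance Gaussian SDT model at
  per-valence (d', c), with recollection (name choice among three) given a hit;
* beat timelines whose successive R-R differences carry a band-limited latent
  component shared with the LC BOLD channel, so that BOLD-HRV coherence
  magnitude and phase are controlled exactly;
* stage-structured saliva alpha-amylase with persistent per-stage offsets and
  log-normal noise (sAA is non-negative and right-skewed);
* a per-subject-per-stage latent arousal factor that raises ΔsAA and lowers
  R-R variability together, giving the within-subject sAA/rMSSD coupling the
  association stage is meant to detect.

Coupling construction.  The latent ``u`` is built by selecting the in-band
bins of a white-noise spectrum (an exact zero-phase band-pass); the partner
copy is phase-shifted in the frequency domain, so the shift is exact at every
in-band frequency with no group-delay distortion.  Mixing weights come from
the magnitude-squared-coherence definition as a shared-power ratio: with
channel i = a_i*u + n_i and in-band latent PSD P_s = 1/W (unit variance over
bandwidth W), the in-band MSC is the product of the two signal fractions
rho_i = a_i^2 P_s / (a_i^2 P_s + P_{n_i}(f0)); setting rho_x = rho_y =
sqrt(target_msc) and solving for a_i is closed-form.

For the beat channel the latent must survive the pipeline's differencing of
R-R intervals, a linear filter H(f) = 1 - e^{-i 2 pi f m} (m = mean R-R).
The R-R *level* series therefore carries the latent pre-divided by H (gain
and phase compensated at every in-band bin), and white per-beat jitter plays
the role of the noise channel — its differenced one-sided PSD,
2 m sigma_w^2 |H(f0)|^2, enters the same closed-form mixing solution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from lcmem.config import (
    BehaviorSpec,
    CohortConfig,
    ConfigurationError,
    CouplingSpec,
    SAA_SCHEDULE,
    VALENCES,
    child_rng,
)
from lcmem.dataset import ROI_CHANNELS, StudyDataset
from lcmem.physio_hrv import DEFAULT_SAA_STAGE_MAP, BeatTimeline

# namespaces for the counter-based seed scheme
_NS_BEHAVIOR, _NS_BEATS, _NS_ROI, _NS_SAA, _NS_AROUSAL = range(5)


# --------------------------------------------------------------------------
# behavioral cohort
# --------------------------------------------------------------------------

def gen_behavioral_cohort(config: CohortConfig, spec: BehaviorSpec) -> pd.DataFrame:
    """Trial table for the whole cohort under the equal-variance SDT model.

    Old-item familiarity ~ N(d', 1), new-item ~ N(0, 1); "old" response when
    familiarity > d'/2 + c, giving hit rate Phi(d'/2 - c) and false-alarm rate
    Phi(-d'/2 - c).  Recollection (correct name out of three) is drawn only
    for endorsed old faces.
    """
    rows = []
    for subject in range(config.n_subjects):
        rng = child_rng(config.seed, _NS_BEHAVIOR, subject)
        for valence in VALENCES:
            dprime = spec.dprime_by_valence[valence]
            crit = spec.criterion_by_valence[valence]
            p_rec = spec.recollection_prob_by_valence[valence]
            threshold = dprime / 2.0 + crit
            n_old = spec.n_old_per_valence[valence]
            n_new = spec.n_new_per_valence[valence]
            fam_old = rng.normal(dprime, 1.0, n_old)
            fam_new = rng.normal(0.0, 1.0, n_new)
            for is_old, fams in ((True, fam_old), (False, fam_new)):
                for fam in fams:
                    recognized = bool(fam > threshold)
                    recollected = np.nan
                    rt_rec = np.nan
                    if recognized and is_old:
                        recollected = float(rng.random() < p_rec)
                        rt_rec = float(rng.lognormal(np.log(1.9), 0.2))
                    rows.append(
                        {
                            "subject": subject,
                            "valence": valence,
                            "is_old": is_old,
                            "recognized": recognized,
                            "recollected": recollected,
                            "rt_recognition": float(rng.lognormal(np.log(1.5), 0.2)),
                            "rt_recollection": rt_rec,
                        }
                    )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# beat series
# --------------------------------------------------------------------------

def _inject_artifacts(times: np.ndarray, artifact_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Displace a random fraction of beats toward their predecessor.

    Each displaced beat produces one implausibly short and one long interval,
    the signature of a spurious pulse detection.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise ConfigurationError("artifact_rate must lie in [0, 1]")
    times = times.copy()
    n = len(times)
    n_bad = int(round(artifact_rate * n))
    if n_bad == 0:
        return times
    candidates = np.arange(1, n - 1)
    bad = rng.choice(candidates, size=min(n_bad, len(candidates)), replace=False)
    for i in np.sort(bad):
        times[i] = times[i] - 0.6 * (times[i] - times[i - 1])
    order = np.argsort(times)
    times = times[order]
    times = times[np.concatenate(([True], np.diff(times) > 1e-6))]
    return times


def gen_beat_series(
    config: CohortConfig,
    mean_rr_ms: float = 1000.0,
    rr_sd_ms: float = 50.0,
    artifact_rate: float = 0.0,
    stage: str = "baseline",
    rng: np.random.Generator | None = None,
) -> BeatTimeline:
    """I.i.d. Gaussian R-R beat timeline with optional artifact contamination.

    The artifact-free timestamps are retained on ``clean_times`` so cleaning
    can be scored against ground truth.  For i.i.d. Gaussian R-R intervals
    with standard deviation sigma, the ground-truth rMSSD is sigma*sqrt(2).
    """
    if not 300.0 <= mean_rr_ms <= 2400.0:
        raise ConfigurationError("mean_rr_ms outside the physiological 25-200 bpm band")
    if rr_sd_ms < 0:
        raise ConfigurationError("rr_sd_ms must be >= 0")
    if not 0.0 <= artifact_rate <= 1.0:
        raise ConfigurationError("artifact_rate must lie in [0, 1]")
    rng = rng if rng is not None else child_rng(config.seed, _NS_BEATS, 0)
    duration = config.duration
    n_beats = int(duration / (mean_rr_ms / 1000.0))
    rr = rng.normal(mean_rr_ms, rr_sd_ms, n_beats) / 1000.0
    rr = np.clip(rr, 0.25 * mean_rr_ms / 1000.0, None)
    clean = np.cumsum(rr)
    times = _inject_artifacts(clean, artifact_rate, rng)
    return BeatTimeline(times=times, stage=stage, clean_times=clean)


# --------------------------------------------------------------------------
# coupled series
# --------------------------------------------------------------------------

def _fine_grid(config: CohortConfig) -> tuple[int, float, int]:
    dt = config.sampling_interval
    step = max(1, int(round(dt / 0.25)))
    return step, dt / step, config.series_length * step


def _band_limited_latent(
    rng: np.random.Generator, n: int, dt: float, band_center: float, band_width: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-variance latent whose spectrum occupies exactly the in-band bins."""
    freqs = np.fft.rfftfreq(n, dt)
    inband = (freqs >= band_center - band_width / 2) & (freqs <= band_center + band_width / 2)
    if not inband.any():
        inband[np.argmin(np.abs(freqs - band_center))] = True
    spec = np.zeros(len(freqs), complex)
    k = int(inband.sum())
    spec[inband] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    u = np.fft.irfft(spec, n)
    sd = u.std()
    if sd == 0:
        raise ConfigurationError("degenerate latent (empty band)")
    return u / sd, freqs, inband


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = rng.normal(0.0, innov_sd, n + 200)
    x = np.empty(n + 200)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, len(x)):
        x[i] = phi * x[i - 1] + e[i]
    return x[200:]


def _ar1_psd(f: float, sd: float, phi: float, dt: float) -> float:
    """One-sided PSD of a mean-zero AR(1) with marginal variance sd^2 at frequency f."""
    innov_var = sd**2 * (1.0 - phi**2)
    return 2.0 * dt * innov_var / (1.0 + phi**2 - 2.0 * phi * np.cos(2.0 * np.pi * f * dt))


def gen_coupled_series(
    config: CohortConfig,
    spec: CouplingSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair of series with expected in-band MSC = target_msc, phase = target_phase.

    Positive ``target_phase`` means the first series leads.  Both channels are
    a*latent + AR(1) noise; see the module docstring for the closed-form
    mixing weight.
    """
    spec.validate_against(config)
    rng = rng if rng is not None else child_rng(config.seed, _NS_ROI, 0)
    n, dt = config.series_length, config.sampling_interval
    u, freqs, inband = _band_limited_latent(rng, n, dt, spec.band_center, spec.band_width)
    df = freqs[1] if len(freqs) > 1 else 1.0
    p_latent = 1.0 / (inband.sum() * df)  # one-sided in-band PSD of the unit-variance latent
    rho = np.sqrt(spec.target_msc)

    uspec = np.fft.rfft(u)
    shifted = np.zeros_like(uspec)
    shifted[inband] = uspec[inband] * np.exp(-1j * spec.target_phase)
    u_shift = np.fft.irfft(shifted, n)

    if rho == 1.0:
        return u.copy(), u_shift
    if rho == 0.0:
        a = 0.0
    else:
        if spec.noise_sd == 0:
            raise ConfigurationError("target_msc < 1 is infeasible with noise_sd = 0")
        p_noise = _ar1_psd(spec.band_center, spec.noise_sd, spec.ar1_coefficient, dt)
        a = np.sqrt(rho / (1.0 - rho) * p_noise / p_latent)
    x = a * u + _ar1_noise(rng, n, spec.ar1_coefficient, spec.noise_sd)
    y = a * u_shift + _ar1_noise(rng, n, spec.ar1_coefficient, spec.noise_sd)
    return x, y


def _coupled_stage(
    rng: np.random.Generator,
    config: CohortConfig,
    spec: CouplingSpec,
    mean_rr_s: float,
    rr_sd_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(LC BOLD series, beat times) sharing the in-band latent of ``spec``.

    The R-R level series carries latent/H(f) so that the pipeline's successive
    differencing restores the latent at exactly ``target_phase`` relative to
    the LC channel (LC is the *first* series of the pair).
    """
    spec.validate_against(config)
    n, dt = config.series_length, config.sampling_interval
    step, dt_f, n_f = _fine_grid(config)
    u, freqs, inband = _band_limited_latent(rng, n_f, dt_f, spec.band_center, spec.band_width)
    df = freqs[1]
    p_latent = 1.0 / (inband.sum() * df)
    rho = np.sqrt(spec.target_msc)

    # LC channel sampled at the TR grid
    if rho == 1.0:
        lc = u[::step].copy()
    elif rho == 0.0:
        lc = _ar1_noise(rng, n, spec.ar1_coefficient, spec.noise_sd)
    else:
        if spec.noise_sd == 0:
            raise ConfigurationError("target_msc < 1 is infeasible with noise_sd = 0")
        p_noise = _ar1_psd(spec.band_center, spec.noise_sd, spec.ar1_coefficient, dt)
        a_x = np.sqrt(rho / (1.0 - rho) * p_noise / p_latent)
        lc = a_x * u[::step] + _ar1_noise(rng, n, spec.ar1_coefficient, spec.noise_sd)

    # beat channel: pre-compensate the difference filter H(f) = 1 - e^{-i2pi f m}
    m = mean_rr_s
    H = 1.0 - np.exp(-1j * 2.0 * np.pi * freqs * m)
    H0_sq = 4.0 * np.sin(np.pi * spec.band_center * m) ** 2
    inv_h2_mean = float(np.mean(1.0 / np.abs(H[inband]) ** 2))
    if rho == 0.0:
        a_y, sigma_w = 0.0, rr_sd_s
    else:
        denom = inv_h2_mean + p_latent * (1.0 - rho) / (2.0 * m * rho * H0_sq)
        a_y = rr_sd_s / np.sqrt(denom)
        sigma_w = np.sqrt(max(rr_sd_s**2 - a_y**2 * inv_h2_mean, 0.0))

    uspec = np.fft.rfft(u)
    vspec = np.zeros_like(uspec)
    vspec[inband] = uspec[inband] * a_y * np.exp(-1j * spec.target_phase) / H[inband]
    v = np.fft.irfft(vspec, n_f)

    duration = config.duration
    n_beats = int(duration / m) - 1
    t_fine = np.arange(n_f) * dt_f
    vspline = CubicSpline(t_fine, v)
    w = rng.normal(0.0, sigma_w, n_beats)
    # the beat clock drifts with the cumulative jitter, so the latent must be
    # evaluated at the *actual* beat times; a short fixed-point iteration on
    # t_k = t_{k-1} + m + v(t_k) + w_k converges quickly (v is slow and small)
    beat_times = m * (np.arange(n_beats) + 1.0)
    for _ in range(3):
        v_at = vspline(np.clip(beat_times, 0.0, t_fine[-1]))
        rr = np.clip(m + v_at + w, 0.3 * m, None)
        beat_times = np.cumsum(rr)
    return lc, beat_times


# --------------------------------------------------------------------------
# full stage dataset
# --------------------------------------------------------------------------

def gen_stage_dataset(
    config: CohortConfig,
    coupling_by_stage: dict[str, CouplingSpec] | None = None,
    behavior: BehaviorSpec | None = None,
    saa_effects: dict[str, float] | None = None,
    mean_rr_ms: float = 1000.0,
    rr_sd_ms: float = 40.0,
    artifact_rate: float = 0.02,
    saa_baseline_median: float = 50.0,
    saa_between_sd: float = 0.4,
    saa_noise_sd: float = 0.12,
    arousal_saa_gain: float = 12.0,
    arousal_rr_gain: float = 0.25,
) -> StudyDataset:
    """Complete synthetic study: trials, beats, ROI series and sAA samples.

    ``saa_effects`` maps a stage to a persistent sAA increment (U/ml) arising
    during that stage — applied at the stage-end sample and all later samples,
    so the stage's ΔsAA recovers the increment without contaminating the next
    stage's difference.  The latent arousal factor z (per subject × stage)
    adds ``arousal_saa_gain * z`` to the same step and scales R-R variability
    by ``exp(-arousal_rr_gain * z)``, producing a negative within-subject
    ΔsAA-rMSSD association like the one the analysis stage estimates.
    """
    behavior = behavior if behavior is not None else BehaviorSpec()
    coupling_by_stage = coupling_by_stage or {stage: CouplingSpec() for stage in config.stages}
    missing = set(config.stages) - set(coupling_by_stage)
    if missing:
        raise ConfigurationError(f"coupling_by_stage missing stages: {sorted(missing)}")
    extra = set(coupling_by_stage) - set(config.stages)
    if extra:
        raise ConfigurationError(f"coupling_by_stage has unknown stages: {sorted(extra)}")
    saa_effects = saa_effects or {}
    unknown = set(saa_effects) - set(config.stages)
    if unknown:
        raise ConfigurationError(f"saa_effects has unknown stages: {sorted(unknown)}")

    trials = gen_behavioral_cohort(config, behavior)

    m = mean_rr_ms / 1000.0
    rr_sd_base = rr_sd_ms / 1000.0
    beats: dict[tuple[int, str], BeatTimeline] = {}
    roi: dict[tuple[int, str], pd.DataFrame] = {}
    arousal: dict[str, dict[str, float]] = {}
    t_grid = np.arange(config.series_length) * config.sampling_interval
    for subject in range(config.n_subjects):
        arousal[str(subject)] = {}
        for stage_idx, stage in enumerate(config.stages):
            z = float(child_rng(config.seed, _NS_AROUSAL, subject, stage_idx).standard_normal())
            arousal[str(subject)][stage] = z
            rr_sd = rr_sd_base * np.exp(-arousal_rr_gain * z)
            rng = child_rng(config.seed, _NS_ROI, subject, stage_idx)
            lc, beat_times = _coupled_stage(rng, config, coupling_by_stage[stage], m, rr_sd)
            beat_times = _inject_artifacts(beat_times, artifact_rate, rng)
            beats[(subject, stage)] = BeatTimeline(times=beat_times, stage=stage)
            frame = {"time": t_grid, "lc": lc}
            for channel in ROI_CHANNELS[1:]:
                frame[channel] = _ar1_noise(rng, config.series_length, 0.3, 1.0)
            roi[(subject, stage)] = pd.DataFrame(frame)

    # seven-sample sAA schedule with persistent steps at stage ends
    end_label_index = {
        stage: SAA_SCHEDULE.index(DEFAULT_SAA_STAGE_MAP[stage][1]) for stage in config.stages
    }
    saa_rows = []
    for subject in range(config.n_subjects):
        rng = child_rng(config.seed, _NS_SAA, subject)
        level = saa_baseline_median * np.exp(saa_between_sd * rng.standard_normal())
        for j, label in enumerate(SAA_SCHEDULE):
            stepsum = sum(
                saa_effects.get(stage, 0.0) + arousal_saa_gain * arousal[str(subject)][stage]
                for stage in config.stages
                if end_label_index[stage] <= j
            )
            value = (level + stepsum) * np.exp(saa_noise_sd * rng.standard_normal())
            saa_rows.append({"subject": subject, "label": label, "value": max(float(value), 1.0)})
    saa = pd.DataFrame(saa_rows)

    ground_truth = {
        "coupling_by_stage": {k: v for k, v in coupling_by_stage.items()},
        "behavior": behavior,
        "saa_effects": dict(saa_effects),
        "arousal_factors": arousal,
        "mean_rr_ms": mean_rr_ms,
        "rr_sd_ms": rr_sd_ms,
        "artifact_rate": artifact_rate,
        "seed": config.seed,
    }
    return StudyDataset(
        config=config, trials=trials, beats=beats, roi=roi, saa=saa, ground_truth=ground_truth
    )
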
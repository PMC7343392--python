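"""Study configuration types shared across the pipeline.

All knobs are plain dataclasses with eager validation; a single integer seed
expands deterministically into per-subject / per-stage child streams via
:func:`child_rng` (counter-based ``SeedSequence`` spawn keys), so any subset
of the cohort is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

#: The four task stages of the paradigm, in temporal order.
DEFAULT_STAGES: tuple[str, ...] = ("baseline", "encoding", "consolidation", "recollection")

#: Saliva sampling schedule (seven samples around the scan session).
SAA_SCHEDULE: tuple[str, ...] = (
    "pre_bore",
    "pre_baseline",
    "pre_encoding",
    "post_encoding",
    "pre_recollection",
    "post_recollection",
    "post_30min",
)

VALENCES: tuple[str, str] = ("emotional", "neutral")


class ConfigurationError(ValueError):
    """Raised when a study configuration violates its invariants."""


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for (seed, key...) without global state.

    The spawn key acts as a counter-based address (e.g. ``(subject, stage)``),
    so regenerating a single subject/stage yields bit-identical draws.
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key)))


def _as_valence_map(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(VALENCES) - set(value)
        if missing:
            raise ConfigurationError(f"{name} missing valences: {sorted(missing)}")
        return {v: float(value[v]) for v in VALENCES}
    return {v: float(value) for v in VALENCES}


@dataclass(frozen=True)
class CohortConfig:
    """Shape of the synthetic cohort.

    ``sampling_interval`` is the BOLD repetition time in seconds (TR = 2 s in
    the paradigm this emulates); ``series_length`` is the number of BOLD
    samples per task stage (default 360, i.e. 12 min — the stages of the
    paradigm run roughly 6-15 min).
    """

    n_subjects: int = 20
    stages: tuple[str, ...] = DEFAULT_STAGES
    sampling_interval: float = 2.0
    series_length: int = 360
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.sampling_interval <= 0:
            raise ConfigurationError("sampling_interval must be > 0")
        if not self.stages or len(set(self.stages)) != len(self.stages):
            raise ConfigurationError("stages must be non-empty and unique")
        if self.series_length < 8:
            raise ConfigurationError("series_length too short")

    @property
    def nyquist(self) -> float:
        return 0.5 / self.sampling_interval

    @property
    def duration(self) -> float:
        """Stage duration in seconds."""
        return self.series_length * self.sampling_interval


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth BOLD-HRV coupling for one stage.

    Two series share a band-limited latent component (one copy phase-shifted
    by ``target_phase``; positive phase means the *first* series leads) on top
    of independent AR(1) noise.  The mixing weight is solved analytically so
    the expected magnitude-squared coherence in the band equals
    ``target_msc`` (see :mod:`lcmem.synthetic_data`).
    """

    band_center: float = 0.2
    band_width: float = 0.02
    target_msc: float = 0.5
    target_phase: float = 0.0
    ar1_coefficient: float = 0.3
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_msc <= 1.0:
            raise ConfigurationError("target_msc must lie in [0, 1]")
        if not -1.0 < self.ar1_coefficient < 1.0:
            raise ConfigurationError("|ar1_coefficient| must be < 1")
        if not -np.pi < self.target_phase <= np.pi:
            raise ConfigurationError("target_phase must lie in (-pi, pi]")
        if self.band_width <= 0 or self.band_center - self.band_width / 2 <= 0:
            raise ConfigurationError("coupling band must lie strictly above 0 Hz")
        if self.target_msc == 1.0 and self.noise_sd > 0:
            raise ConfigurationError("target_msc = 1 requires noise_sd = 0")

    def validate_against(self, config: CohortConfig) -> None:
        if self.band_center + self.band_width / 2 >= config.nyquist:
            raise ConfigurationError(
                f"coupling band exceeds the Nyquist frequency {config.nyquist:g} Hz"
            )


@dataclass(frozen=True)
class BehaviorSpec:
    """Trial structure and ground-truth memory parameters per valence.

    The recognition decision follows the equal-variance Gaussian SDT model:
    old-item familiarity ~ N(d', 1), new-item familiarity ~ N(0, 1), response
    "old" when familiarity exceeds d'/2 + c.  ``recollection_prob_by_valence``
    is the probability of choosing the correct name (out of three options)
    given a hit; chance level is 1/3.
    """

    n_old_per_valence: int | Mapping[str, int] = 45
    n_new_per_valence: int | Mapping[str, int] = field(
        default_factory=lambda: {"emotional": 23, "neutral": 22}
    )
    dprime_by_valence: float | Mapping[str, float] = field(
        default_factory=lambda: {"emotional": 0.85, "neutral": 1.15}
    )
    criterion_by_valence: float | Mapping[str, float] = field(
        default_factory=lambda: {"emotional": -0.15, "neutral": 0.05}
    )
    recollection_prob_by_valence: float | Mapping[str, float] = field(
        default_factory=lambda: {"emotional": 0.55, "neutral": 0.45}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_old_per_valence", {k: int(v) for k, v in _as_valence_map(self.n_old_per_valence, "n_old_per_valence").items()})
        object.__setattr__(self, "n_new_per_valence", {k: int(v) for k, v in _as_valence_map(self.n_new_per_valence, "n_new_per_valence").items()})
        object.__setattr__(self, "dprime_by_valence", _as_valence_map(self.dprime_by_valence, "dprime_by_valence"))
        object.__setattr__(self, "criterion_by_valence", _as_valence_map(self.criterion_by_valence, "criterion_by_valence"))
        object.__setattr__(self, "recollection_prob_by_valence", _as_valence_map(self.recollection_prob_by_valence, "recollection_prob_by_valence"))
        for name in ("n_old_per_valence", "n_new_per_valence"):
            if any(v <= 0 for v in getattr(self, name).values()):
                raise ConfigurationError(f"{name} counts must be > 0")
        if any(not 0.0 <= p <= 1.0 for p in self.recollection_prob_by_valence.values()):
            raise ConfigurationError("recollection probabilities must lie in [0, 1]")


@dataclass
class RunConfig:
    """Thresholds and sizes for a full pipeline run."""

    seed: int = 0
    bpm_bounds: tuple[float, float] = (25.0, 200.0)
    adaptive_threshold: float = 0.13
    missing_cutoff: float = 0.10
    alpha: float = 0.05
    n_boot: int = 5000
    n_surrogates: int = 200
    n_bins: int = 90
    fmax: float = 0.5
    overlap: float = 0.2
    working_rate: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.bpm_bounds
        if not 0 < lo < hi:
            raise ConfigurationError("bpm_bounds must satisfy 0 < low < high")
        if not 0 < self.adaptive_threshold < 1:
            raise ConfigurationError("adaptive_threshold must lie in (0, 1)")
        if not 0 <= self.missing_cutoff <= 1:
            raise ConfigurationError("missing_cutoff must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_boot < 1 or self.n_surrogates < 1 or self.n_bins < 2:
            raise ConfigurationError("n_boot, n_surrogates and n_bins must be positive")
        if not 0 <= self.overlap < 1:
            raise ConfigurationError("overlap must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)
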
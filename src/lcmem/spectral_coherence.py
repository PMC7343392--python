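"""Cross-spectra, magnitude-squared coherence, phase lag, partial coherence
and AR(1)-surrogate null distributions.

Estimation is Welch-averaged with Hamming tapers, 20 % segment overlap and a
segment length chosen to give ``n_bins`` one-sided bins on [0, fmax] at the
working sampling rate (default: 90 bins on 0-0.5 Hz at 1 Hz).  The
magnitude-squared coherence between series A and B is

    C_AB(f) = |P_AB(f)|^2 / (P_AA(f) P_BB(f))  in [0, 1],

and the phase lag is the four-quadrant angle of the cross-spectrum
P_AB = E[A(f) B(f)*]; positive phase means the *first* series leads.

Partial coherence conditions a pair on the remaining series through the
inverse spectral matrix G = S^-1:  |G_ij|^2 / (G_ii G_jj) per bin.

Surrogate nulls fit an AR(1) to each series, redraw it with fresh innovations
(variance-matched), and collect the band-median coherence between surrogate
pairs; by construction the surrogates keep the original autocorrelation
structure while being independent of each other.

Series sampled coarser than the working rate are cubic-interpolated onto the
working grid.  Interpolation cannot create information above the original
Nyquist frequency — bins beyond it contain only spectral images, which are
spuriously coherent — so band searches should be restricted to the informative
range (the pipeline does this by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralGrid:
    """Welch estimation parameters; ``fs`` must equal ``2 * fmax``."""

    n_bins: int = 90
    fmax: float = 0.5
    overlap: float = 0.2
    window: str = "hamming"
    detrend: bool = True

    @property
    def fs(self) -> float:
        return 2.0 * self.fmax

    @property
    def nperseg(self) -> int:
        return 2 * (self.n_bins - 1)

    @property
    def noverlap(self) -> int:
        return int(round(self.overlap * self.nperseg))

    @property
    def freqs(self) -> np.ndarray:
        return np.fft.rfftfreq(self.nperseg, 1.0 / self.fs)


@dataclass
class SpectralMatrix:
    """Hermitian cross-power density matrix S[f, i, j] over a frequency grid."""

    freqs: np.ndarray
    values: np.ndarray  # (F, p, p) complex
    labels: list[str]
    n_windows: int
    fs: float

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SpectralError(f"series {label!r} not in spectral matrix") from None

    def pair(self, a: str, b: str) -> np.ndarray:
        return self.values[:, self.index(a), self.index(b)]


@dataclass
class CoherenceProfile:
    freqs: np.ndarray
    msc: np.ndarray
    phase: np.ndarray | None = None
    phase_reliable: np.ndarray | None = None


@dataclass
class MaxCoherenceBand:
    """Bootstrap CI of the median per-subject argmax frequency of coherence."""

    median: float
    lower: float
    upper: float
    n_boot: int
    argmax_freqs: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class SurrogateNull:
    ar_coefficients: tuple[float, float]
    values: np.ndarray

    def p_value(self, observed: float) -> float:
        """One-sided exceedance probability with the +1 correction."""
        return float((1 + np.sum(self.values >= observed)) / (1 + len(self.values)))


# --------------------------------------------------------------------------
# resampling
# --------------------------------------------------------------------------

def resample_series(
    times: np.ndarray, values: np.ndarray, fs: float, duration: float | None = None
) -> np.ndarray:
    """Cubic interpolation of an equidistant or irregular series onto fs."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if duration is None:
        duration = times[-1]
    grid = np.arange(0.0, duration, 1.0 / fs)
    spline = CubicSpline(times, values, extrapolate=False)
    out = spline(grid)
    # hold the edges rather than extrapolating the cubic
    out[grid < times[0]] = values[0]
    out[grid > times[-1]] = values[-1]
    return out


# --------------------------------------------------------------------------
# Welch cross-spectral matrix (vectorized over channels and batches)
# --------------------------------------------------------------------------

def _segment_fft(data: np.ndarray, grid: SpectralGrid) -> tuple[np.ndarray, int, float]:
    """rfft of windowed, detrended segments: (..., K, F); also K and PSD scale."""
    n = data.shape[-1]
    nperseg, noverlap = grid.nperseg, grid.noverlap
    if n < nperseg:
        raise SpectralError(
            f"series of length {n} shorter than one Welch segment ({nperseg} samples)"
        )
    step = nperseg - noverlap
    starts = np.arange(0, n - nperseg + 1, step)
    segs = np.stack([data[..., s : s + nperseg] for s in starts], axis=-2)
    if grid.detrend:
        segs = segs - segs.mean(axis=-1, keepdims=True)
    win = signal.get_window(grid.window, nperseg)
    scale = 1.0 / (grid.fs * float(np.sum(win**2)))
    return np.fft.rfft(segs * win, axis=-1), len(starts), scale


def cross_spectra(
    series: dict[str, np.ndarray] | np.ndarray,
    grid: SpectralGrid | None = None,
    labels: list[str] | None = None,
) -> SpectralMatrix:
    """Welch-averaged cross-periodogram matrix for a set of equal-length series.

    ``series`` is either ``{label: 1-D array}`` or a (p, n) array with
    ``labels``.  All series must already be on the working grid (``grid.fs``).
    """
    grid = grid or SpectralGrid()
    if isinstance(series, dict):
        labels = list(series)
        data = np.asarray([series[k] for k in labels], float)
    else:
        data = np.atleast_2d(np.asarray(series, float))
        labels = labels or [f"s{i}" for i in range(data.shape[0])]
    if len({len(row) for row in data}) > 1:
        raise SpectralError("series must have equal length")
    fft, k, scale = _segment_fft(data, grid)  # (p, K, F)
    s = np.einsum("ikf,jkf->fij", fft, np.conj(fft)) * (scale / k)
    # one-sided: double all bins except DC and Nyquist
    s[1:-1] *= 2.0
    return SpectralMatrix(freqs=grid.freqs, values=s, labels=labels, n_windows=k, fs=grid.fs)


def _batch_pair_msc(
    x: np.ndarray, y: np.ndarray, grid: SpectralGrid
) -> tuple[np.ndarray, np.ndarray]:
    """MSC[B, F] for batched pairs (rows of x against rows of y)."""
    fx, k, _ = _segment_fft(np.atleast_2d(x), grid)
    fy, _, _ = _segment_fft(np.atleast_2d(y), grid)
    pxy = np.mean(fx * np.conj(fy), axis=-2)
    pxx = np.mean(np.abs(fx) ** 2, axis=-2)
    pyy = np.mean(np.abs(fy) ** 2, axis=-2)
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = np.abs(pxy) ** 2 / (pxx * pyy)
    return grid.freqs, np.clip(msc, 0.0, 1.0)


# --------------------------------------------------------------------------
# coherence and phase
# --------------------------------------------------------------------------

def msc(matrix: SpectralMatrix, pair: tuple[str, str]) -> CoherenceProfile:
    """Magnitude-squared coherence for one ordered pair; zero-power bins → NaN."""
    a, b = pair
    pab = matrix.pair(a, b)
    paa = np.real(matrix.pair(a, a))
    pbb = np.real(matrix.pair(b, b))
    denom = paa * pbb
    values = np.full(len(matrix.freqs), np.nan)
    ok = denom > 0
    values[ok] = np.abs(pab[ok]) ** 2 / denom[ok]
    return CoherenceProfile(freqs=matrix.freqs, msc=np.clip(values, 0.0, 1.0))


def phase_lag(
    matrix: SpectralMatrix, pair: tuple[str, str], msc_floor: float = 0.1
) -> CoherenceProfile:
    """Four-quadrant cross-spectral phase; positive ⇒ first series leads.

    Bins whose MSC falls below ``msc_floor`` are flagged unreliable (phase of
    near-zero cross-power is noise).
    """
    profile = msc(matrix, pair)
    pab = matrix.pair(*pair)
    profile.phase = np.angle(pab)
    profile.phase_reliable = profile.msc >= msc_floor
    return profile


def coherence_profile(
    matrix: SpectralMatrix, pair: tuple[str, str], msc_floor: float = 0.1
) -> CoherenceProfile:
    return phase_lag(matrix, pair, msc_floor=msc_floor)


# --------------------------------------------------------------------------
# band of maximum coherence
# --------------------------------------------------------------------------

def band_of_max_coherence(
    profiles: list[CoherenceProfile],
    n_boot: int = 5000,
    seed: int = 0,
    fmin: float = 0.01,
    fmax: float | None = None,
    ci: float = 0.95,
) -> MaxCoherenceBand:
    """95 % bootstrap CI of the median per-subject argmax frequency.

    Ties at the maximum resolve to the lowest frequency.  ``fmin``/``fmax``
    restrict the search to the informative range (e.g. below the native
    Nyquist of resampled inputs).
    """
    if len(profiles) < 3:
        raise SpectralError("need at least 3 subjects for the coherence band")
    peaks = []
    for prof in profiles:
        sel = (prof.freqs >= fmin) & (np.isfinite(prof.msc))
        if fmax is not None:
            sel &= prof.freqs <= fmax
        values = prof.msc[sel]
        if len(values) == 0 or np.ptp(values) == 0:
            continue  # flat profile carries no peak information
        peaks.append(prof.freqs[sel][int(np.argmax(values))])
    if len(peaks) < 3:
        raise SpectralError("all coherence profiles flat; no peak frequency defined")
    peaks = np.asarray(peaks)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(peaks), size=(n_boot, len(peaks)))
    boot_medians = np.median(peaks[idx], axis=1)
    lo, hi = np.percentile(boot_medians, [(1 - ci) / 2 * 100, (1 + ci) / 2 * 100])
    med = float(np.median(peaks))
    return MaxCoherenceBand(
        median=med,
        lower=float(min(lo, med)),
        upper=float(max(hi, med)),
        n_boot=n_boot,
        argmax_freqs=peaks,
    )


def _circular_median(angles: np.ndarray) -> float:
    """Angle among the data minimizing total circular distance (first on ties)."""
    angles = np.asarray(angles, float)
    diffs = np.abs(angles[:, None] - angles[None, :]) % (2 * np.pi)
    diffs = np.minimum(diffs, 2 * np.pi - diffs)
    return float(angles[int(np.argmin(diffs.sum(axis=1)))])


def band_summary(
    profile: CoherenceProfile, band: MaxCoherenceBand | tuple[float, float]
) -> tuple[float, float]:
    """(median MSC, circular median phase) over the bins inside the band."""
    lo, hi = (band.lower, band.upper) if isinstance(band, MaxCoherenceBand) else band
    sel = (profile.freqs >= lo) & (profile.freqs <= hi) & np.isfinite(profile.msc)
    if not sel.any():
        raise SpectralError(f"band [{lo:g}, {hi:g}] Hz contains no frequency bins")
    med_msc = float(np.median(profile.msc[sel]))
    med_phase = _circular_median(profile.phase[sel]) if profile.phase is not None else float("nan")
    return med_msc, med_phase


# --------------------------------------------------------------------------
# AR(1) fits and surrogates
# --------------------------------------------------------------------------

def fit_ar1(series: np.ndarray) -> tuple[float, float]:
    """Lag-1 Yule-Walker estimate: (coefficient, innovation variance)."""
    x = np.asarray(series, float)
    if len(x) < 10:
        raise SpectralError("need at least 10 samples to fit an AR(1)")
    x = x - x.mean()
    denom = float(np.sum(x**2))
    if denom == 0:
        raise SpectralError("cannot fit an AR(1) to a constant series")
    phi = float(np.sum(x[1:] * x[:-1]) / denom)
    if abs(phi) >= 1.0:
        warnings.warn(f"AR(1) coefficient {phi:.3f} clipped into (-1, 1)", stacklevel=2)
        phi = float(np.clip(phi, -0.999, 0.999))
    innovation_var = float(np.var(x) * (1.0 - phi**2))
    return phi, innovation_var


def _ar1_batch(
    rng: np.random.Generator, n_series: int, n: int, phi: float, target_var: float
) -> np.ndarray:
    e = rng.standard_normal((n_series, n + 100))
    x = signal.lfilter([1.0], [1.0, -phi], e, axis=-1)[:, 100:]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * np.sqrt(target_var)


def ar1_surrogate(series: np.ndarray, rng: np.random.Generator | int = 0) -> np.ndarray:
    """Fresh-noise AR(1) redraw with the series' fitted coefficient and variance."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(series, float)
    phi, _ = fit_ar1(x)
    surrogate = _ar1_batch(rng, 1, len(x), phi, float(np.var(x)))[0]
    return surrogate + x.mean()


def coherence_null(
    x: np.ndarray,
    y: np.ndarray,
    band: tuple[float, float],
    n_surrogates: int = 200,
    seed: int | np.random.Generator = 0,
    grid: SpectralGrid | None = None,
) -> SurrogateNull:
    """Null distribution of band-median MSC between AR(1)-matched surrogate pairs."""
    grid = grid or SpectralGrid()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    phi_x, _ = fit_ar1(x)
    phi_y, _ = fit_ar1(y)
    sx = _ar1_batch(rng, n_surrogates, len(x), phi_x, float(np.var(x)))
    sy = _ar1_batch(rng, n_surrogates, len(y), phi_y, float(np.var(y)))
    freqs, msc_batch = _batch_pair_msc(sx, sy, grid)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise SpectralError("null band contains no frequency bins")
    return SurrogateNull(
        ar_coefficients=(phi_x, phi_y), values=np.median(msc_batch[:, sel], axis=1)
    )


# --------------------------------------------------------------------------
# partial coherence
# --------------------------------------------------------------------------

def partial_coherence(
    matrix: SpectralMatrix,
    pair: tuple[str, str],
    conditioning: tuple[str, ...] = (),
    ridge: float = 1e-10,
) -> CoherenceProfile:
    """Coherence of ``pair`` after removing the linear influence of ``conditioning``.

    Computed per bin from the inverse spectral matrix G of the sub-matrix over
    pair ∪ conditioning: |G_ij|^2 / (G_ii G_jj).  Near-singular bins are
    ridge-regularized with a warning.  An empty conditioning set reduces to
    ordinary MSC bin-wise.
    """
    if not conditioning:
        profile = msc(matrix, pair)
        pab = matrix.pair(*pair)
        profile.phase = np.angle(pab)
        return profile
    names = [pair[0], pair[1], *conditioning]
    idx = [matrix.index(name) for name in names]
    sub = matrix.values[np.ix_(range(len(matrix.freqs)), idx, idx)]
    q = len(names)
    out = np.full(len(matrix.freqs), np.nan)
    phase = np.full(len(matrix.freqs), np.nan)
    warned = False
    eye = np.eye(q)
    for f in range(len(matrix.freqs)):
        s = sub[f]
        if not np.all(np.isfinite(s)):
            continue
        try:
            cond = np.linalg.cond(s)
        except np.linalg.LinAlgError:
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            if not warned:
                warnings.warn("singular spectral matrix bin; ridge-regularizing", stacklevel=2)
                warned = True
            s = s + ridge * np.real(np.trace(s)) / q * eye
        g = np.linalg.inv(s)
        denom = np.real(g[0, 0]) * np.real(g[1, 1])
        if denom > 0:
            out[f] = np.abs(g[0, 1]) ** 2 / denom
            # partial cross-spectrum has opposite sign convention through G
            phase[f] = np.angle(-g[0, 1])
    return CoherenceProfile(freqs=matrix.freqs, msc=np.clip(out, 0.0, 1.0), phase=phase)


def partial_coherence_all(matrix: SpectralMatrix, ridge: float = 1e-10) -> dict[tuple[str, str], np.ndarray]:
    """Partial coherence of every pair given all remaining series (batched).

    Equivalent to :func:`partial_coherence` with the full conditioning set for
    each pair, but inverts the spectral matrix once per bin.
    """
    s = matrix.values.copy()
    q = s.shape[1]
    eye = np.eye(q)
    try:
        g = np.linalg.inv(s)
    except np.linalg.LinAlgError:
        g = np.empty_like(s)
        for f in range(s.shape[0]):
            try:
                g[f] = np.linalg.inv(s[f])
            except np.linalg.LinAlgError:
                g[f] = np.linalg.inv(s[f] + ridge * np.real(np.trace(s[f])) / q * eye)
    diag = np.real(np.einsum("fii->fi", g))
    out: dict[tuple[str, str], np.ndarray] = {}
    for i in range(q):
        for j in range(i + 1, q):
            denom = diag[:, i] * diag[:, j]
            with np.errstate(invalid="ignore", divide="ignore"):
                values = np.abs(g[:, i, j]) ** 2 / denom
            values[denom <= 0] = np.nan
            out[(matrix.labels[i], matrix.labels[j])] = np.clip(values, 0.0, 1.0)
    return out


def partial_coherence_test(
    observed: np.ndarray, null_medians: np.ndarray
) -> tuple[float, float]:
    """Paired signed-rank test of per-subject observed vs. matched-null band medians."""
    from lcmem.behavioral_sdt import paired_compare

    observed = np.asarray(observed, float)
    null_medians = np.asarray(null_medians, float)
    if observed.shape != null_medians.shape:
        raise SpectralError("observed and null medians must be paired")
    d = observed - null_medians
    d = d[~np.isnan(d)]
    if len(d) < 5:
        # exact signed-rank distribution for tiny samples
        from scipy.stats import wilcoxon

        if np.allclose(d, 0):
            return 0.0, 1.0
        res = wilcoxon(d, method="exact")
        return float(res.statistic), float(res.pvalue)
    return paired_compare(observed, null_medians, method="wilcoxon")
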
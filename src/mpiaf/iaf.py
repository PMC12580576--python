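"""Individual alpha frequency (IAF) from resting-state recordings.

Three IAF measures are computed from eyes-closed parieto-occipital EEG:

* **PAF** — peak alpha frequency: the frequency of the maximum of the
  Savitzky-Golay-smoothed log PSD within the 7-13 Hz alpha band,
  per channel, averaged over channels with a detectable peak.
* **COG** — centre of gravity: the power-weighted mean frequency over
  the alpha band (on smoothed linear power), per channel, averaged.
* **F_PAF** — the alpha peak's centre frequency after removing the
  1/f aperiodic background, from a spectral parameterization fit
  (aperiodic line in log-log coordinates plus one Gaussian peak) to the
  channel-averaged spectrum of each 60-s trial; accepted trial peaks
  are averaged.

Channel aggregation follows the source study's rules: at least nine of
the 19 parieto-occipital channels must yield an estimate (two of three
for the O1/Oz/O2 subset), otherwise the measure is missing for that
observer.  Spectral-model fits with R^2 < 0.6 are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .cohort import Recording

__all__ = [
    "SpectralSettings",
    "PSDEstimate",
    "SpectrumModel",
    "IAFEstimate",
    "preprocess",
    "welch_psd",
    "smooth_alpha",
    "estimate_paf",
    "estimate_cog",
    "aggregate_iaf",
    "fit_spectral_model",
    "f_paf_from_trials",
    "estimate_iaf",
]

OCCIPITAL_3 = ("O1", "Oz", "O2")


@dataclass
class SpectralSettings:
    """Spectral-analysis parameters.

    Welch segments are 4-s Hamming windows with 50% overlap, giving a
    0.25 Hz grid so that the 11-bin smoothing frame spans 2.75 Hz.
    ``peak_width_hz`` bounds the full width of the fitted alpha peak;
    Gaussian SD bounds are half of these.
    """

    fs_target: float = 256.0
    band_hz: tuple[float, float] = (1.0, 40.0)
    epoch_seconds: float = 60.0
    welch_window_s: float = 4.0
    welch_overlap: float = 0.5
    smooth_frame: int = 11
    smooth_order: int = 5
    alpha_band: tuple[float, float] = (7.0, 13.0)
    fit_range: tuple[float, float] = (2.0, 20.0)
    peak_width_hz: tuple[float, float] = (0.5, 12.0)
    r2_min: float = 0.6
    peak_threshold_sd: float = 2.0  # candidate peak height, in flattened-SD units
    min_channels: int = 9
    electrode_set: str = "all_19"  # or "occipital_3"

    def min_channels_for(self, n_channels: int) -> int:
        if self.electrode_set == "occipital_3":
            return 2
        return self.min_channels


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs), linear uV^2/Hz
    resolution: float
    channel_labels: tuple[str, ...]

    @property
    def log_power(self) -> np.ndarray:
        return np.log10(self.power)


@dataclass
class SpectrumModel:
    aperiodic_offset: float
    aperiodic_exponent: float
    peak_cf: float
    peak_power: float
    peak_bw: float  # Gaussian SD, Hz
    r_squared: float
    has_peak: bool
    message: str = ""


@dataclass
class IAFEstimate:
    observer_id: str
    paf: float
    cog: float
    f_paf: float
    n_channels_paf: int = 0
    n_channels_cog: int = 0
    n_trials_fpaf: int = 0
    electrode_set: str = "all_19"
    channel_paf: dict[str, float] = field(default_factory=dict)
    channel_cog: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pre-processing and PSD


def preprocess(recording: Recording, settings: SpectralSettings | None = None) -> Recording:
    """Downsample to 256 Hz, zero-phase band-pass 1-40 Hz, trim to 60 s."""
    s = settings or SpectralSettings()
    x = recording.epochs
    fs = recording.fs
    if fs < s.fs_target:
        raise ValueError(f"recording sampled at {fs} Hz; need >= {s.fs_target}")
    if fs > s.fs_target:
        ratio = fs / s.fs_target
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("downsampling requires an integer rate ratio")
        x = signal.resample_poly(x, 1, int(round(ratio)), axis=-1)
        fs = s.fs_target
    n_keep = int(round(s.epoch_seconds * fs))
    if x.shape[-1] < n_keep:
        raise ValueError(
            f"epochs are {x.shape[-1] / fs:.1f} s; need >= {s.epoch_seconds} s"
        )
    sos = signal.butter(4, s.band_hz, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    x = x[..., :n_keep]
    return Recording(
        observer_id=recording.observer_id,
        epochs=x,
        fs=fs,
        channel_labels=recording.channel_labels,
    )


def welch_psd(
    epoch: np.ndarray,
    fs: float = 256.0,
    settings: SpectralSettings | None = None,
    channel_labels: tuple[str, ...] = (),
) -> PSDEstimate:
    """Welch PSD of one epoch, (n_channels, n_samples) -> linear uV^2/Hz."""
    s = settings or SpectralSettings()
    epoch = np.atleast_2d(np.asarray(epoch, float))
    nperseg = int(round(s.welch_window_s * fs))
    noverlap = int(round(nperseg * s.welch_overlap))
    freqs, pxx = signal.welch(
        epoch, fs=fs, window="hamming", nperseg=nperseg, noverlap=noverlap, axis=-1
    )
    if not channel_labels:
        channel_labels = tuple(f"CH{i}" for i in range(epoch.shape[0]))
    return PSDEstimate(
        freqs=freqs,
        power=pxx,
        resolution=float(freqs[1] - freqs[0]),
        channel_labels=tuple(channel_labels),
    )


# ---------------------------------------------------------------------------
# Smoothed-spectrum measures (PAF, COG)


def _alpha_window(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)


def smooth_alpha(
    freqs: np.ndarray, psd_channel: np.ndarray, settings: SpectralSettings | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky-Golay smoothing of the log PSD over the alpha window.

    Returns (window frequencies, smoothed log10 power).  The 11-bin,
    order-5 filter leaves any polynomial of degree <= 5 unchanged.
    """
    s = settings or SpectralSettings()
    mask = _alpha_window(np.asarray(freqs), s.alpha_band)
    fwin = np.asarray(freqs)[mask]
    if fwin.size < s.smooth_frame:
        raise ValueError(
            f"alpha window has {fwin.size} bins; need >= {s.smooth_frame}"
        )
    logp = np.log10(np.asarray(psd_channel, float)[mask])
    smoothed = signal.savgol_filter(logp, s.smooth_frame, s.smooth_order)
    return fwin, smoothed


def estimate_paf(
    freqs: np.ndarray, psd_channel: np.ndarray, settings: SpectralSettings | None = None
) -> float:
    """Peak alpha frequency of one channel, or NaN when no clean peak exists.

    The maximum of the smoothed alpha window counts as a peak only if it
    is unique and interior (an edge maximum means the spectrum is
    monotone across the band; a tie is ambiguous).
    """
    fwin, smoothed = smooth_alpha(freqs, psd_channel, settings)
    i = int(np.argmax(smoothed))
    if i == 0 or i == len(smoothed) - 1:
        return np.nan
    if np.any(np.delete(smoothed, i) == smoothed[i]):
        return np.nan
    return float(fwin[i])


def estimate_cog(
    freqs: np.ndarray, psd_channel: np.ndarray, settings: SpectralSettings | None = None
) -> float:
    """Alpha-band centre of gravity (power-weighted mean frequency)."""
    fwin, smoothed = smooth_alpha(freqs, psd_channel, settings)
    p = 10.0**smoothed
    total = p.sum()
    if total <= 0:
        return np.nan
    return float((fwin * p).sum() / total)


def aggregate_iaf(channel_estimates, min_channels: int) -> float:
    """Mean over non-missing channel estimates, requiring enough channels."""
    v = np.asarray(list(channel_estimates), dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < min_channels:
        return np.nan
    return float(v[ok].mean())


# ---------------------------------------------------------------------------
# Spectral parameterization (aperiodic + single alpha peak)


def _aperiodic(f: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    return offset - exponent * np.log10(f)


def _gauss(f: np.ndarray, height: float, cf: float, sd: float) -> np.ndarray:
    return height * np.exp(-((f - cf) ** 2) / (2 * sd**2))


def _full_model(f, offset, exponent, height, cf, sd):
    return _aperiodic(f, offset, exponent) + _gauss(f, height, cf, sd)


def fit_spectral_model(
    freqs: np.ndarray,
    psd_avg: np.ndarray,
    settings: SpectralSettings | None = None,
) -> SpectrumModel:
    """Decompose a channel-averaged spectrum into 1/f background + alpha peak.

    Procedure on log10 power over the fit range (2-20 Hz): (1) robust
    line fit in log10(f) — an initial least-squares line, then a refit
    with the bins above the 97.5th percentile of positive residuals
    (peak bins) dropped; (2) subtract to flatten; (3) one Gaussian fit
    to the largest flattened peak whose centre lies in the alpha band;
    (4) joint refinement of line + Gaussian; R^2 of the full model
    against the log spectrum gates acceptance (< 0.6 discards the
    trial's peak).
    """
    s = settings or SpectralSettings()
    freqs = np.asarray(freqs, float)
    mask = (freqs >= s.fit_range[0] - 1e-9) & (freqs <= s.fit_range[1] + 1e-9)
    f = freqs[mask]
    y = np.log10(np.asarray(psd_avg, float)[mask])
    lf = np.log10(f)

    def _no_peak(off, exp, r2, msg):
        return SpectrumModel(off, exp, np.nan, np.nan, np.nan, r2, False, msg)

    # (1) robust aperiodic line
    slope, intercept = np.polyfit(lf, y, 1)
    off, exp = float(intercept), float(-slope)
    res = y - _aperiodic(f, off, exp)
    pos = res[res > 0]
    if pos.size:
        keep = res <= np.percentile(pos, 97.5)
        slope, intercept = np.polyfit(lf[keep], y[keep], 1)
        off, exp = float(intercept), float(-slope)

    # (2)-(3) flatten and fit one Gaussian in the alpha band
    flat = y - _aperiodic(f, off, exp)
    alpha = _alpha_window(f, s.alpha_band)
    i_peak = np.argmax(np.where(alpha, flat, -np.inf))
    height0 = float(flat[i_peak])
    cf0 = float(f[i_peak])
    noise_sd = float(np.std(flat))
    r2_ap = 1.0 - np.sum((y - _aperiodic(f, off, exp)) ** 2) / np.sum(
        (y - y.mean()) ** 2
    )
    if height0 < s.peak_threshold_sd * noise_sd:
        return _no_peak(off, exp, float(r2_ap), "no alpha-band candidate peak")

    sd_lo, sd_hi = s.peak_width_hz[0] / 2.0, s.peak_width_hz[1] / 2.0
    try:
        g_opt, _ = optimize.curve_fit(
            _gauss, f, flat,
            p0=[height0, cf0, max(sd_lo * 2, 1.0)],
            bounds=([0.0, s.alpha_band[0], sd_lo], [np.inf, s.alpha_band[1], sd_hi]),
            maxfev=5000,
        )
        # (4) joint refinement
        p_opt, _ = optimize.curve_fit(
            _full_model, f, y,
            p0=[off, exp, *g_opt],
            bounds=(
                [-np.inf, -np.inf, 0.0, s.alpha_band[0], sd_lo],
                [np.inf, np.inf, np.inf, s.alpha_band[1], sd_hi],
            ),
            maxfev=10000,
        )
    except RuntimeError as err:  # optimizer non-convergence
        return _no_peak(off, exp, float(r2_ap), f"fit failed: {err}")
    yhat = _full_model(f, *p_opt)
    r2 = float(1.0 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2))
    off, exp, height, cf, sd = (float(v) for v in p_opt)
    if r2 < s.r2_min:
        return _no_peak(off, exp, r2, f"bad model fit (R^2 = {r2:.3f})")
    return SpectrumModel(off, exp, cf, height, sd, r2, True)


def f_paf_from_trials(trial_models) -> tuple[float, int]:
    """Mean accepted peak CF over trials; (NaN, 0) when no trial has a peak."""
    cfs = [m.peak_cf for m in trial_models if m.has_peak]
    if not cfs:
        return np.nan, 0
    return float(np.mean(cfs)), len(cfs)


# ---------------------------------------------------------------------------
# End-to-end per-observer estimation


def estimate_iaf(
    recording: Recording, settings: SpectralSettings | None = None
) -> IAFEstimate:
    """All three IAF measures for one observer's recording."""
    s = settings or SpectralSettings()
    rec = preprocess(recording, s)
    labels = list(rec.channel_labels)
    if s.electrode_set == "occipital_3":
        idx = [i for i, lab in enumerate(labels) if lab in OCCIPITAL_3]
        if not idx:
            raise ValueError("occipital_3 electrode set requires O1/Oz/O2 channels")
    elif s.electrode_set == "all_19":
        idx = list(range(len(labels)))
    else:
        raise ValueError(f"unknown electrode_set {s.electrode_set!r}")
    labels = [labels[i] for i in idx]
    epochs = rec.epochs[:, idx, :]

    # per-channel PSD averaged across trials for PAF/COG
    psds = [welch_psd(ep, rec.fs, s, tuple(labels)) for ep in epochs]
    freqs = psds[0].freqs
    mean_power = np.mean([p.power for p in psds], axis=0)

    ch_paf = {lab: estimate_paf(freqs, mean_power[c], s) for c, lab in enumerate(labels)}
    ch_cog = {lab: estimate_cog(freqs, mean_power[c], s) for c, lab in enumerate(labels)}
    min_ch = s.min_channels_for(len(labels))
    paf = aggregate_iaf(ch_paf.values(), min_ch)
    cog = aggregate_iaf(ch_cog.values(), min_ch)

    # per-trial channel-averaged spectrum for the parameterized peak
    models = [fit_spectral_model(freqs, p.power.mean(axis=0), s) for p in psds]
    f_paf, n_acc = f_paf_from_trials(models)

    return IAFEstimate(
        observer_id=recording.observer_id,
        paf=paf,
        cog=cog,
        f_paf=f_paf,
        n_channels_paf=int(np.isfinite(list(ch_paf.values())).sum()),
        n_channels_cog=int(np.isfinite(list(ch_cog.values())).sum()),
        n_trials_fpaf=n_acc,
        electrode_set=s.electrode_set,
        channel_paf=ch_paf,
        channel_cog=ch_cog,
    )
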
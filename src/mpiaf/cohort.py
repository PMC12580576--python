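"""Synthetic observer cohorts with known ground truth.

A cohort is a set of simulated observers, each carrying the latent,
person-level quantities that the downstream pipeline tries to estimate:

* a true illusion magnitude for each of the eight motion-position
  illusions (arc degrees of visual angle for the rotational tasks,
  plain dva for the translational ones, % luminance contrast for the
  luminance flash-lag);
* psychophysical response parameters (slope/sigma, lapse rate, bias)
  that drive the simulated judgements feeding the adaptive staircases;
* resting-state EEG spectral parameters: a 1/f aperiodic component
  (offset, exponent in log10 coordinates) plus one Gaussian alpha peak
  whose centre frequency is the observer's true individual alpha
  frequency (IAF).

The magnitudes, alpha centre frequency and age are drawn jointly from a
multivariate Gaussian so that a correlation structure can be planted and
its recovery by the estimation pipeline tested.  Recordings are
synthesized by spectral shaping: frequency-domain white noise scaled by
the square root of the model's linear power target, then inverse-FFT'd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import substream

__all__ = [
    "ILLUSIONS",
    "CORRELATED_TRAITS",
    "ObserverProfile",
    "CohortSpec",
    "RecordingSpec",
    "Recording",
    "make_cohort",
    "model_log_psd",
    "synthesize_eeg",
    "cohort_to_frame",
    "cohort_from_frame",
]

#: Canonical illusion order used everywhere in the package.
ILLUSIONS = ("fle", "lum_fle", "fe", "fd", "fg", "mips", "tg", "fj")

#: Traits drawn from the joint (correlated) Gaussian.
CORRELATED_TRAITS = ILLUSIONS + ("alpha_cf", "age")

#: 19 parietal-occipital channels of a 10-20 montage, posterior row first.
PARIETO_OCCIPITAL_19 = (
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)

# Marginal defaults: illusion magnitudes follow observed group means/SDs
# of the eight tasks; alpha_cf and age follow the study population.
DEFAULT_TRAIT_MEANS = {
    "fle": 1.68, "lum_fle": 12.0, "fe": 1.58, "fd": 0.07, "fg": 4.42,
    "mips": 0.84, "tg": 0.34, "fj": 0.59, "alpha_cf": 10.34, "age": 25.6,
}
DEFAULT_TRAIT_SDS = {
    "fle": 2.14, "lum_fle": 12.0, "fe": 1.53, "fd": 0.07, "fg": 1.51,
    "mips": 0.28, "tg": 0.29, "fj": 0.49, "alpha_cf": 0.83, "age": 6.89,
}

# Psychometric slope defaults (same units as the trait), roughly half the
# between-subject magnitude SD: enough internal noise to need a staircase,
# small enough for reliable 40-trial PSEs.
DEFAULT_SIGMA = {
    "fle": 1.0, "lum_fle": 8.0, "fe": 0.9, "fd": 0.25, "fg": 1.2,
    "mips": 0.4, "tg": 0.3, "fj": 0.4,
}


@dataclass
class ObserverProfile:
    """Ground truth for one simulated participant."""

    observer_id: str
    age: float
    true_magnitude: dict[str, float]
    response_sigma: dict[str, float]
    response_bias: dict[str, float]
    lapse_rate: float
    alpha_cf: float
    alpha_power: float
    alpha_bw: float
    aperiodic_offset: float
    aperiodic_exponent: float
    attention_fail_rate: float = 0.0
    invalid_response_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 7.0 <= self.alpha_cf <= 13.0:
            raise ValueError(f"alpha_cf must lie in [7, 13] Hz, got {self.alpha_cf}")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError(f"lapse_rate must lie in [0, 0.1], got {self.lapse_rate}")
        if any(s <= 0 for s in self.response_sigma.values()):
            raise ValueError("response_sigma values must be positive")
        if self.aperiodic_exponent <= 0:
            raise ValueError("aperiodic_exponent must be positive")
        if self.alpha_power < 0:
            raise ValueError("alpha_power must be non-negative")


@dataclass
class CohortSpec:
    """Recipe for a cohort: marginals plus a planted correlation matrix.

    ``trait_correlation`` is ordered as :data:`CORRELATED_TRAITS`
    (8 illusions, alpha_cf, age).  ``None`` means independence.
    """

    n_observers: int
    trait_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))
    trait_correlation: np.ndarray | None = None
    seed: int = 0
    lapse_max: float = 0.05
    attention_fail_rate: float = 0.0
    invalid_response_rate: float = 0.0

    def correlation_matrix(self) -> np.ndarray:
        k = len(CORRELATED_TRAITS)
        if self.trait_correlation is None:
            return np.eye(k)
        c = np.asarray(self.trait_correlation, dtype=float)
        if c.shape != (k, k):
            raise ValueError(f"trait_correlation must be {k}x{k}, got {c.shape}")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("trait_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise ValueError("trait_correlation must have unit diagonal")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-8:
            raise ValueError(
                f"trait_correlation is not positive semidefinite: "
                f"smallest eigenvalue {w.min():.3e}"
            )
        return c

    def validate(self) -> None:
        if self.n_observers <= 0:
            raise ValueError(f"n_observers must be positive, got {self.n_observers}")
        for t in CORRELATED_TRAITS:
            if t not in self.trait_means or t not in self.trait_sds:
                raise ValueError(f"trait_means/trait_sds missing entry for {t!r}")
            if self.trait_sds[t] < 0:
                raise ValueError(f"trait_sds[{t!r}] must be >= 0")
        self.correlation_matrix()


def planted_correlation(pairs: dict[tuple[str, str], float]) -> np.ndarray:
    """Identity correlation matrix with the given off-diagonal entries set.

    ``pairs`` maps (trait_a, trait_b) to the desired correlation, e.g.
    ``{("alpha_cf", "fle"): 0.5}``.
    """
    k = len(CORRELATED_TRAITS)
    c = np.eye(k)
    idx = {t: i for i, t in enumerate(CORRELATED_TRAITS)}
    for (a, b), r in pairs.items():
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = float(r)
    return c


@dataclass
class RecordingSpec:
    """Shape of one synthetic resting-state recording (eyes closed)."""

    fs: float = 256.0
    n_channels: int = 19
    n_epochs: int = 5
    epoch_seconds: float = 60.0
    channel_labels: tuple[str, ...] | None = None
    cf_jitter_sd: float = 0.05  # Hz, channel-level jitter of the alpha CF

    def __post_init__(self) -> None:
        if self.fs <= 80.0:
            raise ValueError(f"fs must exceed twice the 40 Hz band edge, got {self.fs}")
        n = self.epoch_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_seconds * fs must be an integer sample count")
        if self.channel_labels is None:
            labels = PARIETO_OCCIPITAL_19[: self.n_channels]
            if len(labels) < self.n_channels:
                labels = labels + tuple(
                    f"CH{i}" for i in range(len(labels), self.n_channels)
                )
            self.channel_labels = labels
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_seconds * self.fs))


@dataclass
class Recording:
    """Multichannel epoched recording in microvolts."""

    observer_id: str
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("recording contains non-finite samples")
        if self.epochs.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels length must match epochs axis 1")


def make_cohort(spec: CohortSpec) -> list[ObserverProfile]:
    """Draw a cohort of observers with the requested trait structure.

    Correlated traits come from a multivariate Gaussian with the spec's
    means, SDs and correlation matrix, then are clipped to the type
    invariants (clipping slightly perturbs extreme planted correlations;
    with the default marginals the effect is negligible).  All remaining
    parameters are drawn independently per observer.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    corr = spec.correlation_matrix()
    rng = substream(spec.seed, "cohort")
    k = len(CORRELATED_TRAITS)
    mu = np.array([spec.trait_means[t] for t in CORRELATED_TRAITS])
    sd = np.array([spec.trait_sds[t] for t in CORRELATED_TRAITS])
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((spec.n_observers, k))
    latent = mu + sd * (z @ chol.T)

    profiles: list[ObserverProfile] = []
    for i in range(spec.n_observers):
        row = dict(zip(CORRELATED_TRAITS, latent[i]))
        mags = {il: float(row[il]) for il in ILLUSIONS}
        sigmas = {
            il: float(DEFAULT_SIGMA[il] * np.exp(rng.normal(0.0, 0.3)))
            for il in ILLUSIONS
        }
        biases = {
            il: float(rng.normal(0.0, 0.1 * DEFAULT_SIGMA[il])) for il in ILLUSIONS
        }
        profiles.append(
            ObserverProfile(
                observer_id=f"obs{i:04d}",
                age=float(np.clip(row["age"], 18.0, 70.0)),
                true_magnitude=mags,
                response_sigma=sigmas,
                response_bias=biases,
                lapse_rate=float(rng.uniform(0.0, min(spec.lapse_max, 0.1))),
                alpha_cf=float(np.clip(row["alpha_cf"], 8.0, 12.5)),
                alpha_power=float(np.clip(rng.normal(1.5, 0.25), 0.5, None)),
                alpha_bw=float(np.clip(rng.normal(0.8, 0.15), 0.4, 1.5)),
                aperiodic_offset=float(rng.normal(1.0, 0.3)),
                aperiodic_exponent=float(np.clip(rng.normal(1.0, 0.2), 0.3, None)),
                attention_fail_rate=spec.attention_fail_rate,
                invalid_response_rate=spec.invalid_response_rate,
            )
        )
    return profiles


def model_log_psd(profile: ObserverProfile, freqs: np.ndarray) -> np.ndarray:
    """Model log10 PSD: 1/f aperiodic component plus one Gaussian alpha peak.

    ``log10 P(f) = offset - exponent*log10(f)
                   + alpha_power * exp(-(f - alpha_cf)^2 / (2 alpha_bw^2))``
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    ap = profile.aperiodic_offset - profile.aperiodic_exponent * np.log10(f)
    if profile.alpha_power == 0:
        return ap
    peak = profile.alpha_power * np.exp(
        -((f - profile.alpha_cf) ** 2) / (2 * profile.alpha_bw**2)
    )
    return ap + peak


def synthesize_eeg(
    profile: ObserverProfile,
    rec_spec: RecordingSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> Recording:
    """Synthesize an eyes-closed resting-state recording for one observer.

    Each epoch/channel is generated in the frequency domain: complex
    Gaussian coefficients (white noise) scaled so that the expected
    one-sided PSD equals the linear power target ``10**model_log_psd``,
    then inverse-FFT'd to microvolt samples.  Channels share the
    observer's spectral parameters up to a small fixed per-channel jitter
    of the alpha centre frequency.  Deterministic given the seed.
    """
    rec_spec = rec_spec or RecordingSpec()
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "eeg")
    n = rec_spec.n_samples
    fs = rec_spec.fs
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    nch = rec_spec.n_channels

    cf_jitter = rng.normal(0.0, rec_spec.cf_jitter_sd, size=nch)
    # per-channel linear power targets on the positive-frequency grid
    targets = np.empty((nch, freqs.size))
    for c in range(nch):
        ch_profile = replace(profile, alpha_cf=float(np.clip(profile.alpha_cf + cf_jitter[c], 7.0, 13.0)))
        targets[c, 1:] = 10.0 ** model_log_psd(ch_profile, freqs[1:])
    targets[:, 0] = 0.0  # no DC component

    amp = np.sqrt(targets * fs * n / 4.0)
    epochs = np.empty((rec_spec.n_epochs, nch, n))
    for e in range(rec_spec.n_epochs):
        coef = amp * (
            rng.standard_normal((nch, freqs.size))
            + 1j * rng.standard_normal((nch, freqs.size))
        )
        if n % 2 == 0:  # Nyquist bin of an even-length real FFT is real
            coef[:, -1] = coef[:, -1].real * np.sqrt(2.0)
        epochs[e] = np.fft.irfft(coef, n=n, axis=-1)
    return Recording(
        observer_id=profile.observer_id,
        epochs=epochs,
        fs=fs,
        channel_labels=tuple(rec_spec.channel_labels),
    )


# ---------------------------------------------------------------------------
# Tabular round trip (cohort CSV is the on-disk interface between stages)

def cohort_to_frame(profiles: list[ObserverProfile]) -> pd.DataFrame:
    """One row per observer, one column per trait."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"observer_id": p.observer_id, "age": p.age}
        for il in ILLUSIONS:
            row[f"magnitude_{il}"] = p.true_magnitude[il]
            row[f"sigma_{il}"] = p.response_sigma[il]
            row[f"bias_{il}"] = p.response_bias[il]
        row.update(
            lapse_rate=p.lapse_rate,
            alpha_cf=p.alpha_cf,
            alpha_power=p.alpha_power,
            alpha_bw=p.alpha_bw,
            aperiodic_offset=p.aperiodic_offset,
            aperiodic_exponent=p.aperiodic_exponent,
            attention_fail_rate=p.attention_fail_rate,
            invalid_response_rate=p.invalid_response_rate,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_from_frame(frame: pd.DataFrame) -> list[ObserverProfile]:
    """Inverse of :func:`cohort_to_frame`."""
    profiles = []
    for _, r in frame.iterrows():
        profiles.append(
            ObserverProfile(
                observer_id=str(r["observer_id"]),
                age=float(r["age"]),
                true_magnitude={il: float(r[f"magnitude_{il}"]) for il in ILLUSIONS},
                response_sigma={il: float(r[f"sigma_{il}"]) for il in ILLUSIONS},
                response_bias={il: float(r[f"bias_{il}"]) for il in ILLUSIONS},
                lapse_rate=float(r["lapse_rate"]),
                alpha_cf=float(r["alpha_cf"]),
                alpha_power=float(r["alpha_power"]),
                alpha_bw=float(r["alpha_bw"]),
                aperiodic_offset=float(r["aperiodic_offset"]),
                aperiodic_exponent=float(r["aperiodic_exponent"]),
                attention_fail_rate=float(r.get("attention_fail_rate", 0.0)),
                invalid_response_rate=float(r.get("invalid_response_rate", 0.0)),
            )
        )
    return profiles


def profile_sidecar(profile: ObserverProfile) -> str:
    """JSON ground-truth sidecar written next to each recording."""
    d = {
        "observer_id": profile.observer_id,
        "alpha_cf": profile.alpha_cf,
        "alpha_power": profile.alpha_power,
        "alpha_bw": profile.alpha_bw,
        "aperiodic_offset": profile.aperiodic_offset,
        "aperiodic_exponent": profile.aperiodic_exponent,
    }
    return json.dumps(d, indent=1)
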
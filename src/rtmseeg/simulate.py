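"""Synthetic rTMS-EEG cohorts with ground-truth planted couplings.

The generator emulates the statistical structure the analysis chain assumes
about a 3-arm (Real / active-control / sham) high-frequency rTMS trial:

* subject-level alpha (8-14.5 Hz) amplitude is a stable trait — the same
  subject draw drives the resting and the treatment session, so alpha power
  at rest and in the inter-train intervals correlates strongly across
  subjects;
* stimulation trains evoke band-limited low-gamma (30-40 Hz) activity whose
  envelope decays exponentially across the inter-train interval, spatially
  peaked over the right prefrontal cortex; the per-subject responsiveness
  ``gamma_resp`` is independent of resting gamma, so the rest-vs-treatment
  gamma correlation is abolished exactly where the response dominates;
* clinical improvement in the Real group is linear in the log gamma/alpha
  ratio plus an inter-hemispheric alpha-asymmetry term,
  ``improvement = beta0 + beta1 log(gamma_resp/alpha_amp) + beta2 asym + e``;
  control groups get ``beta1 = beta2 = 0`` with noise matched to the Real
  group's total variance;
* single TMS pulses evoke a stereotyped TEP (N45, P60, N75, N100, P180 as
  alternating Gaussian deflections peaked near F4) with an optional planted
  post-treatment N75 reduction in the Real group.

Protocol constants default to the emulated stimulation protocol:
40 trains of 2 s at 18 Hz (36 pulses each, 1440 per session) separated by
20 s inter-train intervals; 50 single TEP pulses 5 s apart. "20 s apart" is
read as 20 s from train end to the next train onset — the only reading under
which the 1 s + 7 x 2 s + 5 s segmentation of the ITI is exact.

Every random quantity derives from ``CohortConfig.seed`` through per-subject
``SeedSequence`` spawns, so the same configuration reproduces the cohort
bit for bit while recordings can be synthesised lazily (a full cohort of
continuous 64-channel sessions would not fit in memory).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage, default_montage, great_circle_distance
from .preprocess import Recording

__all__ = [
    "SubjectTraits", "CohortConfig", "GroundTruth", "Cohort",
    "generate_cohort", "synthesize_treatment_eeg", "synthesize_rest_eeg",
    "synthesize_tep", "planted_correlation", "solve_beta1_for_target_r",
    "TEP_LATENCIES_MS",
]

GROUPS = ("Real", "AC", "Sham")

#: canonical TEP component latencies (ms) and template parameters
TEP_LATENCIES_MS = {"N45": 45.0, "P60": 60.0, "N75": 75.0,
                    "N100": 100.0, "P180": 180.0}
_TEP_POLARITY = {"N45": -1.0, "P60": 1.0, "N75": -1.0, "N100": -1.0, "P180": 1.0}
# component amplitudes sized so that single-subject TOI estimates over 50
# pulses resolve a treatment-scale change at trial-size groups (the regime
# in which prefrontal TEP treatment effects are reported)
_TEP_AMP_UV = {"N45": 3.5, "P60": 3.0, "N75": 5.0, "N100": 4.5, "P180": 3.5}
_TEP_WIDTH_MS = {"N45": 7.0, "P60": 6.0, "N75": 7.0, "N100": 12.0, "P180": 30.0}

# raw CAARS total modelled as an affine image of the t-score; slope 1 keeps
# raw change equal to t change, offset puts typical baselines near 46 points
_RAW_OFFSET = 30.0


@dataclass(frozen=True)
class SubjectTraits:
    """Latent per-subject quantities the generator plants."""

    subject: str
    group: str
    alpha_amp: float        # alpha source amplitude at the scalp (uV)
    gamma_resp: float       # post-train low-gamma responsiveness (uV)
    rest_gamma_amp: float   # resting low-gamma amplitude (uV), independent trait
    gamma_decay_tau: float  # post-train gamma decay constant (s)
    asym: float             # alpha left-right asymmetry (+ = left-dominant)
    alpha_freq: float       # individual alpha frequency (Hz)
    tep_scale: float        # subject-level TEP amplitude multiplier

    def __post_init__(self):
        if self.alpha_amp <= 0 or self.gamma_resp < 0 or self.gamma_decay_tau <= 0:
            raise ValueError("invalid traits: require alpha_amp > 0, "
                             "gamma_resp >= 0, gamma_decay_tau > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Group sizes, the stimulation protocol and the clinical baselines default
    to the trial being emulated (n = 15/14/14; 40 x 2 s x 18 Hz trains 20 s
    apart; 50 TEP pulses 5 s apart; baseline CAARS t-scores near 73-79).
    The improvement-model coefficients default to a planted FC4
    marker-improvement correlation of ~0.85 with a ~12% explained-variance
    gain from the asymmetry term, and a Real-group mean improvement of
    ~8.3 t-points with SD ~7.
    """

    n_per_group: tuple[int, int, int] = (15, 14, 14)   # Real, AC, Sham
    seed: int = 0
    sfreq: float = 500.0

    # protocol
    n_trains: int = 40
    train_dur: float = 2.0
    iti_dur: float = 20.0
    train_freq: float = 18.0
    n_tep_pulses: int = 50
    tep_ipi: float = 5.0
    rest_dur: float = 120.0

    # improvement model (t-score units)
    beta0: float = 2.0
    beta1: float = 9.3
    beta2: float = 8.2
    noise_sd: float = 2.75

    # trait distributions
    alpha_amp_median: float = 8.0
    alpha_amp_log_sd: float = 0.4
    gamma_resp_median: float = 15.7
    gamma_resp_log_sd: float = 0.5
    rest_gamma_median: float = 2.0
    rest_gamma_log_sd: float = 0.4
    gamma_tau_median: float = 3.0
    gamma_tau_log_sd: float = 0.2
    asym_sd: float = 0.3
    tep_scale_log_sd: float = 0.3

    # scalp model
    topography_width: float = 0.9       # radians, right-prefrontal gamma source
    gamma_center_channel: str = "FC4"
    tep_center_channel: str = "F4"
    background_sd: float = 3.0          # 1/f background (uV)
    alpha_session_jitter: float = 0.05  # log-SD of per-session alpha wobble

    # group response scaling of the train-evoked gamma source: the focal
    # off-target AC stimulation evokes a response comparable to the resting
    # gamma floor, so its rest-vs-treatment correlation is attenuated but
    # not abolished; sham evokes none and keeps the resting pattern intact
    group_gamma_scale: tuple[float, float, float] = (1.0, 0.25, 0.0)

    # clinical baselines
    pre_mean_t: float = 76.0
    pre_sd_t: float = 8.0

    # planted TEP treatment effect: post-treatment N75 scale in the Real group
    tep_n75_post_scale_real: float = 0.6

    # window (s after train offset) of the first ITI segment, used when the
    # planted marker correlation is evaluated in closed form
    marker_seg_window: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self):
        if min(self.n_per_group) < 2:
            raise ValueError("need n_per_group >= 2 in every group")
        if self.sfreq < 200:
            raise ValueError("sfreq must be >= 200 Hz to resolve the 30-40 Hz band")

    @property
    def pulses_per_train(self) -> int:
        return int(round(self.train_dur * self.train_freq))

    @property
    def pulses_per_session(self) -> int:
        return self.n_trains * self.pulses_per_train

    @property
    def sigma_log_ratio(self) -> float:
        """SD of log(gamma_resp/alpha_amp) across subjects."""
        return float(np.hypot(self.gamma_resp_log_sd, self.alpha_amp_log_sd))

    @property
    def mean_log_ratio(self) -> float:
        return float(np.log(self.gamma_resp_median / self.alpha_amp_median))

    def with_target_r(self, target_r: float) -> "CohortConfig":
        """Config whose planted FC4 marker-improvement correlation is ``target_r``.

        Drops the asymmetry term (beta2 = 0) and solves beta1 in closed form
        against the full variance of the generated FC4 log marker (trait
        log-ratio, asymmetry leakage, and the per-subject decay-constant
        contribution to segment-1 gamma power).
        """
        var_xg, cov_xg = self._marker_gamma_stats()
        var_x = (var_xg + self.alpha_amp_log_sd ** 2
                 + self.alpha_session_jitter ** 2 + self.asym_sd ** 2 / 4.0)
        cov_xm = cov_xg + self.alpha_amp_log_sd ** 2
        beta1 = solve_beta1_for_target_r(
            target_r, self.sigma_log_ratio, self.noise_sd, var_x, cov_xm)
        return dataclasses.replace(self, beta1=beta1, beta2=0.0)

    def _marker_gamma_stats(self) -> tuple[float, float]:
        """Moments of the gamma half of the generated FC4 log marker.

        x_g = (1/2) log of the window-averaged power of the segment-1 gamma
        envelope ``gamma_resp exp(-t/tau) + rest_gamma``, integrated over the
        lognormal (gamma_resp, rest_gamma, tau) trait distribution by
        Gauss-Hermite quadrature. Returns (var(x_g), cov(x_g, log gamma_resp)).
        """
        t0, t1 = self.marker_seg_window
        tt = np.linspace(t0, t1, 61)
        z, w = np.polynomial.hermite_e.hermegauss(17)
        w = w / w.sum()
        zg, zr, zt = np.meshgrid(z, z, z, indexing="ij")
        wg = (w[:, None, None] * w[None, :, None] * w[None, None, :])
        g = self.gamma_resp_median * np.exp(self.gamma_resp_log_sd * zg)
        rest = self.rest_gamma_median * np.exp(self.rest_gamma_log_sd * zr)
        tau = self.gamma_tau_median * np.exp(self.gamma_tau_log_sd * zt)
        env2 = (g[..., None] * np.exp(-tt / tau[..., None]) + rest[..., None]) ** 2
        x_g = 0.5 * np.log(env2.mean(axis=-1))
        log_g = np.log(g)
        mu = np.sum(wg * x_g)
        var = np.sum(wg * (x_g - mu) ** 2)
        cov = np.sum(wg * (x_g - mu) * (log_g - np.sum(wg * log_g)))
        return float(var), float(cov)


def solve_beta1_for_target_r(target_r: float, sigma_m: float, noise_sd: float,
                             var_x: float, cov_xm: float) -> float:
    """beta1 giving population corr ``target_r`` between the generated
    right-channel log marker (variance ``var_x``, covariance ``cov_xm``
    with the trait log-ratio) and improvement, with beta2 = 0."""
    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")
    denom = cov_xm ** 2 - target_r ** 2 * var_x * sigma_m ** 2
    if denom <= 0:
        raise ValueError("target correlation unreachable: marker noise too large")
    return float(np.sqrt(target_r ** 2 * var_x * noise_sd ** 2 / denom))


def planted_correlation(config: CohortConfig) -> dict[str, float]:
    """Population correlations implied by the generative model.

    ``r_fc4``: correlation between the right-prefrontal log marker as
    generated (alpha trait with session jitter and asymmetry leakage; gamma
    response with its post-train decay and resting floor) and improvement —
    the quantity the pipeline estimates at the gamma source channel.
    ``r_log_ratio``: correlation of improvement with the pure trait
    log(gamma_resp/alpha_amp). ``r2_dual``: explained variance of the full
    planted linear model (the ceiling for the two-channel model).
    """
    sm2 = config.sigma_log_ratio ** 2
    sa2 = config.asym_sd ** 2
    salpha2 = config.alpha_amp_log_sd ** 2
    var_imp = config.beta1 ** 2 * sm2 + config.beta2 ** 2 * sa2 + config.noise_sd ** 2
    var_xg, cov_xg = config._marker_gamma_stats()
    var_x = var_xg + salpha2 + config.alpha_session_jitter ** 2 + sa2 / 4.0
    cov_imp_x = config.beta1 * (cov_xg + salpha2) + config.beta2 * sa2 / 2.0
    return {
        "r_fc4": float(cov_imp_x / np.sqrt(var_x * var_imp)),
        "r_log_ratio": float(config.beta1 * np.sqrt(sm2 / var_imp)),
        "r2_dual": float((config.beta1 ** 2 * sm2 + config.beta2 ** 2 * sa2) / var_imp),
    }


@dataclass
class GroundTruth:
    """Everything needed to self-validate recovery on a generated cohort."""

    traits: list[SubjectTraits]
    true_improvement: pd.Series           # indexed by subject
    planted_r_fc4: float
    planted_r_log_ratio: float
    planted_r2_dual: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(t) for t in self.traits])
        df["true_improvement"] = self.true_improvement.to_numpy()
        return df


# --------------------------------------------------------------------------
# signal primitives
# --------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                sfreq: float, sd: float) -> np.ndarray:
    """1/f-amplitude background noise, per-channel independent, std ``sd``."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samp, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return sd * x


def _band_noise(rng: np.random.Generator, n_ch: int, n_samp: int, sfreq: float,
                lo: float, hi: float) -> np.ndarray:
    """Per-channel unit-variance noise with spectral support in [lo, hi] Hz.

    Channels are independent realisations: like genuine oscillatory EEG,
    the band activity is not phase-locked across the scalp, so spatial
    re-referencing attenuates the topography only marginally.
    """
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    spec[:, (freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _gaussian_topography(montage: Montage, center: str, width: float) -> np.ndarray:
    d = great_circle_distance(montage.positions, montage.position(center))
    return np.exp(-d ** 2 / (2.0 * width ** 2))


def _alpha_weights(montage: Montage, asym: float) -> np.ndarray:
    """Broad alpha topography with occipital emphasis, modulated by the
    planted inter-hemispheric asymmetry (+asym = left-dominant)."""
    d_oz = great_circle_distance(montage.positions, montage.position("Oz"))
    base = 0.7 + 0.5 * np.exp(-d_oz ** 2 / (2.0 * 1.0 ** 2))
    hemi = np.sign(-montage.positions[:, 0])      # +1 left, -1 right, 0 midline
    return base * np.exp(hemi * asym / 2.0)


# --------------------------------------------------------------------------
# session synthesis
# --------------------------------------------------------------------------

def _session_alpha_amp(traits: SubjectTraits, config: CohortConfig,
                       rng: np.random.Generator) -> float:
    return traits.alpha_amp * np.exp(rng.normal(0.0, config.alpha_session_jitter))


def _base_signal(traits: SubjectTraits, config: CohortConfig,
                 montage: Montage, rng: np.random.Generator,
                 n_samp: int) -> np.ndarray:
    """Background + stable alpha common to every session type."""
    data = _pink_noise(rng, montage.n_channels, n_samp, config.sfreq,
                       config.background_sd)
    # alpha as narrowband noise (~3 Hz wide around the individual alpha
    # frequency), channel realisations independent: like genuine alpha it is
    # neither a pure tone nor phase-locked across the scalp, so band-power
    # estimates are unbiased and average referencing barely attenuates it
    alpha = _band_noise(rng, montage.n_channels, n_samp, config.sfreq,
                        traits.alpha_freq - 1.5, traits.alpha_freq + 1.5)
    amp = _session_alpha_amp(traits, config, rng) / np.sqrt(2.0)
    data += amp * _alpha_weights(montage, traits.asym)[:, None] * alpha
    return data


def synthesize_rest_eeg(traits: SubjectTraits, config: CohortConfig,
                        montage: Montage | None = None,
                        rng: np.random.Generator | None = None) -> Recording:
    """Eyes-closed resting recording: background, trait alpha, resting gamma."""
    montage = montage or default_montage()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_samp = int(round(config.rest_dur * config.sfreq))
    data = _base_signal(traits, config, montage, rng, n_samp)
    g = _band_noise(rng, montage.n_channels, n_samp, config.sfreq, 30.0, 40.0)
    w = _gaussian_topography(montage, config.gamma_center_channel,
                             config.topography_width)
    data += traits.rest_gamma_amp * w[:, None] * g
    return Recording(data, config.sfreq, montage.channel_names, [],
                     subject=traits.subject, session="rest")


def synthesize_treatment_eeg(traits: SubjectTraits, config: CohortConfig,
                             montage: Montage | None = None,
                             rng: np.random.Generator | None = None,
                             gamma_scale: float = 1.0) -> Recording:
    """Treatment session: trains at 18 Hz, post-train decaying gamma.

    The train-evoked low-gamma envelope after each train offset is
    ``gamma_scale * gamma_resp * exp(-t_since_offset / gamma_decay_tau)``,
    on top of the subject's resting gamma. Samples inside trains are
    saturated and flagged in the artifact mask (stand-in for the TMS
    artifact the segmentation must avoid). Events: ``train_onset``,
    ``train_offset`` and one ``tms_pulse`` per delivered pulse.
    """
    montage = montage or default_montage()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lead = 2.0
    period = config.train_dur + config.iti_dur
    dur = lead + config.n_trains * period
    n_samp = int(round(dur * config.sfreq))
    t = np.arange(n_samp) / config.sfreq

    data = _base_signal(traits, config, montage, rng, n_samp)

    onsets = lead + period * np.arange(config.n_trains)
    offsets = onsets + config.train_dur
    envelope = np.full(n_samp, float(traits.rest_gamma_amp))
    resp = gamma_scale * traits.gamma_resp
    if resp > 0:
        for off in offsets:
            tail = t >= off
            envelope[tail] += resp * np.exp(-(t[tail] - off) / traits.gamma_decay_tau)
    g = _band_noise(rng, montage.n_channels, n_samp, config.sfreq, 30.0, 40.0)
    w = _gaussian_topography(montage, config.gamma_center_channel,
                             config.topography_width)
    data += w[:, None] * (g * envelope[None, :])

    mask = np.zeros(n_samp, bool)
    events: list[tuple[float, float, str]] = []
    for on, off in zip(onsets, offsets):
        sl = slice(int(round(on * config.sfreq)), int(round(off * config.sfreq)))
        mask[sl] = True
        data[:, sl] = 500.0 * np.sign(rng.standard_normal((data.shape[0], 1)))
        events.append((float(on), config.train_dur, "train_onset"))
        events.append((float(off), 0.0, "train_offset"))
        for k in range(config.pulses_per_train):
            events.append((float(on + k / config.train_freq), 0.0, "tms_pulse"))
    return Recording(data, config.sfreq, montage.channel_names, events,
                     artifact_mask=mask, subject=traits.subject,
                     session="treatment")


def synthesize_tep(traits: SubjectTraits, config: CohortConfig,
                   component_scales: dict[str, float] | None = None,
                   montage: Montage | None = None,
                   rng: np.random.Generator | None = None) -> Recording:
    """Single-pulse TEP session: 50 pulses, 5 s apart, stereotyped response.

    Each pulse evokes Gaussian-windowed deflections at 45/60/75/100/180 ms
    with the canonical alternating polarity, scaled per component by
    ``component_scales`` and spatially peaked near F4. A high-amplitude
    artifact burst spans -2..10 ms around every pulse.
    """
    montage = montage or default_montage()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scales = {name: 1.0 for name in TEP_LATENCIES_MS}
    if component_scales:
        scales.update(component_scales)
    lead = 2.0
    dur = lead + config.n_tep_pulses * config.tep_ipi
    n_samp = int(round(dur * config.sfreq))
    data = _base_signal(traits, config, montage, rng, n_samp)

    # one template evaluated on a +-0.4 s stencil, added at every pulse
    stencil = np.arange(int(-0.05 * config.sfreq), int(0.4 * config.sfreq))
    ts = stencil / config.sfreq
    template = np.zeros_like(ts)
    for name, lat in TEP_LATENCIES_MS.items():
        width = _TEP_WIDTH_MS[name] / 1000.0
        template += (_TEP_POLARITY[name] * _TEP_AMP_UV[name] * scales[name]
                     * np.exp(-(ts - lat / 1000.0) ** 2 / (2 * width ** 2)))
    template *= traits.tep_scale
    w = _gaussian_topography(montage, config.tep_center_channel,
                             config.topography_width)

    pulses = lead + config.tep_ipi * np.arange(config.n_tep_pulses)
    events = []
    art_lo, art_hi = -0.002, 0.010
    for p in pulses:
        c = int(round(p * config.sfreq))
        idx = c + stencil
        data[:, idx] += np.outer(w, template)
        a0 = c + int(round(art_lo * config.sfreq))
        a1 = c + int(round(art_hi * config.sfreq)) + 1
        data[:, a0:a1] += 300.0 * rng.standard_normal((data.shape[0], a1 - a0))
        events.append((float(p), 0.0, "tms_pulse"))
    return Recording(data, config.sfreq, montage.channel_names, events,
                     subject=traits.subject, session="tep")


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def _draw_traits(config: CohortConfig, rng: np.random.Generator,
                 subject: str, group: str) -> SubjectTraits:
    return SubjectTraits(
        subject=subject, group=group,
        alpha_amp=float(config.alpha_amp_median
                        * np.exp(rng.normal(0, config.alpha_amp_log_sd))),
        gamma_resp=float(config.gamma_resp_median
                         * np.exp(rng.normal(0, config.gamma_resp_log_sd))),
        rest_gamma_amp=float(config.rest_gamma_median
                             * np.exp(rng.normal(0, config.rest_gamma_log_sd))),
        gamma_decay_tau=float(config.gamma_tau_median
                              * np.exp(rng.normal(0, config.gamma_tau_log_sd))),
        asym=float(rng.normal(0, config.asym_sd)),
        alpha_freq=float(rng.uniform(9.0, 11.5)),
        tep_scale=float(np.exp(rng.normal(0, config.tep_scale_log_sd))),
    )


@dataclass
class Cohort:
    """A generated cohort; recordings are synthesised lazily and deterministically.

    Recording synthesis is a pure function of (config.seed, subject, session),
    so repeated calls — and repeated cohorts from the same config — are
    bit-identical without holding hours of 64-channel EEG in memory.
    """

    config: CohortConfig
    montage: Montage
    traits: list[SubjectTraits]
    clinical: pd.DataFrame
    ground_truth: GroundTruth
    _session_codes = {"rest": 0, "treatment": 1, "tep_pre": 2, "tep_post": 3}

    def _rng(self, subject: str, session: str) -> np.random.Generator:
        i = self.subject_ids.index(subject)
        return np.random.default_rng(
            np.random.SeedSequence([self.config.seed, i,
                                    self._session_codes[session]]))

    @property
    def subject_ids(self) -> list[str]:
        return [t.subject for t in self.traits]

    def traits_of(self, subject: str) -> SubjectTraits:
        return self.traits[self.subject_ids.index(subject)]

    def rest_recording(self, subject: str) -> Recording:
        t = self.traits_of(subject)
        return synthesize_rest_eeg(t, self.config, self.montage,
                                   self._rng(subject, "rest"))

    def treatment_recording(self, subject: str) -> Recording:
        t = self.traits_of(subject)
        scale = dict(zip(GROUPS, self.config.group_gamma_scale))[t.group]
        return synthesize_treatment_eeg(t, self.config, self.montage,
                                        self._rng(subject, "treatment"),
                                        gamma_scale=scale)

    def tep_recording(self, subject: str, phase: str = "pre") -> Recording:
        if phase not in ("pre", "post"):
            raise ValueError("phase must be 'pre' or 'post'")
        t = self.traits_of(subject)
        scales = None
        if phase == "post" and t.group == "Real":
            scales = {"N75": self.config.tep_n75_post_scale_real}
        return synthesize_tep(t, self.config, scales, self.montage,
                              self._rng(subject, f"tep_{phase}"))


def generate_cohort(config: CohortConfig,
                    montage: Montage | None = None) -> Cohort:
    """Draw traits and the clinical table; recordings come from the Cohort.

    The clinical improvement of Real-group subject i is
    ``beta0 + beta1 log(gamma_resp_i / alpha_amp_i) + beta2 asym_i + e_i``
    with e ~ N(0, noise_sd); control subjects get beta1 = beta2 = 0 and
    noise matched to the Real group's total improvement SD, so group SDs are
    comparable and only the coupling (and the mean shift it carries)
    distinguishes the arms.
    """
    montage = montage or default_montage()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10 ** 6]))
    traits: list[SubjectTraits] = []
    rows = []
    pr = planted_correlation(config)
    sm2 = config.sigma_log_ratio ** 2
    total_var = (config.beta1 ** 2 * sm2
                 + config.beta2 ** 2 * config.asym_sd ** 2
                 + config.noise_sd ** 2)
    matched_sd = float(np.sqrt(total_var))
    true_imp = {}
    for group, n in zip(GROUPS, config.n_per_group):
        for j in range(n):
            sid = f"{group.lower()}{j + 1:02d}"
            tr = _draw_traits(config, rng, sid, group)
            traits.append(tr)
            if group == "Real":
                imp = (config.beta0
                       + config.beta1 * np.log(tr.gamma_resp / tr.alpha_amp)
                       + config.beta2 * tr.asym
                       + rng.normal(0, config.noise_sd))
            else:
                imp = config.beta0 + rng.normal(0, matched_sd)
            pre_t = rng.normal(config.pre_mean_t, config.pre_sd_t)
            post_t = pre_t - imp
            fu_t = pre_t - (0.8 * imp + rng.normal(0, 3.0))
            pre_raw = pre_t - _RAW_OFFSET
            post_raw = post_t - _RAW_OFFSET
            true_imp[sid] = imp
            rows.append({
                "subject": sid, "group": group,
                "pre_t": pre_t, "post_t": post_t, "fu_t": fu_t,
                "pre_raw": pre_raw, "post_raw": post_raw,
                "improvement_t": imp,
                "responder": (pre_raw - post_raw) / pre_raw >= 0.25,
            })
    clinical = pd.DataFrame(rows)
    gt = GroundTruth(
        traits=traits,
        true_improvement=pd.Series(true_imp, name="true_improvement"),
        planted_r_fc4=pr["r_fc4"],
        planted_r_log_ratio=pr["r_log_ratio"],
        planted_r2_dual=pr["r2_dual"],
    )
    return Cohort(config, montage, traits, clinical, gt)
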
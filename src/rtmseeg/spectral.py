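"""Band powers, the low-gamma/alpha marker, and the scalp-level models.

The biomarker is the ratio of low-gamma (30-40 Hz) to alpha (8-14.5 Hz)
absolute power in the first post-train ITI segment (seconds 1-3 after each
train) of the first treatment session. Note the direction: gamma over alpha,
so the marker grows with cortical responsiveness to the trains and shrinks
with trait alpha — the direction under which its correlation with clinical
improvement is positive. A ``invert`` switch is provided for the reciprocal
convention. Correlations involving the marker are computed on log-marker
values by default (power-ratio distributions are right-skewed); a flag
restores the linear scale.

Scalp-level inference comes in two flavours:

* whole-scalp correlation maps, cluster-corrected by the Monte-Carlo
  permutation machinery in :mod:`rtmseeg.stats`;
* inter-hemispheric balance models — per-electrode partial correlations with
  the outcome controlling for the homologous contralateral electrode,
  tested parametrically (t with df = n - 3) and FDR-corrected over the 54
  lateral channels (or a listed subset), since the two-step partial
  correlation does not permute cleanly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .montage import Montage
from .preprocess import EpochSet
from .stats import ClusterResult, bh_fdr, cluster_permutation, partial_correlation

__all__ = [
    "BandDefinition", "ALPHA", "LOW_GAMMA", "BETA",
    "psd", "band_power", "epochs_band_power",
    "compute_marker", "marker_outcome_map",
    "interhemispheric_balance", "resting_alpha_balance",
    "iti_dynamics", "rest_treatment_correlation",
    "dual_channel_r2",
    "PREFRONTAL_BALANCE_CHANNELS",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float   # Hz, inclusive
    hi: float   # Hz, inclusive

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError("require 0 < lo < hi")


ALPHA = BandDefinition("Alpha", 8.0, 14.5)
LOW_GAMMA = BandDefinition("LowGamma", 30.0, 40.0)
BETA = BandDefinition("Beta", 15.0, 29.5)

#: the eight prefrontal channels of the resting-state balance model
PREFRONTAL_BALANCE_CHANNELS = ("FC4", "FC2", "F4", "F2", "FC3", "FC1", "F3", "F1")


def psd(epochs: EpochSet, seg_len: float = 1.0, overlap: float = 0.5,
        window: str = "hann") -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per channel, averaged across epochs.

    Returns (freqs, pxx) with pxx of shape (n_channels, n_freqs) in
    power/Hz. ``seg_len`` seconds per Welch segment gives a 1/seg_len Hz
    frequency resolution (1 Hz at the 1 s default on 2 s epochs).
    """
    if epochs.n_epochs == 0:
        raise ValueError("no epochs")
    nper = int(round(seg_len * epochs.sfreq))
    if nper > epochs.data.shape[2]:
        raise ValueError("seg_len exceeds the epoch length")
    freqs, pxx = spsig.welch(epochs.data, fs=epochs.sfreq, window=window,
                             nperseg=nper, noverlap=int(round(nper * overlap)),
                             axis=2)
    return freqs, pxx.mean(axis=0)


def band_power(freqs: np.ndarray, pxx: np.ndarray,
               band: BandDefinition) -> np.ndarray:
    """Absolute band power: trapezoid integral of the PSD over [lo, hi].

    Integrates over the frequency-grid points inside the (inclusive) band.
    """
    if band.hi >= freqs[-1] + (freqs[1] - freqs[0]):
        raise ValueError(f"band {band.name} extends beyond the spectrum")
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    if sel.sum() < 2:
        raise ValueError(f"band {band.name} covers fewer than 2 frequency bins")
    return np.trapezoid(pxx[..., sel], freqs[sel], axis=-1)


def epochs_band_power(epochs: EpochSet, bands: tuple[BandDefinition, ...],
                      **psd_kw) -> dict[str, np.ndarray]:
    """Per-channel absolute power for each band, from epoch-averaged Welch PSD."""
    freqs, pxx = psd(epochs, **psd_kw)
    return {b.name: band_power(freqs, pxx, b) for b in bands}


def compute_marker(power_alpha: pd.DataFrame, power_gamma: pd.DataFrame,
                   invert: bool = False) -> pd.DataFrame:
    """Marker map: low-gamma / alpha power ratio, subjects x channels.

    ``invert=True`` switches to the reciprocal (alpha/gamma) convention.
    """
    if not power_alpha.index.equals(power_gamma.index) or \
            not power_alpha.columns.equals(power_gamma.columns):
        raise ValueError("alpha and gamma tables must be aligned")
    if (power_alpha <= 0).any().any():
        raise ValueError("non-positive alpha power: degenerate input")
    marker = power_gamma / power_alpha
    if invert:
        if (power_gamma <= 0).any().any():
            raise ValueError("non-positive gamma power with invert=True")
        marker = 1.0 / marker
    return marker


def marker_outcome_map(marker: pd.DataFrame, improvement: pd.Series,
                       montage: Montage, n_perm: int = 1000,
                       seed: int | None = None, alpha_cf: float = 0.05,
                       log_transform: bool = True) -> ClusterResult:
    """Whole-scalp marker-outcome correlation map, cluster-corrected.

    Per-channel Pearson r between the (log-)marker and the improvement
    score, with Monte-Carlo max-cluster-mass correction over the montage
    adjacency.
    """
    imp = improvement.reindex(marker.index)
    if imp.isna().any():
        raise ValueError("improvement is missing for some subjects")
    x = np.log(marker) if log_transform else marker
    return cluster_permutation(x, "correlate", montage.adjacency,
                               covariate=imp.to_numpy(), alpha_cf=alpha_cf,
                               n_perm=n_perm, seed=seed)


def interhemispheric_balance(values: pd.DataFrame, improvement: pd.Series,
                             montage: Montage, q: float = 0.05,
                             channels: tuple[str, ...] | None = None,
                             log_transform: bool = False) -> pd.DataFrame:
    """Inter-hemispheric balance model over the lateral channels.

    For each lateral channel e: partial correlation between values[e] and
    the improvement, controlling for values at the homologous contralateral
    channel; two-tailed parametric p (df = n - 3); Benjamini-Hochberg q over
    the tested channel set (all 54 lateral channels by default).
    """
    if channels is None:
        channels = montage.lateral_channels
    bad = [c for c in channels if c in montage.midline]
    if bad:
        raise ValueError(f"midline channels have no homologue: {bad}")
    imp = improvement.reindex(values.index)
    if imp.isna().any():
        raise ValueError("improvement is missing for some subjects")
    if len(values) < 6:
        raise ValueError("need >= 6 subjects for the balance model")
    x = np.log(values) if log_transform else values
    rows = []
    for ch in channels:
        pair = montage.pairs[ch]
        if ch not in x.columns or pair not in x.columns:
            warnings.warn(f"skipping {ch}: missing data for the {pair} homologue")
            continue
        r, t, p = partial_correlation(x[ch], imp, x[pair])
        rows.append({"channel": ch, "pair": pair, "r_partial": r, "t": t, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        rej, qv = bh_fdr(out["p"].to_numpy(), q)
        out["q"] = qv
        out["significant"] = rej
    return out


def resting_alpha_balance(rest_alpha: pd.DataFrame, improvement: pd.Series,
                          montage: Montage,
                          channels_of_interest: tuple[str, ...] = PREFRONTAL_BALANCE_CHANNELS,
                          q: float = 0.05, log_transform: bool = False) -> pd.DataFrame:
    """Balance model for resting alpha power over a prefrontal channel set.

    Identical computation to :func:`interhemispheric_balance`, restricted to
    ``channels_of_interest`` (default: FC4, FC2, F4, F2 and their left
    homologues) with FDR over that set only.
    """
    lateral = set(montage.lateral_channels)
    bad = [c for c in channels_of_interest if c not in lateral]
    if bad:
        raise ValueError(f"channels of interest must be lateral: {bad}")
    return interhemispheric_balance(rest_alpha, improvement, montage, q=q,
                                    channels=tuple(channels_of_interest),
                                    log_transform=log_transform)


def iti_dynamics(subject_epochs: dict[str, EpochSet],
                 bands: tuple[BandDefinition, ...] = (ALPHA, LOW_GAMMA),
                 channel: str = "FC4", max_segment: int = 7,
                 **psd_kw) -> dict[str, pd.DataFrame]:
    """Within-ITI power dynamics at one channel, normalised to segment 1.

    Per subject and band, power in ITI segment k is expressed as a ratio to
    the first post-train (1-3 s) segment. Returns the tidy per-subject
    ratios, group-level mean/SE per segment, and a two-way repeated-measures
    ANOVA (segments 2..max x band) whose interaction term captures the
    signature pattern: gamma decaying across the interval while alpha stays
    flat. Subjects missing segment 1 are dropped with a warning.
    """
    import pingouin as pg

    rows = []
    for sid, ep in subject_epochs.items():
        if ep.condition != "iti":
            raise ValueError(f"{sid}: epochs are not ITI-segmented")
        ci = ep.channel_index(channel)
        segs = np.unique(ep.segment_index)
        segs = segs[segs <= max_segment]
        if 1 not in segs or len(segs) < 2:
            warnings.warn(f"dropping {sid}: first ITI segment missing")
            continue
        power = {}
        for k in segs:
            sub = ep.select(ep.segment_index == k)
            bp = epochs_band_power(sub, bands, **psd_kw)
            power[k] = {b.name: bp[b.name][ci] for b in bands}
        for k in segs:
            for b in bands:
                rows.append({"subject": sid, "segment": int(k), "band": b.name,
                             "ratio": power[k][b.name] / power[1][b.name]})
    ratios = pd.DataFrame(rows)
    if ratios.empty:
        raise ValueError("no subject provided at least 2 ITI segments")
    summary = (ratios.groupby(["band", "segment"])["ratio"]
               .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
               .reset_index())
    # ANOVA on segments >= 2 (segment 1 is identically 1 by construction),
    # restricted to segments every subject contributes
    post = ratios[ratios["segment"] >= 2]
    counts = post.groupby("segment")["subject"].nunique()
    full = counts[counts == post["subject"].nunique()].index
    post = post[post["segment"].isin(full)]
    anova = pg.rm_anova(data=post, dv="ratio", within=["segment", "band"],
                        subject="subject", detailed=True)
    return {"ratios": ratios, "summary": summary, "anova": anova}


def rest_treatment_correlation(rest_power: pd.DataFrame,
                               iti_power: pd.DataFrame) -> pd.Series:
    """Across-subject Pearson r per channel: resting vs first-ITI-segment power."""
    if not rest_power.index.equals(iti_power.index):
        raise ValueError("rest and treatment tables must cover the same subjects")
    if len(rest_power) < 4:
        raise ValueError("need >= 4 subjects")
    r = {ch: np.corrcoef(rest_power[ch], iti_power[ch])[0, 1]
         for ch in rest_power.columns}
    return pd.Series(r, name="r")


def dual_channel_r2(values: pd.DataFrame, improvement: pd.Series,
                    channel: str, montage: Montage,
                    log_transform: bool = False) -> dict[str, float]:
    """Explained variance of the single- vs dual-channel outcome models.

    Single: r^2 of improvement on values[channel]. Dual: R^2 of the ordinary
    least-squares fit of improvement on {values[channel], values[pair]} —
    the regression form of the inter-hemispheric balance model.
    """
    pair = montage.pairs.get(channel)
    if pair is None:
        raise ValueError(f"{channel} is a midline channel")
    x = np.log(values) if log_transform else values
    y = improvement.reindex(values.index).to_numpy(float)
    x1 = x[channel].to_numpy(float)
    x2 = x[pair].to_numpy(float)
    r_single = np.corrcoef(x1, y)[0, 1]
    X = np.column_stack([np.ones_like(x1), x1, x2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r2_dual = 1.0 - resid.var() / y.var()
    r_partial, _, _ = partial_correlation(x1, y, x2)
    return {"r_single": float(r_single),
            "r2_single": float(r_single ** 2),
            "r2_dual": float(r2_dual),
            "r_partial": float(r_partial)}
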
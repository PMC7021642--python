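"""TMS-evoked potential (TEP) averaging, component amplitudes, contrasts.

The TEP is the trial-averaged EEG response to single TMS pulses; over the
prefrontal cortex it shows the canonical N45, P60, N75, N100 and P180
deflections. Component statistics are mean amplitudes over fixed time
windows of interest (TOIs), excluding the excised pulse-artifact samples;
treatment effects are assessed on per-subject post-minus-pre change scores
with the cluster-based permutation machinery (one-way F screen across the
three arms, then pairwise independent-t decomposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .stats import ClusterResult, cluster_permutation

__all__ = [
    "TEPComponent", "DEFAULT_COMPONENTS", "TEPWaveform",
    "average_tep", "component_amplitude", "component_amplitude_table",
    "tep_contrast",
]


@dataclass(frozen=True)
class TEPComponent:
    name: str
    polarity: int          # -1 for N components, +1 for P
    toi_ms: tuple[float, float]

    def __post_init__(self):
        if self.toi_ms[0] >= self.toi_ms[1] or self.toi_ms[0] < 0:
            raise ValueError("TOI must be ordered and non-negative")
        expected = -1 if self.name.startswith("N") else 1
        if self.polarity != expected:
            raise ValueError(f"{self.name}: polarity does not match the prefix")


#: Default TOIs. Only the N75 range (60-90 ms) is anchored in prior reports;
#: the others are symmetric windows around the canonical latencies.
DEFAULT_COMPONENTS = (
    TEPComponent("N45", -1, (35.0, 55.0)),
    TEPComponent("P60", +1, (55.0, 70.0)),
    TEPComponent("N75", -1, (70.0, 90.0)),
    TEPComponent("N100", -1, (90.0, 130.0)),
    TEPComponent("P180", +1, (150.0, 250.0)),
)


@dataclass
class TEPWaveform:
    """Across-pulse average TEP: channels x time, with its standard error."""

    mean: np.ndarray          # (n_channels, n_samples), uV
    se: np.ndarray
    times: np.ndarray         # seconds relative to the pulse
    ch_names: tuple[str, ...]
    n_epochs: int
    excluded_samples: np.ndarray | None = None   # artifact-window mask

    def channel(self, label: str) -> np.ndarray:
        return self.mean[self.ch_names.index(label)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ch in enumerate(self.ch_names):
            for j, t in enumerate(self.times):
                rows.append({"channel": ch, "time_ms": 1000 * t,
                             "mean": self.mean[i, j], "se": self.se[i, j]})
        return pd.DataFrame(rows)


def average_tep(epochs: EpochSet, min_epochs: int = 10) -> TEPWaveform:
    """Pointwise mean and standard error across pulse epochs."""
    if epochs.condition != "tep":
        raise ValueError("expected TEP epochs")
    if epochs.n_epochs < min_epochs:
        raise ValueError(f"need >= {min_epochs} epochs, got {epochs.n_epochs}")
    if epochs.times is None:
        raise ValueError("TEP epochs must carry a time axis")
    mean = epochs.data.mean(axis=0)
    se = epochs.data.std(axis=0, ddof=1) / np.sqrt(epochs.n_epochs)
    return TEPWaveform(mean, se, epochs.times, epochs.ch_names,
                       epochs.n_epochs, epochs.excluded_samples)


def component_amplitude(waveform: TEPWaveform,
                        components: tuple[TEPComponent, ...] = DEFAULT_COMPONENTS,
                        channel: str | None = None,
                        mode: str = "mean") -> dict[str, float] | pd.DataFrame:
    """Mean (or signed-peak) amplitude over each component's TOI.

    Flagged artifact samples never contribute. With ``channel`` set, returns
    a {component: amplitude} dict for that channel; otherwise a DataFrame of
    channels x components.
    """
    if mode not in ("mean", "peak"):
        raise ValueError("mode must be 'mean' or 'peak'")
    t_ms = waveform.times * 1000.0
    ok = np.ones_like(t_ms, bool)
    if waveform.excluded_samples is not None:
        ok &= ~waveform.excluded_samples
    table = {}
    for comp in components:
        sel = ok & (t_ms >= comp.toi_ms[0]) & (t_ms <= comp.toi_ms[1])
        if not sel.any():
            raise ValueError(f"{comp.name}: TOI fully excluded by the artifact window")
        seg = waveform.mean[:, sel]
        if mode == "mean":
            table[comp.name] = seg.mean(axis=1)
        else:
            idx = np.argmax(comp.polarity * seg, axis=1)
            table[comp.name] = seg[np.arange(seg.shape[0]), idx]
    df = pd.DataFrame(table, index=list(waveform.ch_names))
    if channel is not None:
        return df.loc[channel].to_dict()
    return df


def component_amplitude_table(epoch_sets: dict[str, EpochSet],
                              components: tuple[TEPComponent, ...] = DEFAULT_COMPONENTS,
                              min_epochs: int = 10,
                              mode: str = "mean") -> dict[str, pd.DataFrame]:
    """Per-component subjects x channels amplitude tables from TEP epochs."""
    per_comp: dict[str, dict[str, pd.Series]] = {c.name: {} for c in components}
    for sid, ep in epoch_sets.items():
        wf = average_tep(ep, min_epochs=min_epochs)
        amp = component_amplitude(wf, components, mode=mode)
        for c in components:
            per_comp[c.name][sid] = amp[c.name]
    return {name: pd.DataFrame(d).T for name, d in per_comp.items()}


def tep_contrast(pre: dict[str, pd.DataFrame], post: dict[str, pd.DataFrame],
                 groups: pd.Series, adjacency: nx.Graph,
                 contrast: tuple[str, str] = ("Real", "Sham"),
                 n_perm: int = 1000, seed: int | None = None,
                 alpha_cf: float = 0.05) -> dict[str, dict[str, ClusterResult]]:
    """Time x Group contrasts on TEP component amplitudes, per TOI.

    ``pre``/``post`` map component name -> subjects x channels amplitude
    table. For each component, subject-level change scores (post - pre) are
    screened for a group interaction (one-way F across all arms, clustered)
    and decomposed with the pairwise independent-t contrast between the two
    ``contrast`` groups. Subjects without both sessions are dropped with a
    warning.
    """
    out: dict[str, dict[str, ClusterResult]] = {}
    for name, pre_tab in pre.items():
        post_tab = post[name]
        common = pre_tab.index.intersection(post_tab.index)
        lost = set(pre_tab.index).symmetric_difference(post_tab.index)
        if lost:
            warnings.warn(f"{name}: dropping unpaired subjects {sorted(lost)}")
        change = post_tab.loc[common] - pre_tab.loc[common]
        g = groups.reindex(common)
        if g.isna().any():
            raise ValueError("group labels missing for some subjects")
        screen = cluster_permutation(change, "group_f", adjacency,
                                     groups=g.to_numpy(), alpha_cf=alpha_cf,
                                     n_perm=n_perm, seed=seed)
        mask = g.isin(contrast).to_numpy()
        pair = cluster_permutation(change.loc[mask], "two_group", adjacency,
                                   groups=g[mask].to_numpy(), alpha_cf=alpha_cf,
                                   n_perm=n_perm, seed=seed)
        out[name] = {"interaction": screen, "pairwise": pair}
    return out
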
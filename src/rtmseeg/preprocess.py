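"""From raw recordings to analysis-ready epochs.

Covers the four preprocessing steps the downstream spectral and TEP analyses
rely on:

* inter-train-interval (ITI) segmentation — 2 s epochs cut from each quiet
  period between stimulation trains, starting 1 s after a train ends (to
  clear residual stimulation artifact) and stopping 5 s before the next
  train (to avoid anticipation effects); with 20 s between train end and the
  next onset this yields exactly 7 segments per ITI;
* TEP epoching around single pulses, with linear interpolation across the
  pulse-artifact window and pre-pulse baseline correction;
* re-referencing: average reference (AVR) and current source density (CSD,
  spherical-spline surface Laplacian after Perrin);
* a simple amplitude-threshold epoch rejector.

Epochs live in :class:`EpochSet`, a plain channels x samples x epochs
container with enough provenance (condition, ITI segment index, reference
scheme) that reference transitions and segment selections stay explicit.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial.legendre import legval

from .montage import Montage

__all__ = [
    "Recording", "EpochSet",
    "extract_iti_epochs", "first_segment",
    "apply_average_reference", "apply_csd", "csd_transform_matrix",
    "extract_tep_epochs", "reject_epochs",
    "read_recording_edf", "save_epochs", "load_epochs",
]


@dataclass
class Recording:
    """A continuous multi-channel recording with event annotations.

    data is channels x samples in microvolts. ``events`` is a list of
    (onset_s, duration_s, label) tuples; labels used by the pipeline are
    ``train_onset``, ``train_offset`` and ``tms_pulse``. ``artifact_mask``
    flags samples that must not enter any epoch (e.g. amplifier saturation
    during stimulation trains).
    """

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    events: list[tuple[float, float, str]]
    artifact_mask: np.ndarray | None = None
    subject: str = ""
    session: str = ""

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples)")
        if self.artifact_mask is not None and \
                self.artifact_mask.shape != (self.data.shape[1],):
            raise ValueError("artifact_mask must be per-sample")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sfreq

    def event_times(self, label: str) -> np.ndarray:
        return np.array([on for on, _, lab in self.events if lab == label])


@dataclass
class EpochSet:
    """Fixed-length epochs: (n_epochs, n_channels, n_samples) in microvolts."""

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    condition: str                       # 'rest' | 'iti' | 'tep'
    reference: str = "raw"               # 'raw' | 'AVR' | 'CSD'
    segment_index: np.ndarray | None = None   # per-epoch ITI position, 1-based
    times: np.ndarray | None = None      # per-sample time axis (s), TEP epochs
    excluded_samples: np.ndarray | None = None  # per-sample mask, TEP artifact
    subject: str = ""
    session: str = ""

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")
        if (self.segment_index is not None) != (self.condition == "iti"):
            raise ValueError("segment_index must be present iff condition == 'iti'")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        seg = None if self.segment_index is None else self.segment_index[mask]
        return dataclasses.replace(self, data=self.data[mask], segment_index=seg)

    def channel_index(self, label: str) -> int:
        try:
            return self.ch_names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epochs") from None

    def pick_channels(self, labels: tuple[str, ...]) -> "EpochSet":
        """Subset to the listed channels (after any referencing)."""
        idx = [self.channel_index(ch) for ch in labels]
        return dataclasses.replace(self, data=self.data[:, idx, :],
                                   ch_names=tuple(labels))


# --------------------------------------------------------------------------
# ITI segmentation
# --------------------------------------------------------------------------

def iti_epoch_count(L: float, epoch_len: float = 2.0, start_gap: float = 1.0,
                    end_gap: float = 5.0) -> int:
    """Number of epochs fitting in one ITI of duration ``L`` seconds."""
    return max(0, int(np.floor((L - start_gap - end_gap) / epoch_len + 1e-9)))


def extract_iti_epochs(
    recording: Recording,
    train_events: list[tuple[float, float]] | None = None,
    epoch_len: float = 2.0,
    start_gap: float = 1.0,
    end_gap: float = 5.0,
) -> EpochSet:
    """Cut non-overlapping epochs from the inter-train intervals.

    ``train_events`` is a sorted list of (onset, offset) train windows in
    seconds; by default it is read from the recording's ``train_onset`` /
    ``train_offset`` annotations. For each ITI (train offset to next train
    onset) consecutive epochs of ``epoch_len`` are cut from
    ``[offset + start_gap, next_onset - end_gap]``; the last train's ITI,
    which has no upcoming train, is bounded by the recording end with no
    ``end_gap``. Epochs overlapping artifact-flagged samples are dropped.
    ``segment_index`` numbers the surviving positions 1..k per ITI in
    temporal order (1 = first post-train segment).
    """
    if train_events is None:
        onsets = recording.event_times("train_onset")
        offsets = recording.event_times("train_offset")
        if len(onsets) != len(offsets):
            raise ValueError("unbalanced train_onset/train_offset annotations")
        train_events = list(zip(onsets, offsets))
    if not train_events:
        raise ValueError("no train events")
    arr = np.asarray(train_events, float)
    if np.any(arr[:, 1] < arr[:, 0]):
        raise ValueError("train offset precedes onset")
    if np.any(np.diff(arr[:, 0]) <= 0) or np.any(arr[1:, 0] < arr[:-1, 1]):
        raise ValueError("train events must be sorted and non-overlapping")
    if arr[0, 0] < 0 or arr[-1, 1] > recording.duration + 1e-9:
        raise ValueError("train events outside the recording")

    sf = recording.sfreq
    n_samp = int(round(epoch_len * sf))
    epochs, seg_idx = [], []
    for i, (_, offset) in enumerate(arr):
        if i + 1 < len(arr):
            hi = arr[i + 1, 0] - end_gap
        else:
            hi = recording.duration
        lo = offset + start_gap
        k = 0
        t = lo
        while t + epoch_len <= hi + 1e-9:
            k += 1
            s0 = int(round(t * sf))
            sl = slice(s0, s0 + n_samp)
            if recording.artifact_mask is not None and \
                    recording.artifact_mask[sl].any():
                t += epoch_len
                continue
            epochs.append(recording.data[:, sl])
            seg_idx.append(k)
            t += epoch_len

    data = (np.stack(epochs) if epochs
            else np.empty((0, len(recording.ch_names), n_samp)))
    return EpochSet(data, sf, tuple(recording.ch_names), "iti",
                    segment_index=np.asarray(seg_idx, int),
                    subject=recording.subject, session=recording.session)


def first_segment(epochs: EpochSet) -> EpochSet:
    """Keep only the first post-train segment (seconds 1-3 after each train)."""
    if epochs.condition != "iti":
        raise ValueError("first_segment applies to ITI epochs")
    return epochs.select(epochs.segment_index == 1)


# --------------------------------------------------------------------------
# referencing
# --------------------------------------------------------------------------

def apply_average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous cross-channel mean from every sample."""
    if epochs.reference != "raw":
        raise ValueError(
            f"refusing to average-reference {epochs.reference}-referenced data")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return dataclasses.replace(epochs, data=data, reference="AVR")


def _legendre_factors(stiffness: int, n_terms: int, offset: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1)
    return np.concatenate([
        [0.0],
        (2 * n + 1) / (n ** (stiffness - offset) * (n + 1) ** (stiffness - offset)
                       * 4 * np.pi),
    ])


def csd_transform_matrix(montage: Montage, stiffness: int = 4,
                         lambda2: float = 1e-5, n_legendre_terms: int = 50,
                         head_radius: float = 0.095) -> np.ndarray:
    """Linear operator mapping scalp potentials to their surface Laplacian.

    Spherical-spline current source density (Perrin et al. style): solve the
    regularised spline system G c = v under a zero-sum constraint, then
    evaluate the Laplacian expansion H c, scaled by 1/head_radius^2.
    Returned matrix T acts on channel vectors: csd = T @ v.
    """
    pos = montage.positions
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    if np.any(np.triu(cosang, k=1) > 1 - 1e-12):
        raise ValueError("duplicate electrode positions make the spline singular")
    G = legval(cosang, _legendre_factors(stiffness, n_legendre_terms, 0))
    H = legval(cosang, _legendre_factors(stiffness, n_legendre_terms, 1))
    n = G.shape[0]
    G_reg = G + np.eye(n) * lambda2
    Gi = np.linalg.inv(G_reg)
    TC = Gi.sum(axis=0)
    sgi = TC.sum()
    # spline coefficients under the zero-sum constraint, for demeaned input
    coef = Gi - np.outer(TC, TC) / sgi
    demean = np.eye(n) - np.ones((n, n)) / n
    return (H @ coef @ demean) / head_radius ** 2


def apply_csd(epochs: EpochSet, montage: Montage, stiffness: int = 4,
              lambda2: float = 1e-5, n_legendre_terms: int = 50,
              head_radius: float = 0.095) -> EpochSet:
    """Current source density (spherical-spline surface Laplacian) reference.

    Accepts raw or average-referenced input (the Laplacian annihilates the
    spatial constant, so both give identical output); output units are
    potential per square metre of scalp for the given ``head_radius``.
    """
    if epochs.reference == "CSD":
        raise ValueError("data is already CSD-referenced")
    if tuple(montage.channel_names) != tuple(epochs.ch_names):
        raise ValueError("montage channels do not match the epochs")
    T = csd_transform_matrix(montage, stiffness, lambda2, n_legendre_terms,
                             head_radius)
    data = np.einsum("ij,ejs->eis", T, epochs.data)
    return dataclasses.replace(epochs, data=data, reference="CSD")


# --------------------------------------------------------------------------
# TEP epoching
# --------------------------------------------------------------------------

def extract_tep_epochs(
    recording: Recording,
    pulse_events: np.ndarray | None = None,
    window: tuple[float, float] = (-0.5, 0.5),
    artifact_window: tuple[float, float] = (-0.002, 0.010),
    baseline: tuple[float, float] = (-0.200, -0.010),
) -> EpochSet:
    """Epoch around single TMS pulses with artifact excision and baselining.

    Samples inside ``artifact_window`` (seconds relative to the pulse) are
    replaced by linear interpolation between the window edges and flagged in
    ``excluded_samples`` so they never enter TOI statistics. The per-channel
    mean over ``baseline`` is then subtracted. Pulses whose window falls
    outside the recording are skipped.
    """
    if pulse_events is None:
        pulse_events = recording.event_times("tms_pulse")
    pulse_events = np.asarray(pulse_events, float)
    if pulse_events.size == 0:
        raise ValueError("need at least one pulse event")
    if baseline[1] > artifact_window[0] and baseline[0] < artifact_window[1]:
        raise ValueError("baseline window overlaps the artifact window")

    sf = recording.sfreq
    n_pre = int(round(-window[0] * sf))
    n_post = int(round(window[1] * sf))
    times = np.arange(-n_pre, n_post) / sf
    art = (times >= artifact_window[0]) & (times <= artifact_window[1])
    base = (times >= baseline[0]) & (times <= baseline[1])
    if not base.any():
        raise ValueError("baseline window contains no samples")

    i_lo = int(np.argmax(art)) - 1 if art.any() else None
    i_hi = (len(art) - int(np.argmax(art[::-1]))) if art.any() else None

    epochs = []
    for t in pulse_events:
        c = int(round(t * sf))
        if c - n_pre < 0 or c + n_post > recording.data.shape[1]:
            warnings.warn(f"pulse at {t:.3f}s too close to the recording edge; skipped")
            continue
        ep = recording.data[:, c - n_pre:c + n_post].astype(float).copy()
        if art.any():
            lo = max(i_lo, 0)
            hi = min(i_hi, ep.shape[1] - 1)
            span = hi - lo
            w = (np.arange(span + 1) / span)[None, :]
            ep[:, lo:hi + 1] = ep[:, [lo]] * (1 - w) + ep[:, [hi]] * w
        ep -= ep[:, base].mean(axis=1, keepdims=True)
        epochs.append(ep)
    if not epochs:
        raise ValueError("no pulse produced a complete epoch")
    return EpochSet(np.stack(epochs), sf, tuple(recording.ch_names), "tep",
                    times=times, excluded_samples=art,
                    subject=recording.subject, session=recording.session)


def reject_epochs(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Drop epochs whose absolute amplitude exceeds ``threshold_uv`` anywhere."""
    peak = np.abs(epochs.data).max(axis=(1, 2))
    return epochs.select(peak <= threshold_uv)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_recording_edf(path: str | Path, subject: str = "",
                       session: str = "") -> Recording:
    """Load an EDF recording (with its annotations as events) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = [(float(on), float(du), str(desc))
              for on, du, desc in zip(raw.annotations.onset,
                                      raw.annotations.duration,
                                      raw.annotations.description)]
    return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names),
                     events, subject=subject, session=session)


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write epochs as ``<path>.npz`` plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    arrays = {"data": epochs.data}
    if epochs.segment_index is not None:
        arrays["segment_index"] = epochs.segment_index
    if epochs.times is not None:
        arrays["times"] = epochs.times
    if epochs.excluded_samples is not None:
        arrays["excluded_samples"] = epochs.excluded_samples
    np.savez_compressed(str(path) + ".npz", **arrays)
    meta = {"sfreq": epochs.sfreq, "ch_names": list(epochs.ch_names),
            "condition": epochs.condition, "reference": epochs.reference,
            "subject": epochs.subject, "session": epochs.session}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    with np.load(str(path) + ".npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(Path(str(path) + ".json").read_text())
    return EpochSet(arrays["data"], meta["sfreq"], tuple(meta["ch_names"]),
                    meta["condition"], reference=meta["reference"],
                    segment_index=arrays.get("segment_index"),
                    times=arrays.get("times"),
                    excluded_samples=arrays.get("excluded_samples"),
                    subject=meta["subject"], session=meta["session"])
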
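"""Filtering, artifact detection and trial segmentation of NREM iEEG.

The raw bipolar channels are high-pass (0.3 Hz) and notch (50 Hz and
harmonics up to 300 Hz) filtered with zero-phase IIR filters.  Artifacts
(epileptiform transients, electrode pops) are flagged per channel where
the z-score of the signal gradient or of >250-Hz activity exceeds a
threshold (default 6), and artifact-free runs of at least 3 s within
same-stage N2/N3 epoch spans are kept as analysis "trials".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "Trial",
    "apply_filters",
    "detect_artifacts",
    "segment_trials",
    "preprocess",
]

EPOCH_S = 20.0  # sleep-stage scoring epoch length
NREM_STAGES = frozenset({"N2", "N3"})

HIGHPASS_HZ = 0.3
NOTCH_HZ = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
NOTCH_Q = 35.0
ARTIFACT_Z = 6.0
ARTIFACT_PAD_S = 0.25  # dilation margin around threshold crossings
HF_BAND_LOW_HZ = 250.0
MIN_TRIAL_S = 3.0


@dataclass
class Trial:
    """Contiguous artifact-free, stage-pure interval, half-open samples."""

    channel: str
    start: int
    end: int
    stage: str

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def duration_s(self, fs: float) -> float:
        return self.n_samples / fs


@dataclass
class Recording:
    """Continuous channels plus stage and artifact annotations.

    ``stages`` holds one label per 20-s scoring epoch ({N1, N2, N3, REM,
    Wake}); the last epoch may be partial.  ``artifact_mask`` maps channel
    label to a boolean series (True = rejected sample).
    """

    channels: dict[str, np.ndarray]
    fs: float
    stages: list[str]
    artifact_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have the same length")
        (self.n_samples,) = lengths
        n_epochs = int(np.ceil(self.n_samples / (EPOCH_S * self.fs)))
        if len(self.stages) < n_epochs:
            raise ValueError("stage annotation does not cover the recording")
        for mask in self.artifact_mask.values():
            if len(mask) != self.n_samples:
                raise ValueError("artifact mask length mismatch")

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def stage_of_sample(self) -> np.ndarray:
        """Per-sample stage label array."""
        idx = (np.arange(self.n_samples) / (EPOCH_S * self.fs)).astype(int)
        return np.asarray(self.stages, dtype=object)[idx]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def apply_filters(series: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.3-Hz high-pass and 50-Hz-harmonic notch filtering.

    Requires ``fs`` > 600 Hz so that the highest notch (300 Hz) stays
    below Nyquist.
    """
    if fs <= 2 * NOTCH_HZ[-1]:
        raise ValueError("sampling rate too low for notches up to 300 Hz")
    sos = signal.butter(2, HIGHPASS_HZ, btype="highpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, np.asarray(series, dtype=float))
    for f0 in NOTCH_HZ:
        b, a = signal.iirnotch(f0, NOTCH_Q, fs=fs)
        out = signal.filtfilt(b, a, out)
    return out


# ---------------------------------------------------------------------------
# artifact detection
# ---------------------------------------------------------------------------

def _dilate(mask: np.ndarray, pad: int) -> np.ndarray:
    if pad <= 0 or not mask.any():
        return mask
    kernel = np.ones(2 * pad + 1, dtype=bool)
    return np.convolve(mask, kernel, mode="same").astype(bool)


def detect_artifacts(series: np.ndarray, fs: float,
                     z_thresh: float = ARTIFACT_Z,
                     pad_s: float = ARTIFACT_PAD_S) -> np.ndarray:
    """Boolean mask of artifactual samples of one channel.

    A sample is flagged where the |z| of the first difference (signal
    gradient) or the |z| of high-frequency (>250 Hz) Hilbert envelope
    exceeds ``z_thresh``; flags are dilated by ``pad_s`` on each side.
    z statistics are computed over the whole recording, giving a single
    channel-specific threshold.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of data for stable z-scoring")
    if np.ptp(x) == 0:
        raise ValueError("constant series: zero variance")

    grad = np.diff(x)
    gsd = grad.std()
    if gsd == 0:
        raise ValueError("zero-variance gradient")
    gz = np.abs(grad - grad.mean()) / gsd
    grad_mask = np.zeros(len(x), dtype=bool)
    hit = gz > z_thresh
    grad_mask[:-1] |= hit
    grad_mask[1:] |= hit  # a step implicates both samples

    hf_hi = fs / 2 - 10.0
    sos = signal.butter(4, [HF_BAND_LOW_HZ, hf_hi], btype="bandpass",
                        fs=fs, output="sos")
    hf = signal.sosfiltfilt(sos, x)
    env = np.abs(signal.hilbert(hf))
    esd = env.std()
    if esd == 0:
        raise ValueError("zero-variance high-frequency envelope")
    ez = np.abs(env - env.mean()) / esd
    mask = grad_mask | (ez > z_thresh)
    return _dilate(mask, int(round(pad_s * fs)))


# ---------------------------------------------------------------------------
# trial segmentation
# ---------------------------------------------------------------------------

def segment_trials(recording: Recording,
                   stages: frozenset[str] | set[str] = NREM_STAGES,
                   min_dur_s: float = MIN_TRIAL_S,
                   channel: str | None = None) -> list[Trial]:
    """Maximal artifact-free runs inside same-stage epoch spans.

    With ``channel=None`` the union (logical OR) of all channels' artifact
    masks is used, yielding trials during which every channel is clean —
    the segmentation used for all cross-channel analyses.  Runs shorter
    than ``min_dur_s`` are dropped; trials never span a stage change.
    """
    fs = recording.fs
    if channel is None:
        mask = np.zeros(recording.n_samples, dtype=bool)
        for m in recording.artifact_mask.values():
            mask |= m
        label = "+".join(sorted(recording.channels))
    else:
        mask = recording.artifact_mask.get(
            channel, np.zeros(recording.n_samples, dtype=bool))
        label = channel

    stage_per_sample = recording.stage_of_sample()
    ok = ~mask & np.isin(stage_per_sample, list(stages))
    # break runs at stage changes as well as at mask flips
    stage_codes = np.unique(stage_per_sample, return_inverse=True)[1]
    boundaries = np.flatnonzero(np.diff(stage_codes)) + 1

    trials: list[Trial] = []
    edges = np.flatnonzero(np.diff(ok.astype(np.int8)))
    starts = list(edges[ok[edges + 1]] + 1)
    ends = list(edges[~ok[edges + 1]] + 1)
    if ok[0]:
        starts.insert(0, 0)
    if ok[-1]:
        ends.append(len(ok))
    min_n = int(round(min_dur_s * fs))
    for s, e in zip(starts, ends):
        cuts = [s] + [b for b in boundaries if s < b < e] + [e]
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a >= min_n:
                trials.append(Trial(channel=label, start=int(a), end=int(b),
                                    stage=str(stage_per_sample[a])))
    trials.sort(key=lambda t: t.start)
    return trials


def preprocess(recording: Recording, z_thresh: float = ARTIFACT_Z,
               stages: frozenset[str] | set[str] = NREM_STAGES,
               min_dur_s: float = MIN_TRIAL_S
               ) -> tuple[Recording, list[Trial]]:
    """Filter all channels, detect artifacts, and cut joint NREM trials.

    Artifact detection runs on the filtered (post-notch) signals.  Returns
    a new :class:`Recording` holding the filtered channels and masks, and
    the list of joint (all-channels-clean) trials.
    """
    filtered = {ch: apply_filters(x, recording.fs)
                for ch, x in recording.channels.items()}
    masks = {ch: detect_artifacts(x, recording.fs, z_thresh=z_thresh)
             for ch, x in filtered.items()}
    clean = Recording(channels=filtered, fs=recording.fs,
                      stages=list(recording.stages), artifact_mask=masks)
    return clean, segment_trials(clean, stages=stages, min_dur_s=min_dur_s)
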
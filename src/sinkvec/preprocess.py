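"""Preprocessing of multichannel interictal iEEG snapshots.

Turns a raw snapshot into filtered, common-average-referenced, windowed
data ready for dynamical-network-model fitting:

    bandpass (0.5-300 Hz, 4th-order Butterworth, zero-phase)
    -> notch at the powerline frequency and its harmonics (2 Hz stopband)
    -> channel exclusion (bad / white-matter / out-of-brain channels)
    -> common average reference
    -> segmentation into non-overlapping 500 ms windows

All filters are applied forward and backward (zero-phase) so that the
one-step-lag regression structure of the downstream model is not skewed
by filter group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "Snapshot",
    "ChannelAnnotation",
    "WindowedData",
    "bandpass_filter",
    "notch_filter",
    "common_average_reference",
    "segment_windows",
    "apply_annotations",
]


@dataclass(frozen=True)
class Snapshot:
    """One interictal multichannel recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Channel voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per row of ``samples``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(samples)):
            raise ValueError("snapshot contains NaN or Inf samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds."""
        return self.n_times / self.fs


@dataclass(frozen=True)
class ChannelAnnotation:
    """Per-channel clinical metadata.

    ``is_ez`` marks membership in the clinically annotated epileptogenic
    zone; ``excluded`` marks channels to drop (broken, excessively noisy,
    white matter, or outside the brain).
    """

    label: str
    is_ez: bool = False
    excluded: bool = False
    notes: str = ""


@dataclass(frozen=True)
class WindowedData:
    """Non-overlapping fixed-length windows cut from one snapshot."""

    windows: tuple[np.ndarray, ...]
    fs: float
    window_ms: int
    channel_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(np.asarray(w, float) for w in self.windows))
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        shapes = {w.shape for w in self.windows}
        if len(shapes) > 1:
            raise ValueError(f"windows have inconsistent shapes: {shapes}")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def _sos_bandpass(low_hz: float, high_hz: float, order: int, fs: float) -> np.ndarray:
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    snapshot: Snapshot,
    low_hz: float = 0.5,
    high_hz: float = 300.0,
    order: int = 4,
) -> Snapshot:
    """Zero-phase Butterworth bandpass, 0.5-300 Hz by default.

    Raises
    ------
    ValueError
        If the band edges are not ``0 < low_hz < high_hz < fs/2``.
    """
    nyq = snapshot.fs / 2.0
    if high_hz >= nyq:
        raise ValueError(
            f"bandpass upper edge {high_hz} Hz must lie below the Nyquist "
            f"frequency {nyq} Hz (fs={snapshot.fs} Hz)"
        )
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    sos = _sos_bandpass(low_hz, high_hz, order, snapshot.fs)
    filtered = signal.sosfiltfilt(sos, snapshot.samples, axis=1)
    return replace(snapshot, samples=filtered)


def notch_filter(
    snapshot: Snapshot,
    line_hz: float = 60.0,
    stop_bw_hz: float = 2.0,
    max_hz: float = 300.0,
) -> Snapshot:
    """Zero-phase notches at the powerline frequency and its harmonics.

    Harmonics are notched up to ``min(fs/2, max_hz)``; the bandpass removes
    energy above ``max_hz`` anyway, so higher harmonics are irrelevant.
    """
    nyq = snapshot.fs / 2.0
    if line_hz >= nyq:
        raise ValueError(
            f"line frequency {line_hz} Hz must lie below Nyquist {nyq} Hz"
        )
    data = snapshot.samples
    top = min(nyq, max_hz)
    freq = line_hz
    while freq < top:
        b, a = signal.iirnotch(freq, Q=freq / stop_bw_hz, fs=snapshot.fs)
        data = signal.filtfilt(b, a, data, axis=1)
        freq += line_hz
    return replace(snapshot, samples=data)


def common_average_reference(snapshot: Snapshot) -> Snapshot:
    """Subtract the across-channel mean at every sample (CAR).

    Mitigates noise common to all electrodes. Idempotent; the output's
    channel mean is zero at every time index.
    """
    if snapshot.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    referenced = snapshot.samples - snapshot.samples.mean(axis=0, keepdims=True)
    return replace(snapshot, samples=referenced)


def segment_windows(snapshot: Snapshot, window_ms: int = 500) -> WindowedData:
    """Cut the snapshot into non-overlapping windows from sample 0.

    The trailing partial window is discarded. Window length in samples is
    ``round(window_ms * fs / 1000)``.
    """
    n_per = int(round(window_ms * snapshot.fs / 1000.0))
    if n_per < 2:
        raise ValueError(f"window of {window_ms} ms is too short at fs={snapshot.fs}")
    n_win = snapshot.n_times // n_per
    if n_win < 1:
        raise ValueError(
            f"snapshot of {snapshot.n_times} samples is shorter than one "
            f"{window_ms} ms window ({n_per} samples)"
        )
    windows = tuple(
        snapshot.samples[:, i * n_per : (i + 1) * n_per] for i in range(n_win)
    )
    return WindowedData(
        windows=windows,
        fs=snapshot.fs,
        window_ms=window_ms,
        channel_labels=snapshot.channel_labels,
    )


def apply_annotations(
    snapshot: Snapshot, annotations: list[ChannelAnnotation]
) -> tuple[Snapshot, np.ndarray]:
    """Drop excluded channels and build the EZ mask over retained channels.

    Returns the reduced snapshot together with a boolean vector aligned to
    its retained channels (True = clinically annotated EZ).

    Raises
    ------
    KeyError
        If an annotation label does not match any snapshot channel.
    ValueError
        If no channel would remain after exclusion.
    """
    by_label = {a.label: a for a in annotations}
    unmatched = sorted(set(by_label) - set(snapshot.channel_labels))
    if unmatched:
        raise KeyError(
            f"annotation labels not present in snapshot: {unmatched}"
        )
    keep_idx = [
        i
        for i, lab in enumerate(snapshot.channel_labels)
        if not (lab in by_label and by_label[lab].excluded)
    ]
    if not keep_idx:
        raise ValueError("all channels excluded; nothing left to analyse")
    reduced = Snapshot(
        samples=snapshot.samples[keep_idx, :],
        fs=snapshot.fs,
        channel_labels=tuple(snapshot.channel_labels[i] for i in keep_idx),
    )
    ez_mask = np.array(
        [
            lab in by_label and by_label[lab].is_ez
            for lab in reduced.channel_labels
        ],
        dtype=bool,
    )
    if not ez_mask.any():
        warnings.warn(
            "no EZ channel retained; the EZ contrast statistic is undefined "
            "downstream",
            UserWarning,
            stacklevel=2,
        )
    return reduced, ez_mask
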
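"""Model/Results facade over the preprocessing-model-biomarker pipeline.

`DynamicalNetworkModel` is constructed from one patient's snapshot plus
channel annotations and preprocessing settings; `fit()` runs the full
chain (filtering, referencing, windowing, per-window least squares,
eigen-decomposition) and returns a `DNMResults` object carrying the
per-window state-transition matrices, leading eigenpairs, the averaged
eigenvector, the EZ contrast theta, source-sink metrics, and a summary
table. Simulation and plotting hang off these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import biomarkers, dnm, preprocess
from .biomarkers import EigenBiomarker
from .dnm import DNMSequence
from .preprocess import ChannelAnnotation, Snapshot

__all__ = ["DynamicalNetworkModel", "DNMResults"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter and windowing settings for one model fit."""

    bandpass_low: float = 0.5
    bandpass_high: float = 300.0
    filter_order: int = 4
    line_freq: float = 60.0
    notch_bw: float = 2.0
    window_ms: int = 500
    ridge: float = 0.0
    apply_filters: bool = True
    apply_car: bool = True


class DynamicalNetworkModel:
    """Windowed linear dynamical network model of one iEEG snapshot.

    Parameters
    ----------
    snapshot : Snapshot
        The raw multichannel recording.
    annotations : sequence of ChannelAnnotation, optional
        Per-channel EZ membership and exclusion flags. Without
        annotations the model still fits and yields eigenvector and
        source-sink features, but theta is unavailable.
    config : PreprocessConfig, optional
        Filtering/windowing settings; defaults follow standard clinical
        preprocessing (0.5-300 Hz bandpass, 60 Hz notches, CAR, 500 ms
        windows, plain least squares).

    Examples
    --------
    >>> from sinkvec import synth
    >>> net = synth.make_sink_network(8, 1, seed=3)
    >>> snap = synth.simulate_snapshot(net, fs=500, duration_s=10, seed=3)
    >>> res = DynamicalNetworkModel(snap).fit()
    >>> res.v_avg.shape
    (8,)
    """

    def __init__(
        self,
        snapshot: Snapshot,
        annotations: Sequence[ChannelAnnotation] | None = None,
        config: PreprocessConfig | None = None,
    ):
        self.config = config or PreprocessConfig()
        self.raw = snapshot
        if annotations:
            snapshot, ez_mask = preprocess.apply_annotations(snapshot, list(annotations))
        else:
            ez_mask = None
        self.snapshot = snapshot
        self.ez_mask = ez_mask

    @classmethod
    def from_arrays(
        cls,
        samples: np.ndarray,
        fs: float,
        channel_labels: Sequence[str] | None = None,
        ez_mask: Sequence[bool] | None = None,
        **config_kwargs,
    ) -> "DynamicalNetworkModel":
        """Build directly from an array, labels, and an optional EZ mask."""
        samples = np.asarray(samples, dtype=float)
        if channel_labels is None:
            channel_labels = tuple(f"CH{i + 1:03d}" for i in range(samples.shape[0]))
        snap = Snapshot(samples=samples, fs=fs, channel_labels=tuple(channel_labels))
        annotations = None
        if ez_mask is not None:
            annotations = [
                ChannelAnnotation(label=lab, is_ez=bool(flag))
                for lab, flag in zip(snap.channel_labels, ez_mask, strict=True)
            ]
        config = PreprocessConfig(**config_kwargs) if config_kwargs else None
        return cls(snap, annotations=annotations, config=config)

    def _preprocessed(self) -> Snapshot:
        snap = self.snapshot
        cfg = self.config
        if cfg.apply_filters:
            snap = preprocess.bandpass_filter(
                snap, cfg.bandpass_low, cfg.bandpass_high, cfg.filter_order
            )
            snap = preprocess.notch_filter(
                snap, cfg.line_freq, cfg.notch_bw, max_hz=cfg.bandpass_high
            )
        if cfg.apply_car:
            snap = preprocess.common_average_reference(snap)
        return snap

    def fit(self) -> "DNMResults":
        """Run the full pipeline and return the results object."""
        snap = self._preprocessed()
        windowed = preprocess.segment_windows(snap, window_ms=self.config.window_ms)
        seq = dnm.fit_dnm_sequence(windowed, ridge=self.config.ridge)
        bio = None
        if self.ez_mask is not None and self.ez_mask.any() and not self.ez_mask.all():
            bio = biomarkers.compute_biomarker(seq, self.ez_mask)
        return DNMResults(model=self, sequence=seq, biomarker=bio)


@dataclass
class DNMResults:
    """Fitted per-window models and the derived eigenvector biomarker."""

    model: DynamicalNetworkModel
    sequence: DNMSequence
    biomarker: EigenBiomarker | None = None
    _ssm: dict | None = field(default=None, repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.sequence)

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return self.sequence.channel_labels

    @property
    def v_avg(self) -> np.ndarray:
        """Window-averaged leading right eigenvector (the per-channel biomarker)."""
        if self.biomarker is not None:
            return self.biomarker.v_avg
        return biomarkers.average_evc(self.sequence)

    @property
    def theta(self) -> float:
        """EZ contrast: mean v_avg over EZ minus mean over non-EZ channels."""
        if self.biomarker is None:
            raise ValueError("theta requires an EZ annotation with both classes")
        return self.biomarker.theta

    @property
    def leading_eigenvalues(self) -> np.ndarray:
        """Modulus of the leading eigenvalue of each window's A."""
        if self.biomarker is not None:
            return np.array([p.lam for p in self.biomarker.per_window])
        return np.array(
            [biomarkers.leading_eigvec(t).lam for t in self.sequence.transitions]
        )

    def source_sink(self) -> dict[str, np.ndarray]:
        """Per-channel source-sink metrics averaged across windows (cached)."""
        if self._ssm is None:
            self._ssm = biomarkers.average_source_sink(self.sequence)
        return self._ssm

    def features(self) -> pd.DataFrame:
        """Per-channel feature table for the classification experiments."""
        ssm = self.source_sink()
        table = pd.DataFrame(
            {
                "channel": list(self.channel_labels),
                "evc_avg": self.v_avg,
                "row_norm_avg": ssm["row_norm"],
                "col_norm_avg": ssm["col_norm"],
                "sink_index_avg": ssm["sink_index"],
                "source_influence_avg": ssm["source_influence"],
                "sink_connectivity_avg": ssm["sink_connectivity"],
            }
        )
        if self.model.ez_mask is not None:
            table["is_ez"] = self.model.ez_mask
        return table

    def simulate(self, x0: np.ndarray, t: int, window: int = 0) -> np.ndarray:
        """Propagate ``x0`` noiselessly through window ``window``'s dynamics."""
        return dnm.simulate_forward(self.sequence.transitions[window], x0, t)

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        lines = [
            "Dynamical Network Model Results",
            "=" * 46,
            f"Channels:            {len(self.channel_labels)}",
            f"Windows fitted:      {self.n_windows}",
            f"Window length:       {self.model.config.window_ms} ms",
            f"Sampling rate:       {self.model.snapshot.fs:g} Hz",
            f"Mean |lambda_1|:     {self.leading_eigenvalues.mean():.4f}",
        ]
        if self.biomarker is not None:
            lines += [
                f"v_EZ (mean EVC, EZ): {self.biomarker.v_ez:.4f}",
                f"v_nEZ (non-EZ):      {self.biomarker.v_nez:.4f}",
                f"theta (contrast):    {self.biomarker.theta:+.4f}",
            ]
        lines.append("-" * 46)
        top = np.argsort(self.v_avg)[::-1][:5]
        lines.append("Top channels by averaged eigenvector component:")
        for i in top:
            marker = ""
            if self.model.ez_mask is not None:
                marker = "  [EZ]" if self.model.ez_mask[i] else ""
            lines.append(f"  {self.channel_labels[i]:<12} {self.v_avg[i]:.4f}{marker}")
        return "\n".join(lines)

    def plot_evc(self, ax=None):
        """Bar plot of the averaged eigenvector component per channel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        order = np.argsort(self.v_avg)[::-1]
        colors = None
        if self.model.ez_mask is not None:
            colors = ["crimson" if self.model.ez_mask[i] else "steelblue" for i in order]
        ax.bar(range(len(order)), self.v_avg[order], color=colors)
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels([self.channel_labels[i] for i in order], rotation=90, fontsize=6)
        ax.set_ylabel("averaged EVC")
        return ax
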
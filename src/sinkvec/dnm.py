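"""Linear dynamical network models (DNMs) of windowed iEEG.

Each 500 ms window is modelled as a linear time-invariant system

    x(t+1) = A x(t) + e(t)

where x(t) is the vector of channel voltages and e(t) white Gaussian
noise. A_ij quantifies the influence of channel j's current activity on
channel i's next sample, so row i collects the network's cumulative
effect on channel i (incoming influence) and column j the effect channel
j exerts on the network (outgoing influence). The time-varying model for
a whole snapshot is the ordered sequence of per-window A matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import WindowedData

__all__ = ["StateTransition", "DNMSequence", "estimate_A", "fit_dnm_sequence", "simulate_forward"]


@dataclass(frozen=True)
class StateTransition:
    """State-transition matrix of one window's LTI model."""

    A: np.ndarray
    window_index: int = 0
    n_samples_fit: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("A contains non-finite entries")
        object.__setattr__(self, "A", A)

    @property
    def n_channels(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class DNMSequence:
    """Ordered stack of per-window state-transition matrices."""

    transitions: tuple[StateTransition, ...]
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        dims = {t.n_channels for t in self.transitions}
        if len(dims) > 1:
            raise ValueError(f"inconsistent matrix dimensions across windows: {dims}")

    def __len__(self) -> int:
        return len(self.transitions)

    def stack(self) -> np.ndarray:
        """All A matrices as one (n_windows, N, N) array."""
        return np.stack([t.A for t in self.transitions])


def estimate_A(
    window: np.ndarray,
    window_index: int = 0,
    ridge: float = 0.0,
) -> StateTransition:
    """Least-squares estimate of the state-transition matrix from one window.

    Solves ``min_A sum_t || x(t+1) - A x(t) ||^2`` over the window's
    consecutive sample pairs. With a rank-deficient regressor matrix the
    minimum-norm solution is returned, which keeps short, ill-conditioned
    windows usable. ``ridge`` adds an optional L2 penalty (default off).

    Parameters
    ----------
    window : ndarray, shape (n_channels, T)
        One window of multichannel data, T >= 2.
    """
    X = np.asarray(window, dtype=float)
    if X.ndim != 2:
        raise ValueError("window must be 2-D (channels x time)")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"window {window_index} contains non-finite samples")
    n, T = X.shape
    if T < 2:
        raise ValueError(f"window {window_index} has T={T} < 2 samples")
    past = X[:, :-1].T        # (T-1, N) regressors
    future = X[:, 1:].T       # (T-1, N) targets
    if ridge > 0.0:
        G = past.T @ past + ridge * np.eye(n)
        A = np.linalg.solve(G, past.T @ future).T
    else:
        # lstsq returns the minimum-norm solution for rank-deficient systems
        sol, *_ = np.linalg.lstsq(past, future, rcond=None)
        A = sol.T
    return StateTransition(A=A, window_index=window_index, n_samples_fit=T)


def fit_dnm_sequence(windowed: WindowedData, ridge: float = 0.0) -> DNMSequence:
    """Fit one state-transition matrix per window, preserving order."""
    if windowed.n_windows == 0:
        raise ValueError("no windows to fit")
    transitions = []
    for i, w in enumerate(windowed.windows):
        try:
            transitions.append(estimate_A(w, window_index=i, ridge=ridge))
        except ValueError as exc:
            raise ValueError(f"window {i}: {exc}") from exc
    return DNMSequence(transitions=tuple(transitions), channel_labels=windowed.channel_labels)


def simulate_forward(A: StateTransition | np.ndarray, x0: np.ndarray, t: int) -> np.ndarray:
    """Propagate the noiseless dynamics: return ``A^t x0``.

    For t large the direction of the result converges to the leading right
    eigenvector of A (for a strictly dominant leading eigenvalue), which is
    why that eigenvector reads out the steady-state sink pattern.
    """
    mat = A.A if isinstance(A, StateTransition) else np.asarray(A, dtype=float)
    x = np.asarray(x0, dtype=float)
    if x.shape != (mat.shape[0],):
        raise ValueError(f"x0 has shape {x.shape}, expected ({mat.shape[0]},)")
    if t < 0:
        raise ValueError("t must be >= 0")
    for _ in range(t):
        x = mat @ x
    return x
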
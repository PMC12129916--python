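"""Leading-eigenvector biomarker and source-sink metrics.

The leading right eigenvector v1 of a state-transition matrix A gives
the direction of the system's steady state: iterating x(t) = A^t x(0)
aligns x with v1 as t grows, so the channels carrying the largest
components of v1 are the network's strongest sinks — they accumulate
activity driven by the rest of the network. Per window we extract the
modulus-largest eigenpair; the per-channel biomarker is the component
of the window-averaged eigenvector v_avg, and the per-patient contrast

    theta = mean(v_avg over EZ channels) - mean(v_avg over non-EZ channels)

measures how strongly the clinically annotated epileptogenic zone (EZ)
coincides with the network's sinks.

Source-sink metrics derived from row/column norms of A are provided as
a comparison feature set. Their exact published form lives in prior
work; here they follow a documented rank-based convention (see
``source_sink_metrics``) and downstream use relies only on their rank
behaviour, not their absolute values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dnm import DNMSequence, StateTransition

__all__ = [
    "EigenPair",
    "EigenBiomarker",
    "SourceSinkMetrics",
    "leading_eigvec",
    "average_evc",
    "evc_contrast",
    "source_sink_metrics",
    "steady_state_direction",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class EigenPair:
    """Leading eigenpair of one window's A matrix.

    ``lam`` is the modulus of the modulus-largest eigenvalue; ``v`` the
    unit-norm nonnegative representative of the corresponding right
    eigenvector (element-wise modulus for a complex pair, sign fixed so
    the component sum is nonnegative for a real one).
    """

    lam: float
    v: np.ndarray
    is_complex: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))


@dataclass(frozen=True)
class EigenBiomarker:
    """Window-resolved eigenpairs plus the averaged biomarker and contrast."""

    per_window: tuple[EigenPair, ...]
    v_avg: np.ndarray
    v_ez: float
    v_nez: float
    theta: float


@dataclass(frozen=True)
class SourceSinkMetrics:
    """Row/column-norm derived channel metrics for one A matrix.

    row_norm_i measures total incoming influence onto channel i,
    col_norm_j total outgoing influence of channel j. The remaining three
    follow the rank-based convention documented in ``source_sink_metrics``.
    """

    row_norm: np.ndarray
    col_norm: np.ndarray
    sink_index: np.ndarray
    source_influence: np.ndarray
    sink_connectivity: np.ndarray


def leading_eigvec(A: StateTransition | np.ndarray) -> EigenPair:
    """Leading (modulus-largest) right eigenpair with a fixed representative.

    The eigenvector is scaled to unit Euclidean norm. For a complex
    eigenpair the representative is the element-wise modulus; for a real
    one the sign is chosen so the component sum is >= 0. A modulus tie
    within 1e-12 is broken toward the larger real part with a warning.
    """
    mat = A.A if isinstance(A, StateTransition) else np.asarray(A, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"A must be square, got {mat.shape}")
    if not np.all(np.isfinite(mat)):
        raise ValueError("A contains non-finite entries")
    eigvals, eigvecs = np.linalg.eig(mat)
    mods = np.abs(eigvals)
    top = mods.max()
    tied = np.flatnonzero(mods >= top - _TIE_TOL)
    if len(tied) > 1:
        # a complex-conjugate pair always shares one modulus; both members
        # yield the same representative, so that is not a genuine tie
        genuine = not (
            len(tied) == 2
            and np.isclose(eigvals[tied[0]], np.conj(eigvals[tied[1]]), atol=1e-9)
            and abs(eigvals[tied[0]].imag) > _TIE_TOL
        )
        if genuine:
            warnings.warn(
                f"leading eigenvalue modulus tied across {len(tied)} "
                "eigenvalues; breaking tie by larger real part",
                UserWarning,
                stacklevel=2,
            )
        idx = tied[np.argmax(eigvals[tied].real)]
    else:
        idx = tied[0]
    lam = eigvals[idx]
    vec = eigvecs[:, idx]
    vec = vec / np.linalg.norm(vec)
    is_complex = bool(abs(lam.imag) > _TIE_TOL or np.abs(vec.imag).max() > 1e-9)
    if is_complex:
        rep = np.abs(vec)
        rep = rep / np.linalg.norm(rep)
    else:
        rep = vec.real
        rep = rep / np.linalg.norm(rep)
        if rep.sum() < 0:
            rep = -rep
    return EigenPair(lam=float(abs(lam)), v=rep, is_complex=is_complex)


def average_evc(seq: DNMSequence) -> np.ndarray:
    """Component-wise mean of per-window leading-eigenvector representatives.

    Representatives are all nonnegative, so the average cannot suffer
    sign cancellation across windows.
    """
    if len(seq) == 0:
        raise ValueError("empty model sequence")
    vecs = np.stack([leading_eigvec(t).v for t in seq.transitions])
    return vecs.mean(axis=0)


def evc_contrast(v_avg: np.ndarray, ez_mask: np.ndarray) -> tuple[float, float, float]:
    """EZ-vs-rest contrast of the averaged eigenvector.

    Returns ``(v_ez, v_nez, theta)`` with ``theta = v_ez - v_nez``, the
    per-patient biomarker: positive when the annotated EZ carries larger
    steady-state components than the rest of the network.
    """
    v = np.asarray(v_avg, dtype=float)
    mask = np.asarray(ez_mask, dtype=bool)
    if v.shape != mask.shape:
        raise ValueError(f"shape mismatch: v_avg {v.shape}, ez_mask {mask.shape}")
    if not mask.any() or mask.all():
        raise ValueError(
            "EZ contrast undefined: mask must contain both EZ and non-EZ channels"
        )
    v_ez = float(v[mask].mean())
    v_nez = float(v[~mask].mean())
    return v_ez, v_nez, v_ez - v_nez


def source_sink_metrics(A: StateTransition | np.ndarray) -> SourceSinkMetrics:
    """Row/column-norm channel metrics in a rank-based source-sink space.

    Convention (a sink has strong incoming and weak outgoing influence):

    - ``row_norm`` / ``col_norm``: Euclidean norms of A's rows / columns.
    - Channels are placed in a 2-D rank space with sink rank = descending
      row-norm rank and source rank = descending col-norm rank, both
      normalized to (0, 1].
    - ``sink_index``: 2 minus the Euclidean distance from the ideal sink
      corner (top row-norm rank, bottom col-norm rank); larger = more
      sink-like.
    - ``source_influence``: for each channel, the mean connection strength
      |A_ij| received from the quartile of channels ranked most source-like.
    - ``sink_connectivity``: the mean strength |A_ij| received from the
      quartile ranked most sink-like.
    """
    mat = A.A if isinstance(A, StateTransition) else np.asarray(A, dtype=float)
    n = mat.shape[0]
    row_norm = np.linalg.norm(mat, axis=1)
    col_norm = np.linalg.norm(mat, axis=0)
    if n == 1:
        one = np.ones(1)
        return SourceSinkMetrics(row_norm, col_norm, one, np.abs(mat[0]), np.abs(mat[0]))

    # rank 1 = smallest; normalized ranks in (0, 1]; average ranks for ties
    def _ranks(x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="stable")
        ranks = np.empty(n, float)
        ranks[order] = np.arange(1, n + 1)
        for val in np.unique(x):
            sel = x == val
            if sel.sum() > 1:
                ranks[sel] = ranks[sel].mean()
        return ranks / n

    rr = _ranks(row_norm)   # high = strong incoming = sink-like
    cr = _ranks(col_norm)   # high = strong outgoing = source-like
    # ideal sink corner: rr = 1, cr = 1/n; max distance sqrt(2)-ish
    sink_index = 2.0 - np.hypot(1.0 - rr, cr - 1.0 / n)

    k = max(1, n // 4)
    source_like = np.argsort(cr - rr)[-k:]   # most source-like channels
    sink_like = np.argsort(rr - cr)[-k:]     # most sink-like channels
    absA = np.abs(mat)
    source_influence = absA[:, source_like].mean(axis=1)
    sink_connectivity = absA[:, sink_like].mean(axis=1)
    return SourceSinkMetrics(
        row_norm=row_norm,
        col_norm=col_norm,
        sink_index=sink_index,
        source_influence=source_influence,
        sink_connectivity=sink_connectivity,
    )


def average_source_sink(seq: DNMSequence) -> dict[str, np.ndarray]:
    """Per-channel source-sink metrics averaged across windows."""
    if len(seq) == 0:
        raise ValueError("empty model sequence")
    acc: dict[str, list[np.ndarray]] = {
        "row_norm": [], "col_norm": [], "sink_index": [],
        "source_influence": [], "sink_connectivity": [],
    }
    for t in seq.transitions:
        m = source_sink_metrics(t)
        for key in acc:
            acc[key].append(getattr(m, key))
    return {key: np.stack(vals).mean(axis=0) for key, vals in acc.items()}


def compute_biomarker(seq: DNMSequence, ez_mask: np.ndarray) -> EigenBiomarker:
    """Full biomarker extraction for one patient's model sequence.

    Computes per-window leading eigenpairs, averages their representatives
    into v_avg, and contrasts EZ against non-EZ channels to obtain theta.
    """
    if len(seq) == 0:
        raise ValueError("empty model sequence")
    pairs = tuple(leading_eigvec(t) for t in seq.transitions)
    v_avg = np.stack([p.v for p in pairs]).mean(axis=0)
    v_ez, v_nez, theta = evc_contrast(v_avg, ez_mask)
    return EigenBiomarker(per_window=pairs, v_avg=v_avg, v_ez=v_ez, v_nez=v_nez, theta=theta)


def steady_state_direction(
    A: StateTransition | np.ndarray, x0: np.ndarray, t_max: int
) -> np.ndarray:
    """Normalized direction of ``A^t x0`` at ``t = t_max``.

    Components are returned as moduli (matching the eigenvector
    representative convention). Renormalizes at every step so the iterate
    neither overflows for an unstable A nor underflows for a stable one.
    """
    mat = A.A if isinstance(A, StateTransition) else np.asarray(A, dtype=float)
    x = np.asarray(x0, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("x0 must be nonzero")
    x = x / norm
    for _ in range(t_max):
        x = mat @ x
        nrm = np.linalg.norm(x)
        if nrm == 0:
            raise ValueError("trajectory collapsed to zero; direction undefined")
        x = x / nrm
    return np.abs(x)
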
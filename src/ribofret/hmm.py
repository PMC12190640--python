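"""FRET efficiency computation and per-trace HMM idealization.

Each selected trace is converted to a FRET efficiency series
``E = I_A / (I_A + I_D)`` and idealized with a Gaussian-emission hidden
Markov model fitted by Baum–Welch expectation–maximization.  The number of
states is chosen per trace by the Bayesian information criterion over
K = 1..K_max, after which the Viterbi path gives the per-frame state
sequence and fitted state means.  Finally each fitted state is mapped to
the nearest canonical conformation (apo / transit / holo at E ~0.2 / 0.6 /
0.8); distinct HMM states that land on the same canonical center merge, so
spurious within-peak transitions are erased.

Fitting is per molecule, not global: each trace gets its own state means,
and pooling across the ensemble happens downstream on idealized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._hmm_core import em_fit, gaussian_loglik_matrix, viterbi_decode
from .io import Trace

__all__ = [
    "FretTrace",
    "HmmModel",
    "IdealizedPath",
    "compute_efret",
    "fit_hmm_em",
    "select_model",
    "viterbi",
    "map_to_canonical",
    "idealize_trace",
]

#: E_FRET values are clamped to this window before fitting (noise can
#: carry the ratio outside [0, 1])
DEFAULT_CLAMP = (-0.2, 1.2)

#: emission-variance floor preventing collapse onto single points
VARIANCE_FLOOR = 1e-4

#: canonical conformation centers and labels, ordered by E
CANONICAL_CENTERS = (0.2, 0.6, 0.8)
CANONICAL_LABELS = ("apo", "transit", "holo")


@dataclass
class FretTrace:
    """Per-frame FRET efficiency of one molecule.

    ``valid`` marks frames whose summed intensity was high enough to define
    E; invalid frames are excluded from fitting and from dwell durations
    (the path is treated as contiguous across them).
    """

    molecule_id: str
    time: np.ndarray
    efret: np.ndarray
    valid: np.ndarray
    frame_rate: float

    @property
    def valid_efret(self) -> np.ndarray:
        return self.efret[self.valid]

    def __len__(self) -> int:
        return len(self.efret)


@dataclass
class HmmModel:
    """Fitted Gaussian-emission HMM for a single trace."""

    n_states: int
    means: np.ndarray
    variances: np.ndarray
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class IdealizedPath:
    """HMM-idealized state sequence of one molecule (valid frames only)."""

    molecule_id: str
    states: np.ndarray
    idealized_efret: np.ndarray
    state_means: np.ndarray
    frame_rate: float
    efret: np.ndarray | None = None
    canonical_labels: np.ndarray | None = None  # int indices into CANONICAL_LABELS

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_transitions(self) -> int:
        labels = self.canonical_labels if self.canonical_labels is not None else self.states
        return int(np.sum(np.diff(labels) != 0))


def compute_efret(
    trace: Trace,
    clamp: tuple[float, float] = DEFAULT_CLAMP,
    min_total_fraction: float = 0.05,
) -> FretTrace:
    """FRET efficiency E = I_A / (I_A + I_D) per frame.

    Frames whose summed intensity falls below ``min_total_fraction`` of the
    trace's median total are marked invalid (E is undefined near zero
    intensity) and excluded downstream.
    """
    if len(trace) < 1:
        raise ValueError("empty trace")
    total = trace.total
    ref = float(np.median(total))
    valid = total > min_total_fraction * ref
    if not np.any(valid):
        raise ValueError(f"{trace.molecule_id}: all frames below intensity threshold")
    e = np.full(len(trace), np.nan)
    e[valid] = trace.acceptor[valid] / total[valid]
    e[valid] = np.clip(e[valid], clamp[0], clamp[1])
    return FretTrace(trace.molecule_id, trace.time, e, valid, trace.frame_rate)


def _em_core(
    x: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    a: np.ndarray,
    pi: np.ndarray,
    max_iter: int,
    tol: float,
) -> HmmModel:
    """Baum–Welch iterations from a given starting point (numba kernel)."""
    k = len(means)
    t_len = len(x)
    means, variances, a, pi, history, it, converged = em_fit(
        x, means, variances, a, pi, max_iter, tol, VARIANCE_FLOOR
    )
    loglik = float(history[-1])
    p = k * k + 2 * k - 1
    bic = -2.0 * loglik + p * np.log(t_len)
    degenerate = bool(np.any(np.diff(np.sort(means)) < 1e-6)) if k > 1 else False
    return HmmModel(
        n_states=k,
        means=means,
        variances=variances,
        transition_matrix=a,
        initial_probs=pi,
        log_likelihood=loglik,
        bic=bic,
        converged=converged,
        degenerate=degenerate,
        n_iter=it,
        loglik_history=np.asarray(history),
    )


def _init_from_means(means: np.ndarray, k: int):
    variances = np.full(k, max(0.05**2, VARIANCE_FLOOR))
    a = np.full((k, k), 0.05 / max(k - 1, 1))
    np.fill_diagonal(a, 0.95)
    if k == 1:
        a = np.ones((1, 1))
    pi = np.full(k, 1.0 / k)
    return np.sort(means), variances, a, pi


def _default_init(x: np.ndarray, k: int, jitter_rng: np.random.Generator | None = None):
    """Quantile-based initialization: means at the (2i+1)/2K quantiles."""
    qs = (2 * np.arange(k) + 1) / (2 * k)
    means = np.quantile(x, qs)
    if jitter_rng is not None:
        means = means + jitter_rng.normal(0.0, 0.1, k)
    return _init_from_means(means, k)


def _spread_init(x: np.ndarray, k: int):
    """Means equispaced over the observed range.

    Quantile placement collapses into the dominant cluster when one state
    holds most of the frames, leaving minority states unseeded; the
    range-spread start guards against that local optimum.
    """
    lo, hi = float(x.min()), float(x.max())
    means = lo + (hi - lo) * (2 * np.arange(k) + 1) / (2 * k)
    return _init_from_means(means, k)


def fit_hmm_em(
    ft: FretTrace,
    k: int,
    init: tuple | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HmmModel:
    """Fit a K-state Gaussian HMM to one trace by Baum–Welch EM.

    The log-likelihood is non-decreasing across iterations; convergence is
    declared when the improvement drops below ``tol``.  Emission variances
    are floored at 1e-4 so constant traces with K >= 2 return a flagged
    model with (near-)duplicated means instead of diverging.
    """
    x = ft.valid_efret
    if k < 1:
        raise ValueError("K must be >= 1")
    if len(x) < 2 * k:
        raise ValueError(f"trace too short for K={k}: {len(x)} valid frames")
    if init is None:
        init = _default_init(x, k)
    means, variances, a, pi = (np.array(v, dtype=float) for v in init)
    return _em_core(x, means, variances, a, pi, max_iter, tol)


#: fixed seeds for the jittered restarts of select_model
RESTART_SEEDS = (1, 2, 3)


def select_model(ft: FretTrace, k_max: int = 4, max_iter: int = 500, tol: float = 1e-6) -> HmmModel:
    """Fit K = 1..K_max and return the minimum-BIC model.

    For each K two deterministic starts are tried (quantile-placed means
    and range-spread means) plus three jittered restarts with fixed seeds,
    keeping the best log-likelihood fit; model complexity is then compared
    by BIC = -2 logL + p log T with p = K^2 + 2K - 1.
    """
    x = ft.valid_efret
    best = None
    for k in range(1, k_max + 1):
        if len(x) < 2 * k:
            break
        candidates = [
            fit_hmm_em(ft, k, max_iter=max_iter, tol=tol),
            fit_hmm_em(ft, k, init=_spread_init(x, k), max_iter=max_iter, tol=tol),
        ]
        for s in RESTART_SEEDS:
            rng = np.random.default_rng(s)
            init = _default_init(x, k, jitter_rng=rng)
            candidates.append(fit_hmm_em(ft, k, init=init, max_iter=max_iter, tol=tol))
        model = max(candidates, key=lambda m: m.log_likelihood)
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise ValueError("trace too short to fit any model")
    return best


def viterbi(model: HmmModel, ft: FretTrace) -> IdealizedPath:
    """Maximum-probability state sequence under a fitted model.

    Ties are broken toward the lower state index.  The returned path covers
    the valid frames of the trace, treated as contiguous.
    """
    x = ft.valid_efret
    logb = gaussian_loglik_matrix(x, model.means, model.variances)
    with np.errstate(divide="ignore"):
        loga = np.log(np.maximum(model.transition_matrix, 1e-300))
        logpi = np.log(np.maximum(model.initial_probs, 1e-300))
    path, _ = viterbi_decode(logb, loga, logpi)
    return IdealizedPath(
        molecule_id=ft.molecule_id,
        states=path,
        idealized_efret=model.means[path],
        state_means=model.means.copy(),
        frame_rate=ft.frame_rate,
        efret=x,
    )


def _suppress_single_frame_runs(labels: np.ndarray) -> np.ndarray:
    """Merge one-frame sojourns into the adjacent dwell.

    A conformational transition in mid-frame produces exactly one camera
    frame whose intensity averages the two states; the HMM assigns that
    frame either to an intermediate state (a phantom one-frame visit) or
    to the far state (a phantom there-and-back flicker).  Both signatures
    are one-frame sojourns, below the instrument's time resolution, and
    are folded into the following dwell (the preceding one at the trace
    end).  Repeats until no interior one-frame sojourn remains.
    """
    labels = labels.copy()
    while True:
        change = np.nonzero(np.diff(labels) != 0)[0]
        if len(change) == 0:
            return labels
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [len(labels)]])
        lengths = ends - starts
        singles = np.nonzero(lengths == 1)[0]
        if len(singles) == 0:
            return labels
        for r in singles:
            if r + 1 < len(starts):
                labels[starts[r]] = labels[starts[r + 1]]
            else:
                labels[starts[r]] = labels[starts[r] - 1]


def map_to_canonical(
    path: IdealizedPath,
    centers: tuple[float, ...] = CANONICAL_CENTERS,
    suppress_blur: bool = True,
) -> IdealizedPath:
    """Assign each fitted state to the nearest canonical conformation.

    Ties go to the lower center.  Distinct HMM states may merge into one
    canonical label, which erases transitions between same-label states.
    With ``suppress_blur`` (default), one-frame sojourns in the canonical
    label sequence — the signature of a mid-frame transition blurred by
    camera integration — are folded into the neighbouring dwell (see
    :func:`_suppress_single_frame_runs`).
    """
    centers_arr = np.asarray(centers)
    # nearest center; numerical ties (within 1e-9) go to the lower center
    dist = np.abs(path.state_means[:, None] - centers_arr[None, :])
    near_min = dist <= dist.min(axis=1, keepdims=True) + 1e-9
    mapping = near_min.argmax(axis=1)  # first True = lowest tied center
    labels = mapping[path.states]
    if suppress_blur and len(labels) > 1:
        labels = _suppress_single_frame_runs(labels)
    path.canonical_labels = labels
    return path


def idealize_trace(trace: Trace, k_max: int = 4) -> IdealizedPath:
    """Convenience pipeline for one trace: E_FRET -> model selection ->
    Viterbi -> canonical mapping."""
    ft = compute_efret(trace)
    model = select_model(ft, k_max=k_max)
    return map_to_canonical(viterbi(model, ft))
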
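"""Ensemble statistics over idealized paths.

Turns per-molecule idealized state sequences into the headline quantities
of a riboswitch smFRET study: pooled FRET histograms and three-Gaussian
population fractions, transition occupancy density plots (TODPs),
static-trace fractions, dwell-time rate constants, Hill-fit dissociation
constants, and donor–acceptor distances from the Förster relation.

Rate estimation
---------------
Dwell times in a finite, photobleach-truncated observation window are a
censored sample: long dwells are preferentially cut off, so the naive
reciprocal mean of fully observed dwells overestimates rates (by tens of
percent at the dwell/window ratios typical here).  The default estimator
is therefore the standard right-censored exponential MLE,

    k = (number of observed transitions) / (total time spent in the state),

where each trace's first sojourn is excluded entirely (its start is
unobserved) and its final sojourn contributes exposure but no event.  On a
fully observed dwell sample this reduces exactly to 1/mean.  The literal
interior-dwell estimator is available as ``method="interior"`` for parity
with histogram-based fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .hmm import CANONICAL_CENTERS, CANONICAL_LABELS, IdealizedPath

__all__ = [
    "GaussianMixtureFit",
    "TODP",
    "DwellSet",
    "RateEstimate",
    "TitrationFit",
    "DistanceEstimate",
    "pooled_histogram",
    "fit_population_mixture",
    "build_todp",
    "classify_static",
    "static_fraction",
    "extract_dwells",
    "estimate_rate",
    "fit_hill",
    "efret_to_distance",
]


@dataclass
class GaussianMixtureFit:
    """Population fractions from a 1-D Gaussian mixture, means ascending."""

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    converged: bool
    n_components: int = 3


@dataclass
class TODP:
    """Transition occupancy density plot.

    ``matrix[i, j]`` is the fraction of molecules exhibiting at least one
    transition from FRET bin i to FRET bin j (off-diagonal); static
    molecules contribute to the diagonal at their mean idealized E.  Each
    molecule adds at most ``1/n_molecules`` per bin pair.
    """

    bin_edges: np.ndarray
    matrix: np.ndarray
    n_molecules: int

    def bin_index(self, e: float) -> int:
        """Bin index of a FRET value, robust at bin edges.

        Values that sit numerically on an edge (the canonical centers do)
        are assigned to the upper bin.
        """
        width = self.bin_edges[1] - self.bin_edges[0]
        n_bins = len(self.bin_edges) - 1
        return min(max(int(np.floor(e / width + 1e-9)), 0), n_bins - 1)


@dataclass
class DwellSet:
    """Dwell durations for one canonical transition, with censoring info.

    ``dwells`` holds interior sojourns in ``from`` that end in an observed
    transition to ``to``.  ``other_exit_durations`` are interior sojourns
    in ``from`` that exit to a different state; ``censored_durations`` are
    final sojourns in ``from`` cut off by the end of the observation
    window.  Both carry exposure time for the censored MLE but no events.
    First sojourns of every trace are excluded from all three.
    """

    transition_label: tuple[str, str]
    dwells: np.ndarray
    frame_period: float
    censored_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    other_exit_durations: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def censored_count(self) -> int:
        return len(self.censored_durations)

    def __len__(self) -> int:
        return len(self.dwells)


@dataclass
class RateEstimate:
    k: float            # 1/s
    se: float           # 1/s
    n_dwells: int
    method: str


@dataclass
class TitrationFit:
    """Hill-equation fit of a state fraction versus ligand concentration."""

    kd: float           # mM
    hill_n: float
    f0: float
    f_inf: float
    residual_norm: float
    at_bound: bool = False


@dataclass
class DistanceEstimate:
    r: float            # Angstrom
    r0: float = 55.0    # Angstrom


def pooled_histogram(
    paths: list[IdealizedPath], bin_width: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-weighted histogram of idealized E over all molecules.

    Every valid frame of every molecule contributes one count; values are
    clipped into [0, 1] so the total count equals the total frame count.
    Returns ``(counts, bin_edges)``.
    """
    if not paths:
        raise ValueError("no paths given")
    values = np.concatenate([p.idealized_efret for p in paths])
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.clip(values, 0.0, 1.0 - 1e-12), bins=edges)
    return counts, edges


def fit_population_mixture(
    e_values: np.ndarray,
    init_means: tuple[float, ...] = CANONICAL_CENTERS,
    max_iter: int = 1000,
    max_points: int = 200_000,
    seed: int = 0,
) -> GaussianMixtureFit:
    """Population fractions by 3-component Gaussian mixture EM.

    Fitted from the fixed canonical initialization; the component weights
    are the reported population fractions.  Inputs larger than
    ``max_points`` are subsampled (seeded) before fitting.
    """
    x = np.asarray(e_values, float).ravel()
    if len(x) < 300:
        raise ValueError(f"need >= 300 values for a stable mixture fit, got {len(x)}")
    if len(x) > max_points:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=max_points, replace=False)
    k = len(init_means)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        max_iter=max_iter,
        reg_covar=1e-8,
        means_init=np.asarray(init_means).reshape(-1, 1),
        weights_init=np.full(k, 1.0 / k),
        precisions_init=np.full((k, 1, 1), 1.0 / 0.07**2),
        tol=1e-8,
        n_init=1,
    )
    gm.fit(x.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    return GaussianMixtureFit(
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sigmas=np.sqrt(gm.covariances_.ravel()[order]),
        converged=bool(gm.converged_),
        n_components=k,
    )


def _label_runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a label sequence: (run_labels, run_lengths)."""
    change = np.nonzero(np.diff(labels) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(labels)]])
    return labels[starts], ends - starts


def _canonical(path: IdealizedPath) -> np.ndarray:
    if path.canonical_labels is None:
        raise ValueError(f"{path.molecule_id}: path has no canonical labels; "
                         "run map_to_canonical first")
    return path.canonical_labels


def build_todp(paths: list[IdealizedPath], bin_width: float = 0.02) -> TODP:
    """Per-molecule-weighted transition occupancy density plot.

    For each molecule, every distinct (from-label, to-label) transition
    that occurs at least once adds ``1/n_molecules`` at the coordinates
    given by the molecule's mean idealized E within the two labels
    (at-least-once semantics: repeats do not add mass).  Static molecules
    add ``1/n_molecules`` on the diagonal at their mean idealized E.
    """
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    matrix = np.zeros((n_bins, n_bins))
    n_mol = len(paths)
    if n_mol == 0:
        raise ValueError("no paths given")
    out = TODP(bin_edges=edges, matrix=matrix, n_molecules=n_mol)
    to_bin = out.bin_index

    for path in paths:
        labels = _canonical(path)
        mean_e = {
            lab: float(path.idealized_efret[labels == lab].mean())
            for lab in np.unique(labels)
        }
        run_labels, _ = _label_runs(labels)
        if len(run_labels) == 1:
            b = to_bin(mean_e[run_labels[0]])
            matrix[b, b] += 1.0 / n_mol
            continue
        seen = set(zip(run_labels[:-1], run_labels[1:]))
        for frm, to in seen:
            matrix[to_bin(mean_e[frm]), to_bin(mean_e[to])] += 1.0 / n_mol
    return out


def classify_static(path: IdealizedPath, high_threshold: float = 0.7) -> str:
    """Classify one molecule as ``static_high``, ``static_other`` or ``dynamic``.

    Static means zero canonical-label changes over the analyzed window;
    static_high additionally requires a mean idealized E at or above
    ``high_threshold``.
    """
    labels = _canonical(path)
    if np.any(np.diff(labels) != 0):
        return "dynamic"
    if float(path.idealized_efret.mean()) >= high_threshold:
        return "static_high"
    return "static_other"


def static_fraction(
    paths: list[IdealizedPath],
    high_threshold: float = 0.7,
    min_frames: int = 100,
) -> dict:
    """Fractions of static molecules over traces long enough to judge.

    Traces shorter than ``min_frames`` cannot distinguish slow dynamics
    from true stasis and are excluded from the denominator.
    """
    eligible = [p for p in paths if len(p) >= min_frames]
    if not eligible:
        raise ValueError(f"no paths with >= {min_frames} frames")
    classes = [classify_static(p, high_threshold) for p in eligible]
    n = len(eligible)
    return {
        "n_eligible": n,
        "static_high": classes.count("static_high") / n,
        "static_other": classes.count("static_other") / n,
        "dynamic": classes.count("dynamic") / n,
    }


def extract_dwells(
    paths: list[IdealizedPath],
    transition: tuple[str, str],
) -> DwellSet:
    """Collect dwell times for one canonical transition across molecules.

    A dwell is the duration of a sojourn in ``from`` that ends in an
    observed switch to ``to``; durations are (frame count) x (frame
    period), counting valid frames only.  The first and last sojourns of
    every trace are censored: firsts are dropped, lasts are kept as
    exposure-only observations for the censored rate MLE, as are interior
    sojourns exiting to a third state.
    """
    frm, to = transition
    i_from = CANONICAL_LABELS.index(frm)
    i_to = CANONICAL_LABELS.index(to)
    dwells, censored, other = [], [], []
    dt = None
    for path in paths:
        dt = 1.0 / path.frame_rate
        labels = _canonical(path)
        run_labels, run_lengths = _label_runs(labels)
        n_runs = len(run_labels)
        if n_runs < 2:
            continue  # single sojourn: both first and last, excluded
        for r in range(1, n_runs):
            if run_labels[r] != i_from:
                continue
            duration = run_lengths[r] * dt
            if r == n_runs - 1:
                censored.append(duration)
            elif run_labels[r + 1] == i_to:
                dwells.append(duration)
            else:
                other.append(duration)
    return DwellSet(
        transition_label=(frm, to),
        dwells=np.asarray(dwells, float),
        frame_period=dt if dt is not None else np.nan,
        censored_durations=np.asarray(censored, float),
        other_exit_durations=np.asarray(other, float),
    )


def estimate_rate(ds: DwellSet, method: str = "exposure", min_dwells: int = 20) -> RateEstimate:
    """Exponential rate constant from a dwell set.

    ``method="exposure"`` (default) is the right-censored MLE
    k = n_events / total exposure (see module docstring); on uncensored
    data it equals 1/mean.  ``method="interior"`` is the reciprocal mean of
    interior dwells with a discretization correction
    k = -ln(1 - 1/mean_frames) / dt applied when the mean dwell is shorter
    than 10 frames.  The standard error is k / sqrt(n_events).
    """
    n = len(ds.dwells)
    if n < min_dwells:
        raise ValueError(f"too few dwells for {ds.transition_label}: {n} < {min_dwells}")
    if method == "exposure":
        exposure = ds.dwells.sum() + ds.censored_durations.sum() + ds.other_exit_durations.sum()
        k = n / exposure
    elif method == "interior":
        mean = ds.dwells.mean()
        mean_frames = mean / ds.frame_period
        if mean_frames < 10:
            k = -np.log(1.0 - 1.0 / mean_frames) / ds.frame_period
        else:
            k = 1.0 / mean
    else:
        raise ValueError(f"unknown method {method!r}")
    return RateEstimate(k=float(k), se=float(k / np.sqrt(n)), n_dwells=n, method=method)


def _hill(c, f0, f_inf, kd, n):
    return f0 + (f_inf - f0) * c**n / (kd**n + c**n)


def fit_hill(
    concentrations: np.ndarray,
    fractions: np.ndarray,
    fix_n: float | None = None,
) -> TitrationFit:
    """Least-squares Hill fit of a state fraction versus concentration.

    f(c) = f0 + (f_inf - f0) * c^n / (Kd^n + c^n), with f0 and f_inf in
    [0, 1], n in [0.5, 4] (optionally fixed), and Kd > 0.  Multi-start over
    Kd decades {0.01, 0.1, 1} mM; the best-residual solution is returned.
    Degenerate (flat) data leaves Kd at a bound and flags the result.
    """
    from lmfit import Model

    c = np.asarray(concentrations, float)
    f = np.asarray(fractions, float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentration points")
    if not np.any(c == 0):
        raise ValueError("titration must include a zero-concentration point")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")

    model = Model(_hill, independent_vars=["c"])
    kd_lo, kd_hi = 1e-4, 1e3
    best = None
    for kd0 in (0.01, 0.1, 1.0):
        params = model.make_params(
            f0=dict(value=float(f[np.argmin(c)]), min=0.0, max=1.0),
            f_inf=dict(value=float(f[np.argmax(c)]), min=0.0, max=1.0),
            kd=dict(value=kd0, min=kd_lo, max=kd_hi),
            n=dict(value=fix_n if fix_n is not None else 1.0, min=0.5, max=4.0,
                   vary=fix_n is None),
        )
        res = model.fit(f, params, c=c)
        if best is None or res.chisqr < best.chisqr:
            best = res
    kd = float(best.params["kd"].value)
    amplitude = abs(best.params["f_inf"].value - best.params["f0"].value)
    # Kd is unidentifiable when the curve is flat or Kd ran to a bound
    at_bound = kd <= kd_lo * 1.01 or kd >= kd_hi * 0.99 or amplitude < 1e-3
    return TitrationFit(
        kd=kd,
        hill_n=float(best.params["n"].value),
        f0=float(best.params["f0"].value),
        f_inf=float(best.params["f_inf"].value),
        residual_norm=float(np.sqrt(best.chisqr)),
        at_bound=at_bound,
    )


def efret_to_distance(e: float, r0: float = 55.0) -> DistanceEstimate:
    """Donor–acceptor distance from the Förster relation.

    E = 1 / (1 + (R/R0)^6), inverted to R = R0 * (1/E - 1)^(1/6).  Defined
    only for E strictly inside (0, 1); at E = 0.5, R = R0.
    """
    if not 0.0 < e < 1.0:
        raise ValueError(f"distance undefined for E={e}; need 0 < E < 1")
    return DistanceEstimate(r=float(r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)), r0=r0)
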
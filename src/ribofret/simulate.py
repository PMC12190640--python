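"""Synthetic two-channel smFRET trace generation.

Molecules interconvert between conformational states following a
continuous-time Markov chain (CTMC).  The continuous state path is sampled
by the Gillespie algorithm, integrated over camera frames (a transition in
mid-frame produces a fractionally averaged FRET efficiency, as real EMCCD
frames do), converted to donor/acceptor intensities, and finally subjected
to Gaussian channel noise and single-step photobleaching of each
fluorophore.

The emission model is deliberately simple: the summed intensity is constant
(detection factor gamma = 1), noise is additive Gaussian per channel plus a
per-state Gaussian spread of the FRET efficiency itself, and there is no
spectral crosstalk, shot noise, or blinking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Trace, TraceSet

__all__ = [
    "EmissionModel",
    "RateMatrix",
    "ConditionFixture",
    "GroundTruth",
    "build_generator",
    "simulate_state_path",
    "discretize_path",
    "emit_trace",
    "apply_photobleach",
    "simulate_molecule",
    "generate_dataset",
    "generate_titration",
    "hill_fraction",
]


@dataclass(frozen=True)
class EmissionModel:
    """Maps conformational states to observed channel intensities.

    Attributes
    ----------
    state_centers:
        Mean FRET efficiency of each state, strictly increasing, in [0, 1].
    state_sigma:
        Per-state Gaussian standard deviation of the *observed* FRET
        efficiency (conformational breadth), dimensionless.
    total_intensity:
        Mean summed donor + acceptor intensity, counts/frame.
    intensity_sigma:
        Additive Gaussian detection noise per channel, counts/frame.
    background:
        Mean background level per channel after bleaching, counts/frame.
    """

    state_centers: tuple[float, ...]
    state_sigma: tuple[float, ...]
    total_intensity: float = 1000.0
    intensity_sigma: float = 40.0
    background: float = 0.0

    def __post_init__(self) -> None:
        centers = np.asarray(self.state_centers, float)
        sigma = np.asarray(self.state_sigma, float)
        if sigma.ndim == 0:
            sigma = np.full(centers.shape, float(sigma))
            object.__setattr__(self, "state_sigma", tuple(sigma))
        if len(sigma) != len(centers):
            raise ValueError("state_sigma length must match state_centers")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("state_centers must be strictly increasing")
        if np.any(sigma < 0):
            raise ValueError("state_sigma must be >= 0")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")

    @property
    def n_states(self) -> int:
        return len(self.state_centers)


@dataclass(frozen=True)
class RateMatrix:
    """Generator matrix Q of a CTMC over conformational states.

    Off-diagonal entries ``q[i, j]`` are first-order rate constants (1/s)
    for the ``i -> j`` transition; each diagonal entry is minus the row sum
    of the off-diagonals, so rows sum to zero.
    """

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("q must be square")
        off = q - np.diag(np.diag(q))
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.any(np.abs(q.sum(axis=1)) > 1e-9 * max(1.0, np.abs(q).max())):
            raise ValueError("rows of a generator must sum to 0")
        object.__setattr__(self, "q", q)

    @property
    def n_states(self) -> int:
        return self.q.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution pi solving pi Q = 0, sum(pi) = 1."""
        n = self.n_states
        a = np.vstack([self.q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        if np.any(pi < -1e-9):
            raise ValueError("no non-negative stationary distribution")
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass(frozen=True)
class ConditionFixture:
    """Named simulation ground truth for one experimental condition.

    Exactly one of ``occupancies`` (stationary fractions, turned into a
    nearest-neighbour generator at ``exchange_timescale``) or ``rates`` (an
    explicit generator) drives the dynamic pool.  A ``static_fraction`` of
    molecules is simulated with zero exchange in ``static_state``.
    """

    name: str
    emission: EmissionModel
    occupancies: tuple[float, ...] | None = None
    exchange_timescale: float = 5.0
    rates: RateMatrix | None = None
    static_fraction: float = 0.0
    static_state: int = -1
    frame_rate: float = 10.0
    duration: float = 100.0
    donor_lifetime: float = 80.0
    acceptor_lifetime: float = 80.0
    mg_mM: float | None = None
    sam_mM: float | None = None

    def __post_init__(self) -> None:
        if (self.occupancies is None) == (self.rates is None):
            raise ValueError("exactly one of occupancies or rates must be set")
        if self.occupancies is not None:
            occ = np.asarray(self.occupancies, float)
            if abs(occ.sum() - 1.0) > 1e-9:
                raise ValueError("occupancies must sum to 1")
        if not 0.0 <= self.static_fraction <= 1.0:
            raise ValueError("static_fraction must be in [0, 1]")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be > 0")

    def rate_matrix(self) -> RateMatrix:
        if self.rates is not None:
            return self.rates
        return build_generator(self.occupancies, self.exchange_timescale)


@dataclass
class GroundTruth:
    """Per-molecule true paths and bleach times for a simulated dataset."""

    fixture: str
    seed: int
    molecules: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fixture": self.fixture,
            "seed": self.seed,
            "molecules": self.molecules,
        }


def build_generator(occupancies, exchange_timescale: float) -> RateMatrix:
    """Nearest-neighbour CTMC generator with a prescribed stationary law.

    Builds a reversible birth–death chain (only adjacent states exchange,
    reflecting a sequential folding pathway) whose stationary distribution
    equals ``occupancies``.  Detailed balance with exchange flux
    ``w_i = c * sqrt(pi_i * pi_{i+1})`` on each adjacent pair gives
    ``q[i, i+1] = w_i / pi_i`` and ``q[i+1, i] = w_i / pi_{i+1}``; the
    geometric-mean flux keeps dwell times comparable across states instead
    of letting the most populated state become near-frozen.  ``c`` is
    scaled so the stationary transition frequency ``sum_i pi_i |q_ii|``
    equals ``1 / exchange_timescale``.
    """
    pi = np.asarray(occupancies, dtype=float)
    if pi.ndim != 1 or len(pi) < 2:
        raise ValueError("need at least two occupancies")
    if np.any(pi <= 0):
        raise ValueError("occupancies must all be > 0 (no empty states)")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancies must sum to 1 (got {pi.sum():.12g})")
    if exchange_timescale <= 0:
        raise ValueError("exchange_timescale must be > 0")
    n = len(pi)
    # stationary transition frequency is 2 * sum of pair fluxes
    w = np.sqrt(pi[:-1] * pi[1:])
    w *= 1.0 / (2.0 * w.sum() * exchange_timescale)
    q = np.zeros((n, n))
    for i in range(n - 1):
        q[i, i + 1] = w[i] / pi[i]
        q[i + 1, i] = w[i] / pi[i + 1]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(q)


def two_state_rates(k_fold: float, k_unfold: float) -> RateMatrix:
    """Two-state generator: state 0 --k_fold--> state 1 --k_unfold--> state 0."""
    if k_fold <= 0 or k_unfold <= 0:
        raise ValueError("rates must be > 0")
    return RateMatrix(np.array([[-k_fold, k_fold], [k_unfold, -k_unfold]]))


def simulate_state_path(
    rates: RateMatrix,
    duration: float,
    rng: np.random.Generator | int,
    initial_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie sample of the CTMC over ``[0, duration]``.

    Returns ``(change_points, states)`` where the path occupies
    ``states[k]`` on ``[change_points[k], change_points[k+1])`` and the last
    segment extends to ``duration``.  ``change_points[0]`` is 0.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    q = rates.q
    if initial_state is None:
        pi = rates.stationary_distribution()
        state = int(rng.choice(len(pi), p=pi))
    else:
        state = int(initial_state)
    t = 0.0
    times = [0.0]
    states = [state]
    while True:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            break  # absorbing: dwell covers the rest of the window
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = np.clip(q[state].copy(), 0.0, None)
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(len(probs), p=probs))
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=int)


def discretize_path(
    change_points: np.ndarray,
    states: np.ndarray,
    n_states: int,
    duration: float,
    frame_period: float,
) -> np.ndarray:
    """Fractional per-frame state occupancies from a continuous path.

    Models camera frame integration: a frame during which the molecule
    switches state carries the time-weighted mixture of both states.
    Returns an array of shape ``(n_frames, n_states)`` whose rows sum to 1.
    """
    if frame_period <= 0:
        raise ValueError("frame_period must be > 0")
    n_frames = int(round(duration / frame_period))
    occ = np.zeros((n_frames, n_states))
    if n_frames == 0:
        return occ
    bounds = np.append(change_points, duration)
    for k in range(len(states)):
        t0, t1 = bounds[k], min(bounds[k + 1], duration)
        if t1 <= t0:
            continue
        s = states[k]
        j0 = int(t0 / frame_period)
        j1 = int(t1 / frame_period)
        j0 = min(j0, n_frames - 1)
        if j1 >= n_frames:
            j1 = n_frames - 1
            t1 = duration
        if j0 == j1:
            occ[j0, s] += (t1 - t0) / frame_period
        else:
            occ[j0, s] += ((j0 + 1) * frame_period - t0) / frame_period
            occ[j1, s] += (t1 - j1 * frame_period) / frame_period
            if j1 > j0 + 1:
                occ[j0 + 1 : j1, s] += 1.0
    # guard against roundoff: renormalize rows
    row = occ.sum(axis=1)
    occ[row > 0] /= row[row > 0, None]
    return occ


def emit_trace(
    occupancies: np.ndarray,
    emission: EmissionModel,
    rng: np.random.Generator | int,
    molecule_id: str = "mol",
    frame_rate: float = 10.0,
) -> Trace:
    """Convert per-frame state occupancies into a noisy two-channel trace.

    The noiseless FRET efficiency of a frame is the occupancy-weighted mean
    of the state centers; ``state_sigma`` adds Gaussian spread in E-space
    and ``intensity_sigma`` adds independent Gaussian noise per channel.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    occ = np.asarray(occupancies, float)
    centers = np.asarray(emission.state_centers)
    sigma_e = np.asarray(emission.state_sigma)
    n_frames = occ.shape[0]
    e = occ @ centers
    frame_sigma = occ @ sigma_e
    if np.any(frame_sigma > 0):
        e = e + rng.normal(0.0, 1.0, n_frames) * frame_sigma
    total = emission.total_intensity
    acceptor = total * e
    donor = total * (1.0 - e)
    if emission.intensity_sigma > 0:
        acceptor = acceptor + rng.normal(0.0, emission.intensity_sigma, n_frames)
        donor = donor + rng.normal(0.0, emission.intensity_sigma, n_frames)
    acceptor = acceptor + emission.background
    donor = donor + emission.background
    time = np.arange(n_frames) / frame_rate
    return Trace(molecule_id, time, donor, acceptor, frame_rate)


def apply_photobleach(
    trace: Trace,
    donor_lifetime: float,
    acceptor_lifetime: float,
    emission: EmissionModel,
    rng: np.random.Generator | int,
) -> tuple[Trace, float, float]:
    """Impose single-step, irreversible photobleaching on each fluorophore.

    Bleach times are exponential with the given mean lifetimes (seconds;
    ``inf`` disables bleaching of that channel).  After the acceptor
    bleaches, FRET is lost: the acceptor falls to background and the donor
    rises to the full summed intensity.  After the donor bleaches, both
    channels fall to background (no excitation transfer remains).

    Returns ``(bleached trace, donor_bleach_s, acceptor_bleach_s)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t_d = rng.exponential(donor_lifetime) if np.isfinite(donor_lifetime) else np.inf
    t_a = rng.exponential(acceptor_lifetime) if np.isfinite(acceptor_lifetime) else np.inf
    donor = trace.donor.copy()
    acceptor = trace.acceptor.copy()
    n = len(trace)
    dt = 1.0 / trace.frame_rate
    sig = emission.intensity_sigma
    b_a = int(t_a / dt) if np.isfinite(t_a) else n
    b_d = int(t_d / dt) if np.isfinite(t_d) else n
    # acceptor-only window: acceptor dark, donor at full intensity
    lo, hi = min(b_a, n), min(b_d, n)
    if lo < hi:
        m = hi - lo
        acceptor[lo:hi] = emission.background
        donor[lo:hi] = emission.total_intensity + emission.background
        if sig > 0:
            acceptor[lo:hi] += rng.normal(0.0, sig, m)
            donor[lo:hi] += rng.normal(0.0, sig, m)
    if b_d < n:
        m = n - b_d
        donor[b_d:] = emission.background
        acceptor[b_d:] = emission.background
        if sig > 0:
            donor[b_d:] += rng.normal(0.0, sig, m)
            acceptor[b_d:] += rng.normal(0.0, sig, m)
    out = Trace(trace.molecule_id, trace.time.copy(), donor, acceptor, trace.frame_rate)
    return out, float(t_d), float(t_a)


def simulate_molecule(
    fixture: ConditionFixture,
    rng: np.random.Generator,
    molecule_id: str,
    static: bool = False,
) -> tuple[Trace, dict]:
    """Simulate one molecule under a condition fixture.

    Static molecules occupy ``fixture.static_state`` for the whole movie;
    dynamic molecules follow the fixture's CTMC.  Returns the bleached
    trace and its ground-truth record.
    """
    n_states = fixture.emission.n_states
    duration = fixture.duration
    if static:
        state = fixture.static_state % n_states
        change_points = np.array([0.0])
        states = np.array([state])
    else:
        change_points, states = simulate_state_path(fixture.rate_matrix(), duration, rng)
    occ = discretize_path(change_points, states, n_states, duration, 1.0 / fixture.frame_rate)
    trace = emit_trace(occ, fixture.emission, rng, molecule_id, fixture.frame_rate)
    trace, t_d, t_a = apply_photobleach(
        trace, fixture.donor_lifetime, fixture.acceptor_lifetime, fixture.emission, rng
    )
    truth = {
        "molecule_id": molecule_id,
        "static": bool(static),
        "change_points_s": [round(float(t), 6) for t in change_points],
        "states": [int(s) for s in states],
        "donor_bleach_s": None if not np.isfinite(t_d) else round(t_d, 6),
        "acceptor_bleach_s": None if not np.isfinite(t_a) else round(t_a, 6),
    }
    return trace, truth


def generate_dataset(
    fixture: ConditionFixture, n_molecules: int, seed: int
) -> tuple[TraceSet, GroundTruth]:
    """Simulate a full dataset of ``n_molecules`` under one condition.

    ``round(static_fraction * n)`` molecules (largest-remainder rounding
    over the two classes) are static; which positions they occupy is a
    seeded random permutation so file order carries no class information.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    ss = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    n_static = int(np.floor(fixture.static_fraction * n_molecules + 0.5))
    flags = np.zeros(n_molecules, dtype=bool)
    flags[:n_static] = True
    assign_rng.shuffle(flags)
    child_seeds = ss.spawn(n_molecules + 1)[1:]
    traces, truth = [], GroundTruth(fixture.name, seed)
    width = max(4, len(str(n_molecules - 1)))
    for i in range(n_molecules):
        rng = np.random.default_rng(child_seeds[i])
        mol_id = f"mol_{i:0{width}d}"
        trace, rec = simulate_molecule(fixture, rng, mol_id, static=bool(flags[i]))
        traces.append(trace)
        truth.molecules.append(rec)
    manifest = {
        "fixture": fixture.name,
        "seed": seed,
        "frame_rate_hz": fixture.frame_rate,
        "duration_s": fixture.duration,
        "mg_mM": fixture.mg_mM,
        "sam_mM": fixture.sam_mM,
        "static_fraction": fixture.static_fraction,
        "occupancies": (
            None if fixture.occupancies is None
            else [float(o) for o in fixture.occupancies]
        ),
    }
    return TraceSet(traces, manifest), truth


def hill_fraction(c, f0: float, f_inf: float, kd: float, n: float = 1.0):
    """Hill saturation curve f(c) = f0 + (f_inf - f0) * c^n / (Kd^n + c^n)."""
    c = np.asarray(c, dtype=float)
    out = f0 + (f_inf - f0) * c**n / (kd**n + c**n)
    return out if out.ndim else float(out)


def generate_titration(
    concentrations,
    n_molecules: int,
    seed: int,
    f0: float = 0.186,
    f_inf: float = 0.596,
    kd: float = 0.06,
    hill_n: float = 1.0,
    apo_transit_ratio: tuple[float, float] = (0.597, 0.217),
    emission: EmissionModel | None = None,
    exchange_timescale: float = 5.0,
) -> list[tuple[float, TraceSet, GroundTruth]]:
    """Simulate one dataset per ligand concentration along a Hill curve.

    The high-FRET (holo) occupancy at concentration ``c`` follows the Hill
    fixture; the apo/transit states split the remaining occupancy in the
    fixed zero-ligand ratio.  Returns ``[(c_mM, TraceSet, GroundTruth), ...]``.
    """
    from .fixtures import DEFAULT_EMISSION  # local import avoids a cycle

    concentrations = list(concentrations)
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")
    emission = emission or DEFAULT_EMISSION
    r_apo, r_transit = apo_transit_ratio
    out = []
    for j, c in enumerate(concentrations):
        holo = hill_fraction(c, f0, f_inf, kd, hill_n)
        rest = 1.0 - holo
        apo = rest * r_apo / (r_apo + r_transit)
        transit = rest * r_transit / (r_apo + r_transit)
        fixture = ConditionFixture(
            name=f"titration_mg{c:g}mM",
            emission=emission,
            occupancies=(apo, transit, holo),
            exchange_timescale=exchange_timescale,
            mg_mM=c,
        )
        ts, gt = generate_dataset(fixture, n_molecules, (seed + 1000 * j) % (2**31 - 1))
        out.append((float(c), ts, gt))
    return out
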
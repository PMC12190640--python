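# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `ribofret`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Trace model

Each molecule is a continuous-time Markov chain (CTMC) over conformational
states with FRET-efficiency centers (0.2, 0.6, 0.8) for apo / transit /
holo (two-state kinetics conditions use 0.2 and 0.8 only). Paths are
sampled exactly by the Gillespie algorithm from a generator matrix Q and
integrated over camera frames: a frame during which the molecule switches
carries the time-weighted mixture of both states' signals, reproducing the
blurred-transition frames real EMCCD movies show. Acquisition defaults are
10 Hz for 100 s (1000 frames).

Emission is deliberately minimal. The noiseless frame efficiency is the
occupancy-weighted mean of state centers; a per-state Gaussian spread of E
itself (σ_E = 0.07) models conformational breadth, and independent
Gaussian noise (σ_I = 40 counts) is added per channel around a constant
summed intensity of 1000 counts (detection factor γ = 1, no crosstalk, no
shot noise, no blinking — an oxygen-scavenged, corrected-trace regime).
Because the E-spread enters donor and acceptor with opposite signs, even a
conformationally static molecule shows strongly anticorrelated channel
fluctuations (difference correlation ≈ −0.75); this is what the selection
screen keys on. Each fluorophore bleaches once, irreversibly, with
exponential lifetime 80 s per channel: after acceptor bleach the donor
rises to the full summed intensity, after donor bleach both channels fall
to background (default 0).

### Generator construction

`build_generator` builds a reversible nearest-neighbour chain
(apo ↔ transit ↔ holo; direct apo ↔ holo exchange is set to zero, matching
the sequential folding picture) whose stationary law equals the requested
occupancies. The free scale is fixed by an *exchange timescale* τ defined
through the stationary transition frequency, Σᵢ πᵢ|qᵢᵢ| = 1/τ. The
per-pair exchange flux is wᵢ = c·√(πᵢπᵢ₊₁): detailed balance then fixes
both rates of each pair, and the geometric-mean flux keeps dwell times
comparable across states (an equal-flux chain would make the most
populated state near-frozen). Occupancy fixtures use τ = 5 s.

### Condition fixtures

Published populations and published rate constants are mutually
inconsistent under any simple scheme (0.097/0.167 s⁻¹ implies a holo:apo
ratio of 0.58; the populations give 0.31), so two fixture families
coexist: `*_occupancy` (populations exact, rates constructed at τ = 5 s)
and `*_kinetics` (two-state, printed rates verbatim). The static-fraction
conditions (`mg005mM`, `mg2mM`, `mg10mM`, `mg2mM_SAM`, `mg10mM_SAM`) pin
only the static holo fraction; their dynamic pool uses the Mg-saturated
populations at τ = 1.5 s, fast enough that a dynamic molecule shows at
least one transition in every eligible window, including the shortest
(10 s) ones — measured pseudo-static misclassification is ≤ ~1%, so the
static/dynamic distinction these fixtures test is a property of the
molecule, not of the observation length. (Because eligible windows run
from 10 s to 100 s, a slower pool — 3–5 s exchange — leaves the
longest-dwelling state indistinguishable from stasis in a few percent of
short windows.) Static
molecules are a distinct subpopulation with zero exchange, not a slowed
dynamic pool. The titration family places the holo occupancy on
f(c) = f0 + (f∞ − f0)·c/(Kd + c) with f0 = 0.186, f∞ = 0.596,
Kd = 0.06 mM and Hill coefficient 1 (n = 1 is a modeling choice; only "a
Hill fit" is reported for the original data), with apo/transit splitting
the remainder 59.7 : 21.7.

## Preprocessing

Donor bleaching is located as the single change point of the summed
intensity minimizing the two-segment sum of squares (equivalently,
maximizing the Gaussian mean-shift likelihood), accepted only if the
post-step mean falls below 0.5× the pre-step mean. With γ = 1 the summed
intensity is *conserved* under acceptor-only bleaching, so acceptor
bleaching is detected separately as a terminal run (≥ 3 frames) of
5-frame-median-filtered acceptor signal below 10% of the median total —
safely below the lowest-FRET state, which keeps the acceptor near 20%.
Traces are truncated at the earlier event; only the first bleach is used.
When a donor-bleach segment exists, its per-channel medians are subtracted
as background (both channels are dark only there).

Selection accepts a trace if the pre-bleach segment has ≥ 50 frames (5 s)
and the Pearson correlation of frame-to-frame donor vs acceptor changes is
≤ 0.0 — static and dynamic molecules both sit well below zero under the
emission model above, while positively correlated artifacts fail. Both
thresholds are configurable; they are explicit stand-ins for the manual
screening such studies describe.

## HMM idealization

E = I_A/(I_A + I_D) is computed per frame, clamped to [−0.2, 1.2]; frames
whose summed intensity falls below 5% of the trace median are excluded and
the path treated as contiguous across them. Each trace is fitted
independently with a Gaussian-emission HMM by Baum–Welch EM (scaled
forward–backward, numba kernels): variance floor 1e-4, convergence when
the log-likelihood improves by < 1e-6, cap 500 iterations. The
log-likelihood is non-decreasing by construction and asserted in tests.

State number is selected by BIC = −2 logL + p log T with p = K² + 2K − 1
over K = 1…4. For each K, five starts are run: means at the (2i+1)/2K
quantiles, means equispaced over the observed E range, and three
quantile starts jittered with fixed seeds {1, 2, 3} (σ = 0.1). The spread
start matters: with ~70% of frames in one state, quantile placement seeds
every low mean inside the dominant cluster and EM reliably converges to a
local optimum that misses a minority state; with it, K = 3 is selected on
30/30 simulated three-state traces. Viterbi decoding (ties toward the
lower state index) yields the idealized path.

Fitted states are then mapped to the nearest canonical center (ties to the
lower center); distinct HMM states landing on one label merge, erasing
within-peak pseudo-transitions. Finally, one-frame sojourns in the
canonical sequence are folded into the following dwell: a mid-frame
transition produces exactly one frame of averaged signal, which the HMM
assigns either to an intermediate state (a phantom one-frame visit that
steals the true transition's identity) or to the far state (a phantom
there-and-back flicker). Left in place, these artifacts bias recovered
rate constants by −13% to +35% depending on the dwell/frame ratio; with
the cleanup, recovery is within ~5%. The cost is erasing the ~2–4% of
genuine sojourns shorter than one frame — below the instrument's time
resolution in any case.

## Ensemble statistics

**Populations.** Idealized E values of all accepted molecules are pooled
frame-weighted (bin width 0.02) and fitted with a three-component Gaussian
mixture (scikit-learn, initialized at the canonical centers, deterministic);
component weights are the reported fractions. Inputs above 200k frames are
subsampled with a fixed seed (weight SE at that size ≪ 1 pp).

**TODP.** For every molecule, each distinct (initial label → final label)
transition observed at least once adds 1/N at the molecule's mean
idealized E of the two labels; molecules with zero transitions add 1/N on
the diagonal. Coordinates use per-molecule fitted means, so the map shows
the natural spread around the canonical centers. Bin width 0.02 on [0, 1];
values sitting numerically on a bin edge go to the upper bin.

**Static fractions.** A molecule is static iff its canonical label never
changes over the accepted window; static-high additionally requires mean
idealized E ≥ 0.7. Only traces with ≥ 100 frames enter the statistic —
shorter windows cannot distinguish slow dynamics from stasis.

**Rate constants.** Dwells are read off the canonical label sequence
(durations = frame count × frame period, valid frames only). Because
photobleaching truncates observation (~40 s mean usable window against
6–30 s dwells), fully observed dwells are a length-biased sample: their
reciprocal mean overestimates rates by 16–29% at the study's conditions
(Monte-Carlo, 5000 molecules). The default estimator is therefore the
standard right-censored exponential MLE,
k(from→to) = N(from→to events) / T(total time in *from*), where each
trace's first sojourn is dropped entirely (its start is unobserved), its
final sojourn contributes exposure but no event, and interior sojourns
exiting to a third state contribute exposure for this transition and an
event for their own. On fully observed dwell sets this reduces exactly to
1/mean. SE = k/√N. The literal interior-dwell estimator (with a
−ln(1 − 1/m̄)/Δt discretization correction when the mean dwell is under 10
frames) is kept as `method="interior"` for histogram-fit parity.

**Titration.** The holo fraction (weight of the highest-mean mixture
component) per concentration is fitted with
f(c) = f0 + (f∞ − f0)cⁿ/(Kdⁿ + cⁿ) by bounded least squares (lmfit),
multi-started over Kd ∈ {0.01, 0.1, 1} mM, f0, f∞ ∈ [0, 1], n ∈ [0.5, 4]
and fixed to 1 where stated. Noiseless data are inverted to 1e-6. Fits
with Kd at a bound or amplitude < 1e-3 are flagged unidentifiable.

**Distances.** The printed form of the efficiency–distance relation is
implemented with the standard sixth power, E = 1/(1 + (R/R₀)⁶), R₀ = 55 Å;
both forms agree at E(R₀) = 0.5 but only the sixth-power form has the
physical curvature. Defined for E strictly inside (0, 1).

## Reproducibility and problem sizes

A single dataset seed drives everything: per-molecule generators are
spawned from it (`numpy` SeedSequence), HMM restarts use fixed seeds, the
mixture fit is deterministic, and identical seeds yield byte-identical
trace files and result JSON. The study-scale checks use 574 molecules for
populations, centers and static fractions, 500 per kinetics condition, and
8 × 300 for the titration; unit and example scripts use 10–150 molecules.
At these sizes the whole test suite runs in ~12 minutes on one CPU.

## What the synthetic tests do not show

The generator reproduces the statistical structure the analysis relies on
— Markovian exchange, Gaussian noise around well-separated centers,
single-step bleaching — but not spectral crosstalk, γ ≠ 1 detection
imbalance, shot noise, dye blinking, baseline drift, or non-Markovian
(e.g. heterogeneous-rate) dynamics. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to instrument pathologies; the anticorrelation screen in
particular leans on the per-state E spread dominating channel noise.
Static molecules are simulated as a discrete subpopulation, so the static
fraction is a well-defined ground truth; on real data the static/dynamic
boundary depends on the observation window, and the ≥ 100-frame
eligibility cut is the corresponding analysis convention.
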
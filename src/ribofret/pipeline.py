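"""End-to-end orchestration: simulate -> select -> idealize -> analyze.

Every stage logs its input/output molecule counts so attrition is
auditable, and a single seed drives all randomness (per-molecule seeds are
derived from it), making whole runs reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fixtures as fx
from .hmm import IdealizedPath, compute_efret, map_to_canonical, select_model, viterbi
from .io import TraceSet, load_dataset, write_dataset
from .preprocess import SelectionReport, select_traces, write_selection_report
from .simulate import generate_dataset, generate_titration
from .stats import (
    GaussianMixtureFit,
    build_todp,
    estimate_rate,
    extract_dwells,
    fit_hill,
    fit_population_mixture,
    pooled_histogram,
    static_fraction,
)

__all__ = [
    "AnalysisResult",
    "analyze_traceset",
    "run_simulate",
    "run_analyze",
    "run_titration",
]

log = logging.getLogger("ribofret")

#: ordered canonical transition pairs for which rates are attempted
RATE_TRANSITIONS = [
    ("apo", "transit"), ("transit", "apo"),
    ("transit", "holo"), ("holo", "transit"),
    ("apo", "holo"), ("holo", "apo"),
]


@dataclass
class AnalysisResult:
    """Bundle of everything one dataset analysis produces."""

    n_input: int
    n_accepted: int
    reports: list[SelectionReport]
    paths: list[IdealizedPath]
    models: list = field(default_factory=list)
    mixture: GaussianMixtureFit = None
    histogram: tuple[np.ndarray, np.ndarray] = None
    todp: object = None
    static: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)

    @property
    def holo_fraction(self) -> float:
        """Weight of the highest-mean mixture component."""
        return float(self.mixture.weights[-1])

    @property
    def apo_fraction(self) -> float:
        """Weight of the lowest-mean mixture component."""
        return float(self.mixture.weights[0])

    def to_dict(self) -> dict:
        out = {
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            "mixture": {
                "weights": [float(w) for w in self.mixture.weights],
                "means": [float(m) for m in self.mixture.means],
                "sigmas": [float(s) for s in self.mixture.sigmas],
                "converged": self.mixture.converged,
            },
            "static": {k: (float(v) if isinstance(v, float) else v)
                       for k, v in self.static.items()},
            "rates": {
                f"{frm}->{to}": {
                    "k_per_s": float(r.k),
                    "se_per_s": float(r.se),
                    "n_dwells": int(r.n_dwells),
                    "method": r.method,
                }
                for (frm, to), r in self.rates.items()
            },
        }
        return out


def analyze_traceset(
    ts: TraceSet,
    min_length: int = 50,
    max_anticorr: float = 0.0,
    k_max: int = 4,
    high_threshold: float = 0.7,
    static_min_frames: int = 100,
    bin_width: float = 0.02,
    rate_method: str = "exposure",
    min_dwells: int = 20,
    mixture_init: tuple[float, ...] = fx.STATE_CENTERS,
) -> AnalysisResult:
    """Run the full analysis on an in-memory trace set.

    Stages: photobleach/anticorrelation selection, per-trace FRET
    efficiency, per-trace HMM idealization with BIC state-number
    selection, canonical state mapping, then ensemble statistics
    (pooled histogram, 3-Gaussian populations, TODP, static fractions,
    dwell-time rate constants for every transition with enough events).
    """
    selected, reports = select_traces(ts, min_length=min_length, max_anticorr=max_anticorr)
    log.info("selection: %d/%d traces accepted", len(selected), len(ts))
    paths, models = [], []
    for trace in selected:
        ft = compute_efret(trace)
        model = select_model(ft, k_max=k_max)
        models.append(model)
        paths.append(map_to_canonical(viterbi(model, ft)))
    if not paths:
        raise ValueError("zero accepted traces; selection report: "
                         + ", ".join(f"{r.molecule_id}:{r.reject_reason}" for r in reports[:10]))
    log.info("idealized %d traces", len(paths))
    hist = pooled_histogram(paths, bin_width=bin_width)
    mixture = fit_population_mixture(
        np.concatenate([p.idealized_efret for p in paths]), init_means=mixture_init
    )
    todp = build_todp(paths, bin_width=bin_width)
    static = static_fraction(paths, high_threshold=high_threshold, min_frames=static_min_frames)
    rates = {}
    for frm, to in RATE_TRANSITIONS:
        ds = extract_dwells(paths, (frm, to))
        if len(ds) >= min_dwells:
            rates[(frm, to)] = estimate_rate(ds, method=rate_method, min_dwells=min_dwells)
    log.info("rates estimated for %d transitions", len(rates))
    return AnalysisResult(
        n_input=len(ts),
        n_accepted=len(selected),
        reports=reports,
        paths=paths,
        models=models,
        mixture=mixture,
        histogram=hist,
        todp=todp,
        static=static,
        rates=rates,
    )


def run_simulate(
    fixture_name: str,
    n_molecules: int,
    seed: int,
    out_dir: str | Path,
    force: bool = False,
) -> Path:
    """Simulate a dataset under a named fixture and write it to disk."""
    fixture = fx.get_fixture(fixture_name)
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    ts, truth = generate_dataset(fixture, n_molecules, seed)
    manifest_path = write_dataset(ts, out_dir, ground_truth=truth.to_dict())
    log.info("wrote %d traces to %s", len(ts), out_dir)
    return manifest_path


def _write_idealized(paths: list[IdealizedPath], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tframe\tefret\tstate\tidealized_efret\tcanonical_label\n")
        for p in paths:
            labels = p.canonical_labels
            for i in range(len(p)):
                lab = fx.CANONICAL_LABELS[labels[i]] if labels is not None else ""
                e = p.efret[i] if p.efret is not None else float("nan")
                fh.write(
                    f"{p.molecule_id}\t{i}\t{e:.4f}\t{p.states[i]}"
                    f"\t{p.idealized_efret[i]:.4f}\t{lab}\n"
                )


def run_analyze(
    dataset_path: str | Path,
    out_dir: str | Path,
    plots: bool = True,
    **options,
) -> AnalysisResult:
    """Analyze a dataset on disk and write the results bundle.

    Writes ``selection.tsv``, ``idealized.tsv``, ``results.json`` and
    (optionally) figures into ``out_dir``.
    """
    dataset_path = Path(dataset_path)
    manifest = dataset_path if dataset_path.is_file() else dataset_path / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest at {manifest}")
    ts = load_dataset(manifest)
    result = analyze_traceset(ts, **options)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_selection_report(result.reports, out_dir / "selection.tsv")
    _write_idealized(result.paths, out_dir / "idealized.tsv")
    models = {
        p.molecule_id: {
            "n_states": int(m.n_states),
            "means": [round(float(v), 6) for v in m.means],
            "variances": [round(float(v), 8) for v in m.variances],
            "transition_matrix": [
                [round(float(v), 6) for v in row] for row in m.transition_matrix
            ],
            "bic": round(float(m.bic), 4),
        }
        for p, m in zip(result.paths, result.models)
    }
    with open(out_dir / "models.json", "w") as fh:
        json.dump(models, fh, indent=1, sort_keys=True)
    with open(out_dir / "results.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
    np.savetxt(out_dir / "todp.tsv", result.todp.matrix, fmt="%.6f", delimiter="\t")
    if plots:
        from . import plots as plotmod

        plotmod.plot_histogram_with_mixture(
            result.histogram, result.mixture, out_dir / "histogram.png"
        )
        plotmod.plot_todp(result.todp, out_dir / "todp.png")
    return result


def run_titration(
    concentrations=fx.TITRATION_CONCENTRATIONS_MM,
    n_molecules: int = 300,
    seed: int = 7,
    out_dir: str | Path | None = None,
    fix_n: float | None = 1.0,
    **options,
) -> dict:
    """Simulate and analyze a ligand titration; Hill-fit the holo fraction.

    One dataset is generated and analyzed per concentration; the weight of
    the highest-E mixture component is the holo fraction entering the Hill
    fit.  Returns a dict with the per-concentration fractions and the fit.
    """
    concentrations = list(concentrations)
    if len(concentrations) < 4:
        raise ValueError("need at least 4 concentrations for a titration")
    series = generate_titration(concentrations, n_molecules, seed)
    fracs = []
    for c, ts, _truth in series:
        res = analyze_traceset(ts, **options)
        fracs.append(res.holo_fraction)
        log.info("c=%g mM: holo fraction %.3f (%d traces)", c, fracs[-1], res.n_accepted)
    fit = fit_hill(np.asarray(concentrations), np.asarray(fracs), fix_n=fix_n)
    out = {
        "concentrations_mM": [float(c) for c in concentrations],
        "holo_fractions": [float(f) for f in fracs],
        "hill_fit": {
            "kd_mM": fit.kd,
            "hill_n": fit.hill_n,
            "f0": fit.f0,
            "f_inf": fit.f_inf,
            "residual_norm": fit.residual_norm,
            "at_bound": fit.at_bound,
        },
        "n_molecules_per_point": n_molecules,
        "seed": seed,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "titration.json", "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)
    return out
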
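"""Idealize one trace with the Gaussian-emission HMM.

Builds a two-state trace (E 0.2 <-> 0.8), screens it, computes E_FRET,
selects the number of states by BIC, decodes the Viterbi path, and prints
the fitted state means next to the truth.  The fitted means should land
within a few hundredths of 0.2 and 0.8, and the transition count should be
close to the true number of state changes.
"""

import numpy as np

import ribofret as rf

fixture = rf.get_fixture("noMg_kinetics")  # k_fold 0.097 /s, k_unfold 0.167 /s
ts, truth = rf.generate_dataset(fixture, n_molecules=1, seed=4)
selected, reports = rf.select_traces(ts)
trace = selected.traces[0]
print(f"selection: accepted={reports[0].accepted}, "
      f"bleach_frame={reports[0].bleach_frame}, "
      f"anticorrelation={reports[0].anticorrelation:.2f}")

ft = rf.compute_efret(trace)
model = rf.select_model(ft)
path = rf.map_to_canonical(rf.viterbi(model, ft))

print(f"BIC selected K={model.n_states} states "
      f"(logL={model.log_likelihood:.1f}, BIC={model.bic:.1f})")
print(f"fitted state means: {np.round(np.sort(model.means), 3)} (truth: 0.2, 0.8)")
print(f"idealized transitions: {path.n_transitions} "
      f"(true changes in full movie: {len(truth.molecules[0]['states']) - 1})")
print("Transitions can differ from truth because the movie is truncated at "
      "the first photobleach and sub-frame events are unresolvable.")
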
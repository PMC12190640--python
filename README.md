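# ribofret

Simulation and analysis of single-molecule FRET (smFRET) trajectories for
riboswitch conformational dynamics.

Ligand-sensing RNAs such as the SAM-VI riboswitch interconvert between an
unbound (*apo*), intermediate (*transit*) and ligand-competent (*holo*)
conformation. In a surface-immobilized smFRET experiment each molecule
carries a Cy3 donor and Cy5 acceptor, and its conformation is read out
frame by frame as the FRET efficiency

```
E = I_A / (I_A + I_D)
```

with the three conformations appearing at E ≈ 0.2, 0.6 and 0.8. `ribofret`
implements the complete trajectory-level workflow that turns raw
donor/acceptor intensity movies into the quantities such a study reports:

- **`ribofret.simulate` / `ribofret.fixtures`** — synthetic two-channel trace
  generation from a continuous-time Markov chain (Gillespie sampling, camera
  frame integration, Gaussian noise, single-step photobleaching), with named
  condition fixtures (state populations, rate constants, static fractions,
  a Mg²⁺ titration) so every downstream stage can be verified against known
  ground truth.
- **`ribofret.io`** — one-CSV-per-molecule trace files plus a JSON dataset
  manifest, validated strictly on read.
- **`ribofret.preprocess`** — photobleach detection (change point in the
  summed intensity; terminal background run in the acceptor channel) and
  trace selection by donor–acceptor anticorrelation.
- **`ribofret.hmm`** — per-trace idealization with a Gaussian-emission hidden
  Markov model fitted by Baum–Welch EM (numba-accelerated), state number
  chosen by BIC over K = 1…4, Viterbi decoding, and mapping of fitted states
  onto the canonical apo/transit/holo conformations.
- **`ribofret.stats`** — pooled E histograms and three-Gaussian population
  fractions, transition occupancy density plots (TODPs), static-trace
  classification, dwell-time rate constants by right-censored exponential
  MLE, Hill-equation titration fits (Kd), and Förster-relation distance
  conversion, `R = R₀ (1/E − 1)^{1/6}` with R₀ = 55 Å for Cy3/Cy5.
- **`ribofret.pipeline` / `ribofret.cli`** — orchestration of
  simulate → select → idealize → analyze as seeded, reproducible runs, plus
  a thin `ribofret` command-line interface (`simulate`, `analyze`,
  `titrate`, `report`).

## Worked example

`examples/` contains one short script per capability. For instance,
recovering conformational populations from a simulated 80-molecule cohort
(`python examples/03_population_fractions.py`) prints

```
accepted 69/80 traces
population fractions (truth 0.597 / 0.217 / 0.186):
  E ~ 0.20:  58.6 %   (sigma 0.005, dye separation ~69 A at R0 = 55 A)
  E ~ 0.60:  21.9 %   (sigma 0.008, dye separation ~51 A at R0 = 55 A)
  E ~ 0.80:  19.5 %   (sigma 0.010, dye separation ~44 A at R0 = 55 A)
```

Each line is one fitted mixture component: its mean FRET efficiency, the
fraction of pooled idealized frames it carries (the conformational
population), the component width, and the implied donor–acceptor distance.
Eleven of the 80 traces were rejected by the photobleach/anticorrelation
screen, mostly for bleaching too early. The other examples demonstrate
trace simulation (`01`), single-trace HMM idealization (`02`), dwell-time
rate constants (`04`), the Hill fit of the Mg²⁺ titration (`05`), and the
TODP with static-fraction counting (`06`).

The same workflow from the shell:

```bash
ribofret simulate --fixture noMg_occupancy --n 574 --seed 7 --out run/ds
ribofret analyze run/ds --out run/results
ribofret report run/results/results.json
```

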
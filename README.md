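# modnet

Spike-train analysis for **modular cultured neuronal networks** recorded on
microelectrode arrays (MEAs).

Engineered cultures grown in hydrogel micropatterns form small networks
("modules") of neurons over a handful of electrodes. When two modules become
connected by neurites, their population bursts start to synchronize; when the
connection is cut, or one module's firing is reversibly suppressed
(e.g. by photothermal neuromodulation), the division of labor between local
and global activity is exposed. `modnet` implements the electrophysiology
side of such experiments as a tested, reusable pipeline:

- **Spike detection** from band-pass-filtered extracellular traces at a
  −6 SD threshold (robust MAD noise estimate), with stimulation-artifact
  blanking.
- **Functional connectivity** from firing rates: 100 ms rate histograms,
  5-bin Gaussian smoothing, a > 0.05 Hz activity filter, Pearson correlation
  matrices, and intra-/inter-module correlation summaries (intra-CC /
  inter-CC).
- **Synchronized events**: per-electrode bursts (inter-spike gaps ≤ 200 ms),
  synchronized bursting events (SBEs: overlapping bursts on ≥ 2 electrodes,
  merged transitively), inter-network synchronized events (SEs: SBEs spanning
  ≥ 2 modules), per-electrode **association degree** (fraction of spikes
  inside SE windows) and **propagation direction** (modules ordered by first
  spike time within each SE).
- **Network-to-network influence** from suppression experiments: per-trial
  percent rate change against power density, and
  `I[A→B] = |percent change of B's baseline rate while A is fully
  suppressed|`, with exact two-sided Mann–Whitney tests against control
  electrodes.
- **Evoked-response mapping**: peri-stimulus time histograms and per-trial
  response probabilities in early (< 10 ms) and late (15–35 ms) windows.
- A **synthetic generator** of modular bursting networks — Poisson burst
  cascades with directed, delayed inter-module triggering, suppression
  epochs, evoked responses, and raw noisy traces — with full ground truth,
  so every stage is verifiable without access to recordings.

## Worked example

Generate a two-module network where module N2 drives N1 (every N1 burst is
triggered by N2; 60 % of N2's bursts are echoes driven back from N1), then
run the analyses:

```python
import numpy as np
from modnet import synth, rates, events, modulation as mo

cfg = synth.asymmetric_pair_config(seed=42, duration=600.0)
bundle = synth.generate_session(cfg)

summary = rates.cc_summary(rates.session_matrix(bundle.session), bundle.module_map)
print("intra-CC:", {m: round(v, 3) for m, v in summary.intra_per_module.items()})
print("inter-CC (N1-N2):", round(summary.inter_per_pair[("N1", "N2")], 3))

sbes, ses, assoc, labels = events.detect_session_events(bundle.session, bundle.module_map)
print("SBEs:", len(sbes), " SEs:", len(ses))
props = events.propagation_proportions(labels)
print("propagation:", {"->".join(k): round(v, 2) for k, v in sorted(props.items())})

epochs = synth.make_suppression_protocol("N2")
cfg2 = synth.asymmetric_pair_config(seed=42, duration=synth.protocol_duration(epochs))
bundle2 = synth.generate_session(cfg2, epochs)
curve = mo.suppression_curve(bundle2.session, epochs, bundle2.module_map)
entry = mo.influence(curve, "N1")
print(f"I[N2->N1] = {entry.influence:.0f}%  (source suppression {entry.source_suppression:.0f}%)")
```

Output:

```
intra-CC: {'N1': 0.943, 'N2': 0.939}
inter-CC (N1-N2): 0.918
SBEs: 358  SEs: 104
propagation: {'N1->N2': 0.06, 'N2->N1': 0.94}
I[N2->N1] = 98%  (source suppression -100%)
```

Both modules are internally synchronized (intra-CC ≈ 0.94) and globally
synchronized with each other (inter-CC ≈ 0.92). Nearly all SEs start in N2
(propagation N2→N1 in 94 % of events), and fully suppressing N2 abolishes
N1's activity (influence ≈ 100 %): the perturbation-based influence measure
and the spontaneous-activity analysis agree on the direction of dependence.

## Command line

Each stage is also exposed as a subcommand over the same library code:

```sh
modnet synth --seed 5 --duration 600 --out-dir fixtures/
modnet connectivity --spikes fixtures/spikes.csv --map fixtures/map.yaml --out cc.json
modnet events --spikes fixtures/spikes.csv --map fixtures/map.yaml --out events.json
modnet influence --spikes spikes.csv --map map.yaml --protocol protocol.yaml --out infl.json
modnet psth --spikes spikes.csv --map map.yaml --stims stims.yaml --out psth.json
modnet run --config analysis.yaml
```

Spike tables are CSV (`electrode_id,time_s` with `# key=value` metadata
lines) or HDF5; module maps and protocols are YAML/JSON; raw traces are
HDF5 (channels × samples, with a sampling-rate attribute).

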
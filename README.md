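# measeg

Segregation/integration analysis of compartmentalized neuronal cultures on
micro-electrode arrays (MEAs).

Cortical assemblies grown in four physically separated compartments on a
120-electrode MEA (a cross-shaped mask splits the culture into quadrants of
~15 electrodes each) let one study how *segregated* sub-populations become
*integrated* as connections form between them. `measeg` implements the
spike-train analysis chain used to quantify that balance:

1. **Spike detection** on raw 10 kHz traces with a per-electrode
   differential threshold (peak-to-peak excursion of a biphasic waveform
   above 8× the channel noise SD, 2 ms peak lifetime, 1 ms refractory).
2. **Burst detection** with the string method (≥ 5 spikes, inter-spike
   intervals ≤ 100 ms) and the firing statistics MFR (spikes/s), MBR
   (bursts/min), MFIB (spikes per burst duration) and RS (% spikes outside
   bursts), per electrode and per compartment (active = MFR > 0.1 spikes/s).
3. **Network-burst detection**: activity is binned at 25 ms and the per-bin
   product (active electrodes × spikes) thresholded at 5% of its recording
   maximum, with an 80 ms minimum inter-event interval; each event reports
   its duration (NBD), the involved compartments (≥ 3 electrodes firing),
   the initiating (leader) electrode/compartment and follower delays.
4. **Functional connectivity** with a total-spiking-probability-edges
   (TSPE) style cross-correlation estimator (1 ms bins, lags ≤ 25 ms,
   running-window contrast filters), followed by a propagation-speed filter
   (keep edges with distance/delay in 30–300 mm/s), a hard threshold
   `thCM = μ ± σ` over the non-zero weights, and *strong* connections
   (|w| > μ + σ). Graph readouts: in+out node degree, the
   distance-weighted clustering coefficient
   `CC_i = Σ_j (1/d_ij²) / (k_i(k_i−1)/2)` (d in mm, j over unique
   neighbours), intra- vs inter-compartment edge percentages, and the
   Bhattacharyya distance `BC = −ln Σ √(A·B)` between the length
   distributions of all vs inter-compartment connections.
5. A **synthetic-culture generator** that emulates these recordings —
   background Poisson firing, electrode bursts, network events that start
   in a leader compartment and recruit the others with probability
   `p_couple`, conduction delays in the physiological speed band, and
   optional lag-coupled electrode pairs — with full ground truth, so every
   stage is testable without recordings.

## Worked example

```python
import numpy as np
from measeg import (SynthConfig, grid_layout, generate_spike_trains,
                    run_pipeline, RunConfig)

layout = grid_layout()                      # 120 electrodes, 4 x 15 assigned
cfg = SynthConfig(duration_s=300.0, seed=7, p_couple=0.5)
trains, truth = generate_spike_trains(cfg, layout)
bundle = run_pipeline(trains, layout, RunConfig(recording_id="demo"))

print(bundle["firing_stats"].per_compartment.round(2))
m = bundle["metrics"]
nb = bundle["nb_table"]
print(len(nb), round(nb["NBD_s"].mean() * 1000))
print(m["pct_inter_strong"], m["mean_cc"], m["bhattacharyya"])
```

Output (5-minute recording at moderate coupling, seed 7):

```
             n_electrodes   MFR   MBR    MFIB     RS
compartment
C1                     15  1.02  4.32  120.86  46.13
C2                     15  1.24  5.76  124.08  39.74
C3                     15  1.13  5.12  125.07  43.07
C4                     15  1.18  5.44  124.32  41.58
```

Each compartment fires at ~1 spike/s with ~5 bursts/min; roughly 40–46% of
spikes fall outside bursts. The pipeline then finds **52 network bursts**
(mean NBD 82 ms); at `p_couple = 0.5` most involve 2–3 compartments
(involvement spectrum 1C/2C/3C/4C = 15.4/30.8/40.4/13.5%), and the leader
hierarchy (32.7/28.8/19.2/19.2%) stays near the uniform 25% reference, as
expected when every compartment may initiate. The thresholded connectivity
graph has 533 edges (mean degree 8.9, mean clustering coefficient 0.299),
of which 265 are strong; strong connections are predominantly
intra-compartment (76.2% vs 23.8% inter) — the network is only partially
integrated — and the Bhattacharyya distance between the total and
inter-compartment connection-length distributions is 0.198.

A command-line interface mirrors the stages:

```bash
measeg synth --config cfg.yaml --out rec/ --seed 3
measeg detect --raw rec.h5 --out spikes.csv
measeg bursts --spikes rec/spikes.csv --layout rec/layout.json --out stats.csv
measeg netbursts --spikes rec/spikes.csv --layout rec/layout.json --out nb.csv
measeg run --spikes rec/spikes.csv --layout rec/layout.json --out results/
```

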
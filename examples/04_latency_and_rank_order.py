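"""First-spike latency codes: filtering and rank-order decoding.

Builds spike-event tables for two stimuli whose responses differ mainly in
the relative timing of each neuron's first spike, reduces the spike trains
to first spikes only, and compares (a) space-by-time NMF decoding of the
full and first-spike-only responses with (b) a rank-order decoder that
classifies trials by correlating the neurons' latency ranks with
per-stimulus templates — a readout that needs no stimulus-onset reference.
"""

import numpy as np
import pandas as pd

from popfactor import (
    bin_spikes,
    decode_pipeline,
    first_spike_filter,
    rank_order_decode,
)

rng = np.random.default_rng(0)
n_neurons, n_trials = 8, 30
base = np.linspace(40.0, 150.0, n_neurons)
latency_by_stim = {"up": base, "down": base[::-1]}

rows = []
trial = 0
for stim, latencies in latency_by_stim.items():
    for _ in range(n_trials):
        for neuron, lat in enumerate(latencies):
            t = lat + rng.normal(0, 5.0)
            rows.append((trial, stim, neuron, float(np.clip(t, 0, 299))))
            # a couple of later spikes that carry no extra information
            for extra in rng.uniform(t + 20, 295, size=2):
                rows.append((trial, stim, neuron, float(extra)))
        trial += 1
events = pd.DataFrame(rows, columns=["trial", "stimulus", "neuron", "time_ms"])

full = bin_spikes(events, 10.0, (0.0, 300.0))
first_only = bin_spikes(first_spike_filter(events), 10.0, (0.0, 300.0))

acc_full = decode_pipeline(full, "sbt-nmf", (3, 3), n_train=15, seed=0).accuracy
acc_first = decode_pipeline(
    first_only, "sbt-nmf", (3, 3), n_train=15, seed=0
).accuracy
acc_rank = rank_order_decode(events, n_train=15, seed=0).accuracy

print(f"space-by-time NMF, full spike trains:      {acc_full:.1f}%")
print(f"space-by-time NMF, first spikes only:      {acc_first:.1f}%")
print(f"rank-order decoder (latency ranks):        {acc_rank:.1f}%")
print(
    "\nAll the stimulus information here sits in first-spike latencies: "
    "the later\nspikes are pure noise, so deleting them *improves* the "
    "module-based decoder,\nand the reference-free rank-order readout of "
    "the latency ranks is best of all."
)
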
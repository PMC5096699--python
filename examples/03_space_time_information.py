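"""Where does the information live: space, time, or both?

Three equal-area patterns define three stimuli: pattern 0 is unique in
both its neurons and its timing, pattern 1 shares its time course with
pattern 0 (so only *which neurons* fire distinguishes it: space-only
information), and pattern 2 shares its neurons with pattern 0 (so only
*when* they fire distinguishes it: time-only information).

Shuffling time bins within each trial destroys timing information
(space-only condition); shuffling neuron identities destroys spatial
information (time-only condition).  The report shows the full code is
nearly perfect, and each shuffle selectively removes the distinction that
lives in the destroyed dimension.
"""

from popfactor import (
    PresenceDesign,
    generate_trials,
    make_block_patterns,
    space_time_report,
)

patterns = make_block_patterns("info_type", foreground_rate=100.0)
design = PresenceDesign.conditions({f"pattern{k}": (k,) for k in range(3)})
trials = generate_trials(patterns, design, 20, seed=0)

report = space_time_report(
    trials, "sbt-nmf", (2, 2), n_train=10, seed=0,
    precision_groups=(2, 5, 30),
)
print(report.to_string(index=False))
print(
    "\naccuracy: % correct (chance 33.3%); delta: loss vs the unshuffled "
    "space-and-time code.\nprecision(k): bins shuffled within groups of k "
    "(k=30 destroys all order at 10 ms bins,\nreducing the effective "
    "temporal precision to 300 ms)."
)
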
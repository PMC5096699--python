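"""Decode simulated stimuli from single-trial activation coefficients.

Six stimulus conditions are built from the four overlap-level-1 blocks:
each condition activates exactly one unordered pair of blocks.  Modules
are fit on a training half of the trials only; test-trial coefficients
are inferred with the modules frozen and classified with multiclass LDA.

The module counts are then re-derived from the data by leave-one-out
cross-validation within the training set, showing that the selection
procedure finds the generating counts (2 temporal x 2 spatial for the
tensor model, 4 spatiotemporal modules for the matrix model).
"""

from popfactor import (
    PresenceDesign,
    decode_pipeline,
    generate_trials,
    make_block_patterns,
    pair_conditions,
    select_module_numbers,
    train_test_split,
)

patterns = make_block_patterns("overlap", overlap_level=1,
                               foreground_rate=100.0)
design = PresenceDesign.conditions(pair_conditions(4))
trials = generate_trials(patterns, design, 20, seed=0)
print(f"6 stimulus conditions, 20 trials each; chance level "
      f"{100 / 6:.1f}%")

for model, counts in [("sbt-nmf", (2, 2)), ("st-nmf", (4,)),
                      ("tucker2", (2, 2))]:
    result = decode_pipeline(trials, model, counts, n_train=10, seed=1)
    print(f"{model} {counts}: {result.accuracy:.1f}% correct on the test set")

train, _ = train_test_split(trials, 10, seed=1)
opts = {"n_restarts": 1, "max_iter": 200, "tol": 1e-4}
selected = select_module_numbers(train, "sbt-nmf", seed=1, fit_opts=opts)
print(f"\nleave-one-out selection (space-by-time NMF): {selected} "
      f"(generating counts: (2, 2))")
selected = select_module_numbers(train, "st-nmf", seed=1, fit_opts=opts)
print(f"leave-one-out selection (spatiotemporal NMF): {selected} "
      f"(generating count: (4,))")
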
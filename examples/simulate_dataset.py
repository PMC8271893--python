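"""Generate a synthetic Go/Nogo ERP dataset and write it to disk.

Builds elderly-group study-condition data (20 trials per sign shape,
75% "different" stimuli, reference error rates, incorrect-answer traces
with shifted component latencies and doubled fluctuation), then saves
the trial log as CSV and the epochs as an HDF5 bundle.
"""

from pathlib import Path

import erpsign as es

out = Path("scratch/example_output")
out.mkdir(parents=True, exist_ok=True)

configs = {("elderly", cond): es.default_config("elderly", cond)
           for cond in ("correct", "incorrect")}
bundle = es.make_dataset(configs, n_subjects=4, seed=11)

cfg_hash = es.io.config_hash({"n_subjects": 4, "seed": 11})
es.io.write_trial_log(bundle.trials, out / "trials.csv", seed=11,
                      cfg_hash=cfg_hash)
es.io.write_epoch_bundle(bundle, out / "epochs.h5", cfg_hash=cfg_hash)

n_incorrect = sum(not t.is_correct for t in bundle.trials)
print(f"subjects:          4")
print(f"trials generated:  {len(bundle.trials)} "
      f"({n_incorrect} incorrect, {n_incorrect / len(bundle.trials):.1%})")
print(f"epochs generated:  {len(bundle.epochs)} (one per trial, "
      f"{bundle.epochs[0].n_samples} samples each, -1 s to +2 s)")
print(f"written to:        {out}/trials.csv, {out}/epochs.h5")
# The error fraction tracks the per-shape reference rates (~21% for the
# elderly group); each epoch carries the N200/P300/N400/P600 complex.
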
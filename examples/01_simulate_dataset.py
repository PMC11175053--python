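"""Generate a synthetic collar-sensor dataset and write it as CSV.

Builds labeled/unlabeled/test pools of 2-s, 12-channel windows for the five
behaviors (stand, walk, sit, lying, eat), contaminates the unlabeled pool
with 30% inactive windows and 5% Bluetooth-style missing-value gaps, and
prints the resulting counts.
"""

from pathlib import Path

from cmpl.synthetic_data import StreamSpec, make_dataset, write_csv, write_manifest

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)

spec = StreamSpec(
    n_labeled_per_class=40,
    n_unlabeled=300,
    inactive_fraction=0.3,
    missing_rate=0.05,
    seed=1,
)
dataset = make_dataset(spec)

for name in ("labeled", "unlabeled", "test"):
    write_csv(getattr(dataset, name), out / f"{name}.csv")
write_manifest(dataset, spec, out / "manifest.json")

print(f"labeled windows:   {len(dataset.labeled)} (balanced over 5 classes)")
print(f"unlabeled windows: {len(dataset.unlabeled)}")
print(f"  of which inactive (ground truth): {int(dataset.inactive_mask.sum())}")
print(f"  of which contain missing values:  {int(dataset.unlabeled.has_missing.sum())}")
print(f"test windows:      {len(dataset.test)}")
print(f"files written to {out}/")
# The inactive count is the contamination the cleaning stage must find;
# the missing-value windows are dropped outright during preprocessing.
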
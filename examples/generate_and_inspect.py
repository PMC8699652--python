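"""Generate the 110-sample blend design and inspect its structure.

Builds the default synthetic dataset — sesame and rapeseed oil blended
with soybean oil at 0-100% in 10% steps, five replicate groups, with
scatter and white noise — labels it for the qualitative task, and writes
the spectral table to CSV.
"""

from collections import Counter

from oilblend import ScatterNoiseModel, assign_class_labels, generate_dataset, write_spectra

data = generate_dataset(noise=ScatterNoiseModel(seed=0))
print(f"samples: {data.n_samples}, wavelengths: {data.n_wavelengths} "
      f"({data.grid.values[0]:.0f}-{data.grid.values[-1]:.0f} nm)")

labelled = assign_class_labels(data)
counts = Counter(m.class_label for m in labelled.meta)
for label, n in sorted(counts.items(), key=lambda kv: (kv[0] is None, kv[0])):
    print(f"  {label or '(excluded 50% blends)'}: {n}")

path = write_spectra(labelled, "scratch_spectra.csv")
print(f"wrote {path}")
# Expected: 110 samples, 7 classes plus 10 excluded 50% blends; the CSV is
# the canonical exchange format every other stage reads.
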
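"""Generate a Debrecen-style synthetic screening table and inspect it.

The generator reproduces the schema of the UCI diabetic-retinopathy
feature table: quality/pre-screening flags, six microaneurysm counts at
tightening confidence thresholds, eight exudate features, two normalized
geometry features and a binary outcome, with a planted class signal in the
mid-ladder microaneurysm counts.
"""

from hho_featsel import SyntheticSpec, generate_synthetic

table = generate_synthetic(SyntheticSpec(n_rows=1151, seed=0))
frame = table.to_frame()

print(f"rows x features : {table.features.shape}")
print(f"positive rate   : {table.labels.mean():.3f}")
print("microaneurysm-count means (confidence 0.5 -> 1.0, non-increasing):")
print(frame[["ma_05", "ma_06", "ma_07", "ma_08", "ma_09", "ma_10"]].mean().round(1))
# The per-class means of the informative columns (ma_06..ma_09 by default)
# differ by about one standard deviation:
by_class = frame.groupby("class")[["ma_07"]].mean()
print("ma_07 mean by class:\n", by_class.round(1))
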
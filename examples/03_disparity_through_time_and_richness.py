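"""Disparity-through-time curves and range-through richness.

Species are assigned to their epoch of appearance (the interval containing
the first-occurrence age); disparity per interval is computed on both the
7-epoch chronostratigraphic scale and 7 equal 18.1-My bins, alongside
per-stage range-through richness.
"""

from morphodisp import (
    default_epochs,
    default_stages,
    disparity_through_time,
    equal_bins,
    gpa,
    make_outline_scheme,
    pca,
    range_through_richness,
)
from morphodisp.chronology import SPAN_END_MA, SPAN_START_MA
from morphodisp.synthetic import default_truth, simulate_dataset

template, sliders = make_outline_scheme(11, 25)
truth, census = default_truth(template=template, seed=1)
configs, metadata = simulate_dataset(truth, census, seed=1)

sample = gpa(configs, sliders=sliders)
ordination = pca(sample)

epochs = default_epochs()
bins = equal_bins(SPAN_START_MA, SPAN_END_MA, 7)
print(f"study window: {SPAN_START_MA}-{SPAN_END_MA} Ma "
      f"({SPAN_START_MA - SPAN_END_MA:.1f} My, bin width {126.7 / 7:.1f} My)\n")

print("Procrustes variance per epoch of appearance:")
print(disparity_through_time(sample, ordination, metadata, epochs, "procrustes_variance")
      .round(5).to_string(index=False))

print("\nSum of variances per equal 18.1-My bin:")
print(disparity_through_time(sample, ordination, metadata, bins, "sum_of_variances")
      .round(5).to_string(index=False))
# intervals holding fewer than 2 species have no defined dispersion: NaN, not 0

print("\nRange-through richness per stage (species counted throughout FAD-LAD):")
print(range_through_richness(metadata, default_stages()).to_string(index=False))
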
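"""Quantify centromere dots on a simulated mitotic spread.

Reproduces the manual microscopy workflow: background-corrected intensity in
a fixed 10x18-pixel box around each dot, normalization against reference
centromeres within the same spread, peak-to-peak distance along a line
profile through each sister pair, and one-dot/two-dots classification.
"""

import numpy as np

from neocent import (
    SimulationConfig,
    SpotROI,
    classify_dot_pattern,
    extract_line_profile,
    normalize_within_spread,
    peak_pair_distance,
    quantify_spot,
    simulate_spread,
)

cfg = SimulationConfig()  # 1-um pairs, 0.1 um/px, noise at 5% of amplitude
image, truth = simulate_spread(cfg, seed=5)
print(f"spread image {image.shape}, {truth.pair_id.nunique()} dot pairs\n")

intensities = {}
for row in truth.itertuples(index=False):
    roi = SpotROI(center=(int(round(row.row)), int(round(row.col))))
    intensities[row.spot_id] = quantify_spot(image, roi)

target = truth.spot_id.iloc[0]
references = [v for k, v in intensities.items() if k != target]
norm = normalize_within_spread(intensities[target], references)
print(f"spot {target}: corrected intensity {intensities[target]:.0f}, "
      f"{norm:.2f}x the within-spread reference mean")

print("\npair  planted(um)  measured(um)  pattern")
for pair_id, pair in truth.groupby("pair_id"):
    (r1, c1), (r2, c2) = pair[["row", "col"]].to_numpy()
    profile = extract_line_profile(image, (r1, c1), (r2, c2), cfg.pixel_size,
                                   min_prominence=300)
    d = peak_pair_distance(profile)
    pattern = classify_dot_pattern(profile)
    print(f"{pair_id:>4}  {pair.separation_um.iloc[0]:>10.2f}  {d:>12.3f}  {pattern}")
print()
print("Measured separations track the planted 1.00 um to within a few")
print("hundredths; resolved pairs classify as 'two-dots'.")
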
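"""Stained-area fraction and automated nuclei counting.

Quantifies a synthetic Alizarin-red-style section by HSV color
thresholding (positive pixels / tissue pixels) and counts nuclei on a
synthetic Hoechst-style field by threshold + connected components. The
nuclei count then normalizes a per-well enzymatic activity to a per-cell
value, the way ALP activity is normalized to cell number.
"""

from htsrepurpose import (
    count_nuclei,
    normalize_per_cell,
    simulate_nuclei_image,
    simulate_stain_image,
    stain_positive_area,
)

section, truth = simulate_stain_image((512, 512), true_fraction=0.18, seed=5)
res = stain_positive_area(section)
print(f"stain-positive fraction: {res.fraction:.4f} "
      f"({res.positive_pixels}/{res.total_tissue_pixels} tissue pixels; "
      f"painted truth {truth['fraction']:.4f})")

field, truth_n = simulate_nuclei_image((1024, 1024), n_nuclei=180, radius=5,
                                       seed=6)
cnt = count_nuclei(field, intensity_threshold=100, min_size=4)
print(f"nuclei counted: {cnt.count} (generated {truth_n['count']})")

alp_absorbance = 0.84  # a.u. at 405 nm for the whole well
per_cell = normalize_per_cell(alp_absorbance, cnt.count)
print(f"ALP activity per cell: {per_cell:.2e} a.u./cell")
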
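"""Slide-level tangle burden scores and their ordinal-grade correlation.

Each synthetic slide is segmented by sliding a predictor over
non-overlapping 1024-px tiles; detections are counted as contiguous
blobs at 1/64 resolution and normalized by detected tissue area, then
rescaled by a reference (median) area.  Scores are compared with
ordinal grades via Spearman's rho.
"""

import warnings

from nftseg import correlate_with_grades, make_synthetic_wsi, score_slide

warnings.filterwarnings("ignore", message=".*DAB channel.*")

slides = {"none": 0, "sparse": 2, "moderate": 8, "frequent": 20}
median_area = 1500.0  # downscaled px; the rescale constant

scores, grades = [], []
for grade, n_nft in slides.items():
    wsi = make_synthetic_wsi(n_nft, dims=(3072, 3072), tissue_fraction=0.6,
                             seed=60 + n_nft)
    s = score_slide(wsi.image, median_area=median_area, wsi_id=grade)
    scores.append(s.score)
    grades.append(grade)
    print(f"{grade:9s} tangles {n_nft:2d}  blobs {s.blob_count:2d}  "
          f"tissue {s.tissue_area:5d} px  burden score {s.score:7.2f}")

rho, p = correlate_with_grades(scores, grades)
print(f"Spearman rho vs ordinal grade: {rho:.3f} (p = {p:.3g})")
print(
    "-> the burden score is blobs per median-sized slide: linear in the\n"
    "   count, halved when tissue area doubles, and exactly 0 on a slide\n"
    "   with no detections."
)
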
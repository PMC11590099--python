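"""Repeat-imaging measurement uncertainty for single granules.

Builds scenes of ~50 stationary granules (pH 4.5–6.5), images each scene
four times with independent Poisson noise at the working photon budget
(median ~70 counts/pixel in the cell), segments and matches the granules
across the repeats, and reports the per-granule standard deviation of the
recovered pH.

The mean SD is the single-measurement uncertainty of the pipeline; at this
photon budget it comes out near 0.04 pH units, i.e. a single granule's pH
reading is reproducible to roughly +/-0.04.
"""

import numpy as np

from phasorph.pipeline import run_uncertainty

exp = run_uncertainty(seed=1, n_granules=50, n_repeats=4, n_scenes=2)

sds = np.array(exp.report.per_track_sd)
print(f"granules detected per frame : {exp.n_detected}")
print(f"tracks spanning all repeats : {exp.report.n_tracks}")
print(f"per-track pH SD             : median {np.median(sds):.4f}, "
      f"90th pct {np.percentile(sds, 90):.4f}")
print(f"mean measurement uncertainty: {exp.report.mean_sd:.4f} pH units")
print("\nEach track is one granule measured four times; its SD mixes photon")
print("shot noise, segmentation jitter and background-subtraction noise.")
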
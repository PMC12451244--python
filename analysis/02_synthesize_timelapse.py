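#!/usr/bin/env python
"""Generate the synthetic time-lapse products consumed downstream.

Bundles node-marker tracks (with jitter and dropout, as for real
fluorescent dots), the noisy curvature and apparent-elongation
kymographs, and a short speckle-frame sequence, all with the generating
truth attached.  Everything is reproducible from the seed.
"""

from pathlib import Path

import numpy as np

from nutkin import io as nio
from nutkin.synth import make_kymograph_dataset, render_frames

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SCRATCH.mkdir(exist_ok=True)

SEED = 1
ds = make_kymograph_dataset(
    noise_sd_curv=2e-4,       # ~5 % of the curvature oscillation amplitude
    noise_sd_elong=2e-3,
    node_noise_sd=0.05,       # mm jitter on detected node centres
    dropout_p=0.02,
    seed=SEED,
)
nio.write_tracks(OUT / "node_tracks.csv", ds.node_tracks)
nio.write_kymograph(OUT / "curvature_kymo_noisy.csv", ds.curvature_kymo)
nio.write_kymograph(OUT / "elongation_kymo_noisy.csv", ds.elong_kymo)
print(f"seed {SEED}: {ds.node_tracks.n_nodes} node tracks over "
      f"{len(ds.node_tracks.times)} frames "
      f"({(~ds.node_tracks.visible).mean()*100:.1f} % dropout)")

# short speckle sequence (binary TIFF goes to scratch/, not the deliverable)
frames = render_frames(ds.truth, noise_sd=0.01, stride=30, seed=SEED + 1)
nio.write_frames(SCRATCH / "speckle_frames.tif", frames)
print(f"rendered {frames.n_frames} speckle frames "
      f"({frames.images.shape[1]}x{frames.images.shape[2]} px at "
      f"{frames.mm_per_px} mm/px) -> scratch/speckle_frames.tif")
print(f"tabular outputs in {OUT}")
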
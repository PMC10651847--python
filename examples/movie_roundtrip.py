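"""Two-half-field movie synthesis and trace re-extraction.

Renders eight molecules as Gaussian spots (donor left half-field, acceptor
right half-field shifted by a rigid channel offset), then runs the full
localization front end: spot detection on the 20-frame average, 2D Gaussian
fits, displacement-vote channel registration, and per-frame intensity
extraction at the matched positions.
"""

from dataclasses import replace

import numpy as np

from smfretkit.localize import extract_movie
from smfretkit.scenarios import canonical_t99
from smfretkit.synth import MovieSpec, render_movie, render_trace, sample_state_path

scenario = replace(canonical_t99(), n_frames=120, bleach_rate_donor=0.0,
                   bleach_rate_acceptor=0.0, shot_noise=False,
                   read_noise_sd=0.0, total_intensity=3000.0)
rng = np.random.default_rng(9)
gx, gy = np.meshgrid([14, 28, 42], [14, 30, 46])
positions = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[:8]
positions += rng.uniform(-1, 1, positions.shape)
traces = [render_trace(sample_state_path(0.4, 0.22, scenario.duration, rng),
                       scenario, rng) for _ in range(len(positions))]

spec = MovieSpec(frame_shape=(64, 128), n_molecules=len(positions), psf_sigma=1.2,
                 channel_offset=(2.0, -1.0), background_level=20.0,
                 read_noise_sd=2.0, seed=5)
movie = render_movie(spec, traces, positions)
extracted, transform = extract_movie(movie)

print(f"registered channel offset : dx={transform.dx:.2f}, dy={transform.dy:.2f} px "
      f"(truth {64 + spec.channel_offset[0]:.1f}, {spec.channel_offset[1]:.1f};"
      " dx includes the 64 px half-field shift)")
print(f"molecules recovered       : {len(extracted)}/{len(positions)}")
errs = []
for tr in extracted:
    j = int(np.argmin(np.sum((positions - tr.meta["donor_fit"].center) ** 2, axis=1)))
    for ch in ("donor", "acceptor"):
        a, b = getattr(tr, ch), getattr(traces[j], ch)
        errs.append(np.sqrt(np.mean((a - b) ** 2)) / b.mean())
print(f"per-frame intensity error : {100*np.mean(errs):.1f}% relative RMS "
      "(photon + background noise floor)")
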
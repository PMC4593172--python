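"""Cooperation time courses and strategy snapshots for three amplitudes.

Reproduces the characteristic trajectory shapes from the prepared
half-cooperator/half-defector state at b=1.34, delta=0.4: collapse with
frozen weights, a no-retreat climb at ratio 0.5, and an intermediate
plateau at ratio 1.0.  Snapshots of the strategy field are written as
plain-text matrices and PNG images under example_output/.
"""

from pathlib import Path

import coevopd as cp
from coevopd.observables import snapshot_to_image, snapshot_to_text

outdir = Path("example_output")
outdir.mkdir(exist_ok=True)

for Delta in (0.0, 0.2, 0.4):
    cfg = cp.make_config(
        b=1.34, delta=0.4, Delta=Delta,
        init_mode="half_plane", total_mcs=3000, measure_window=500, seed=7,
    )
    traj = cp.time_course(cfg, snapshot_steps=(0, 800, 1300, 3000))
    label = f"ratio {Delta / 0.4:.1f}"
    print(
        f"{label}: rho_C start {traj.rho[0]:.2f} -> min {traj.rho.min():.3f} "
        f"-> stationary {traj.stationary(500):.3f}"
    )
    for snap in traj.snapshots:
        stem = outdir / f"ratio{Delta/0.4:.1f}_mcs{snap.mcs}"
        snapshot_to_text(snap, stem.with_suffix(".txt"))
        snapshot_to_image(snap, stem.with_suffix(".png"))

print()
print(f"snapshots written to {outdir}/ (blue = cooperators, red = defectors)")
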
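"""Compare positional rigidity of the wild-type and mutant systems.

Generates 16 replicate pseudo-trajectories per variant (the mutant
fluctuation scale is 0.7x the wild-type's, mimicking its greater
stiffness), measures per-frame RMSD against each run's first frame
after Kabsch superposition, and pools the runs. Lower mean AND lower
spread of the RMSD distribution is read as greater rigidity.
"""

import numpy as np

from snpbindshift import rigidity_summary, rmsd_histogram, rmsd_series
from snpbindshift.synthetic_data import preset

dataset = preset("paper_default", n_runs=16, n_samples=10, n_frames=30, seed=42)

groups = {}
for variant in ("AT", "GC"):
    series = []
    for i, traj in enumerate(dataset.trajectories[(variant, "Complex")], start=1):
        reference = traj.topology.with_coordinates(traj.frames[0])
        series.append(rmsd_series(traj, reference, fit=True, run_id=f"run{i:02d}"))
    groups[variant] = series
    hist = rmsd_histogram(series, bin_width=0.1)
    pooled = np.concatenate([s.values for s in series])
    print(
        f"{variant} complex: {hist.counts.sum()} frames over {hist.n_runs} runs, "
        f"RMSD {pooled.mean():.3f} +/- {pooled.std():.3f} A"
    )

summary = rigidity_summary(wt=groups["AT"], mut=groups["GC"])
print(f"mean difference (mut - wt): {summary.mean_difference:.3f} A")
print(f"verdict: {summary.verdict}")
print("the variant complex sits lower and fluctuates less -> more rigid")
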
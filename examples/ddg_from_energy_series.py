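"""Relative binding free energy from the four-system thermodynamic cycle.

Generates 16 replicate AR(1) interaction-energy series for each of the
four systems {AT, GC} x {Complex, DNA}, estimates block-averaged mean
energies per run, closes the LIE cycle per run (alpha = 0.18,
beta = 0.43), and pools the replicates. The generating preset encodes a
true ddG of -0.800 kcal/mol (-0.700 electrostatic, -0.100 van der
Waals); the pooled estimate recovers it within its standard error.
"""

from snpbindshift import ddg_bind, mean_interaction_energies, pool_runs
from snpbindshift.synthetic_data import preset

dataset = preset("paper_default", n_runs=16, n_samples=10_000, n_frames=1, seed=42)

per_run = []
for run in range(16):
    cells = {
        key: mean_interaction_energies(series_list[run], block_count=10)
        for key, series_list in dataset.energies.items()
    }
    per_run.append(ddg_bind(cells, run_label=run + 1))

pooled = pool_runs(per_run)
print("per-run ddG_bind (kcal/mol):")
print(pooled.per_run[["run", "ddg", "el_component", "vdw_component"]].round(3).to_string(index=False))
print(f"\npooled ddG_bind = {pooled.ddg:.3f} +/- {pooled.se_ddg:.3f} kcal/mol")
print(f"  electrostatic component: {pooled.ddg_el_component:.3f} kcal/mol")
print(f"  van der Waals component: {pooled.ddg_vdw_component:.3f} kcal/mol")
print("negative ddG: the variant C.G pair binds the transcription factor more strongly,")
print("and the shift is dominated by electrostatics")
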
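# snp-bindshift

Post-simulation analysis of how a single regulatory base-pair
substitution shifts a transcription factor's binding to its DNA site.
The motivating system is a promoter rSNP that swaps a wild-type A·T
base pair for C·G inside a transcription-factor binding site; the
package quantifies the consequences of such a swap from MD-style output
along three axes:

1. **Rigidity** — per-frame RMSD of atomic positions against a
   reference after optimal (Kabsch) superposition, pooled into
   histograms over replicate runs, with a verdict on which variant's
   structures sit lower and fluctuate less;
2. **Hydrogen bonding** — strictly geometric detection (donor–acceptor
   distance < 3.0 Å and H–donor–acceptor angle < 20°) of direct
   protein–DNA hydrogen bonds and of water-mediated bridges within
   10 Å of the variant site, with occupancy and lifetime statistics;
3. **Binding free energy** — the Linear Interaction Energy (LIE)
   estimate per variant,

   ΔG_bind = α·(⟨E_vdW⟩_bound − ⟨E_vdW⟩_unbound) + β·(⟨E_el⟩_bound − ⟨E_el⟩_unbound),

   with α = 0.18, β = 0.43, closed into a four-system thermodynamic
   cycle over {AT, GC} × {Complex, DNA}:

   ΔΔG_bind = ΔG_bind^GC − ΔG_bind^AT,

   decomposed exactly into electrostatic (β) and van der Waals (α)
   components, with block-averaging standard errors within runs and
   replicate pooling across runs. A negative ΔΔG_bind means the variant
   pair binds the factor more strongly.

Because real MD trajectories are bulky and engine-specific, the package
ships a first-class synthetic-data module that generates every input at
desk scale: idealized B-DNA duplexes with explicit polar hydrogens and
correct Watson–Crick bond counts (G·C three, A·T two), toy protein–DNA
complexes with a bridging water, replicate Gaussian-fluctuation
pseudo-trajectories (mutant preset 0.7× the wild-type amplitude), and
replicate AR(1) interaction-energy series whose four-system means close
the cycle at exactly −0.800 kcal/mol (−0.700 electrostatic, −0.100 van
der Waals).

## Worked example

```sh
python examples/ddg_from_energy_series.py
```

generates 16 replicate energy series per system, closes the cycle per
run and pools the replicates:

```
pooled ddG_bind = -0.792 +/- 0.016 kcal/mol
  electrostatic component: -0.695 kcal/mol
  van der Waals component: -0.097 kcal/mol
```

The pooled estimate recovers the generating value of −0.800 kcal/mol
within one standard error, and the electrostatic term dominates — the
shape-complementarity (van der Waals) term plays only a minor role.
The other scripts in `examples/` walk through the remaining
capabilities one at a time (`build_and_count_hbonds.py`,
`rigidity_comparison.py`, `water_bridges.py`, `full_pipeline.py`), each
printing a few annotated numbers.

The same analyses are scriptable from the shell:

```sh
snp-bindshift simulate --preset paper_default --outdir data/ --seed 42
snp-bindshift run --input-dir data/ --outdir report/
snp-bindshift ddg --energies data/energies --out ddg.csv
```

`run` writes per-stage CSVs (RMSD histograms, hydrogen-bond summaries,
per-run + pooled ΔΔG) and a combined `report.json` with full
provenance (configuration, seed, package version).

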
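# Methods

## Problem setting

A regulatory single-nucleotide polymorphism (rSNP) inside a
transcription-factor binding site replaces a wild-type A·T base pair
with C·G. The package quantifies, from trajectory- and energy-level
simulation output, whether and why the substitution changes (i) the
positional rigidity of the DNA and of the protein–DNA complex, (ii) the
hydrogen-bond network across the interface, and (iii) the binding free
energy of the factor, via a relative (wild-type vs variant)
thermodynamic cycle. The MD engine itself is out of scope: the package
is strictly post-analysis, plus a synthetic generator that emulates the
statistical character of the inputs.

## Rigidity (RMSD)

Per frame, the RMSD of atomic positions is measured against a reference
over a configurable atom selection, after optimal rigid-body
superposition when `fit=True`. Superposition solves the constrained
orthogonal Procrustes problem (via
`scipy.spatial.transform.Rotation.align_vectors`), so the returned
rotation is always proper — reflections are excluded — and the fitted
RMSD is recomputed from the optimal transform itself for ~1e-15
accuracy. Defaults, stated explicitly because they are genuine choices:

* selection: heavy atoms (hydrogens excluded), standard practice;
* reference: each run's own first frame rather than a crystal
  structure, making the measure self-contained per run (configurable by
  passing any reference structure);
* histograms: bin width 0.1 Å, edges starting at 0.

The rigidity verdict compares pooled mean and pooled standard deviation
between variants: the mutant is called more rigid only when both are
lower (mirror case symmetric; an sd tie below 1e-12 falls back to the
means so the verdict is total). No significance test is attached — the
comparison is descriptive, and deliberately so: attaching one would
imply a sampling model the Gaussian pseudo-trajectories do not share
with real MD.

## Hydrogen bonds and water bridges

Bond existence is strictly geometric: donor–acceptor distance < 3.0 Å
and hydrogen–donor–acceptor angle < 20°, both strict inequalities, the
angle measured at the donor between the D→H and D→A vectors (the only
reading under which "< 20°" means a near-linear D–H···A arrangement).
Which atoms may donate or accept is pinned by a fixed, versioned
dictionary (`chemistry.py`): Watson–Crick faces and purine N7 of the
four deoxyribonucleotides, backbone phosphate/ester oxygens, amino-acid
backbone N–H and C=O plus polar side chains, and water. Hydrogens are
attached to the nearest heavy atom within 1.2 Å; heavy pairs closer
than 1.9 Å are treated as covalent contacts and never reported as
bonds. Bonds are keyed by (donor heavy atom, acceptor): which hydrogen
satisfies the criterion in a frame does not split one bond into many
(rotating water hydrogens keep a single identity).

A water bridge is one water whose oxygen lies within 10 Å of the
variant-site base-pair centroid (recomputed per frame — the site is
positional, not lab-frame) and that simultaneously hydrogen-bonds, in
either donor/acceptor direction, at least one protein atom and one DNA
atom. Occupancy is the fraction of frames a bond key is present;
durations are maximal runs of consecutive presence times the frame
spacing; events are those runs.

## LIE binding free energies

Per variant, ΔG_bind = α·Δ⟨E_vdW⟩ + β·Δ⟨E_el⟩ between the bound
(complex) and unbound (free DNA) simulations, with the pre-optimized
empirical parameters α = 0.18 and β = 0.43. Entropy is implicit in the
parametrization; no explicit entropy term is computed, and α/β are not
refit. The relative quantity closes the four-system cycle
ΔΔG_bind = ΔG_bind^GC − ΔG_bind^AT, which decomposes exactly into a
β-scaled electrostatic and an α-scaled van der Waals component. The
"ligand" whose interaction energies enter the cycle is the variant base
pair itself (the quantity of interest is the local substitution), with
whole-DNA series equally accepted — the energy tables carry a free-text
ligand label and the math is agnostic to it.

Uncertainties: energy series from dynamics are autocorrelated, so naive
standard errors would be optimistic. Within a run, means carry
block-averaging SEs (default 10 contiguous blocks; SD of block means
over √blocks), and single-cycle SEs propagate as the root sum of
squares of the scaled cell SEs. Across runs, replicates are pooled as
an unweighted mean (equal-length runs give no weighting basis), with
the pooled SE taken as the population standard deviation of the per-run
ΔΔG values over √n_runs — the package's fixed convention, stated here
because sample-vs-population sd differs by ~3% at n = 16. Pooling a
single run is refused; the run's own result is reported instead.

## Synthetic data: what it emulates, and what it does not

* **Structures.** Duplexes are idealized B-form ladders (rise 3.38 Å,
  twist 36°/step) built from a fixed, versioned template set. Templates
  carry every hydrogen-bond-relevant atom at geometry giving exactly
  three bonds per G·C and two per A·T pair under the default criteria,
  but omit cosmetic ring carbons and nonpolar hydrogens: they are
  chemically labelled scaffolds, not crystallographic nucleotides. The
  toy complex adds a two-residue peptide (Ser donating to a backbone
  phosphate, Asn providing the acceptor for a placeable bridging
  water). Mutation rebuilds one rung from the new pair's template in
  the same helical frame, leaving every other atom bit-identical.
* **Trajectories.** Frames are the base structure plus independent
  isotropic Gaussian heavy-atom displacements (hydrogens ride their
  heavy atom); the mutant preset uses 0.7× the wild-type scale
  (defaults 0.35 vs 0.5 Å), encoding the qualitative rigidity ordering
  by construction. There is no inertia, no correlation between frames
  and no physics — so passing rigidity tests shows the measurement
  chain is correct, not that any force field predicts rigidity.
* **Energies.** Per system and channel, stationary AR(1) series
  x_t = μ + φ(x_{t−1} − μ) + ε_t with lag-1 autocorrelation φ = 0.9 and
  stationary sds of 1 (vdW) and 2 (el) kcal/mol — fluctuation scales
  typical of interaction-energy traces at this sampling interval
  (0.02 ps, i.e. every 10 steps of 2 fs). The `paper_default` preset
  pins the four means so the noiseless cycle evaluates to exactly
  −0.800 kcal/mol, split −0.700 electrostatic / −0.100 van der Waals
  (component deltas −0.7/0.43 and −0.1/0.18 kcal/mol on the GC-complex
  cell); the absolute means (−90 to −200 kcal/mol) are arbitrary, since
  only cycle differences matter. The `null` preset carries no mutation
  at all — the GC systems are exact copies of the AT ones, sharing
  seeds — so every contrast closes at exactly zero.
* **Replicate design.** 16 runs per system by default; 10 000 samples
  per run is the package's desk-scale default for the energy series
  (the estimator is n-agnostic, and 10 000 samples already put the
  pooled SE near 0.02 kcal/mol, an adequate resolution for a
  −0.8 kcal/mol effect). All generators are deterministic given a seed,
  with per-(run, system, channel) substreams.

## Numerical choices and degenerate inputs

* Strict inequalities at the 3.0 Å / 20° boundaries; boundary values
  excluded by definition.
* Superposition requires ≥ 3 points; fewer is a degenerate-input error,
  mismatched point counts a dimension error.
* Histogram edges start at 0 and extend to the rounded-up maximum;
  every count is conserved.
* Block averaging drops trailing remainder samples from the SE estimate
  only (means always use all samples).
* Frame indices are 0-based in code, 1-based in files and reports; run
  labels are 1-based.
* Coordinates in Å, energies in kcal/mol, times in ps, angles in
  degrees, throughout.
* Trajectory I/O is multi-model PDB only, with the frame spacing in a
  `REMARK 1 DT_PS` header; a caller-supplied spacing overrides the
  header, and 1 ps is assumed when neither exists.

## Known limitations

* The geometric H-bond definition has no energetic component; bifurcated
  bonds are collapsed onto their best-angle hydrogen per (donor,
  acceptor) key.
* The donor/acceptor dictionary covers standard residues only;
  modified bases or nonstandard ligands need a dictionary extension.
* Absolute LIE ΔG values are not calibrated against experiment and are
  known to be unreliable in general; only the relative ΔΔG ranking is
  meaningful, which is why the cycle is the headline output.
* The synthetic trajectories cannot exhibit conformational transitions,
  correlated motions or diffusing waters; water-bridge statistics on
  them demonstrate detector correctness, not solvation thermodynamics.
* `mutate_pair` assumes the deterministic helical frames of the
  internal builder; applying it to arbitrary external structures is
  unsupported.
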
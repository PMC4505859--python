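# Methods

This note documents the models and procedures implemented in `pipsites`:
what is computed, under which assumptions, with which defaults, and what the
synthetic validation experiments do and do not establish.

## 1. System representation

A coarse-grained system is a flat list of beads (`BeadTopology`) plus
per-frame coordinates in an orthorhombic periodic box (`Frame`,
`Trajectory`). Units are nm / ns / kJ·mol⁻¹ / elementary charges.

Lipids are represented by a single head bead. This is deliberate: every
analysis in the package touches only head/phosphate beads and minimal
distances, never lipid internal structure, so tail beads would add cost
without changing any observable the package defines. Each PIP₂ molecule
carries exactly one phosphate head bead with charge −5 e by default (a
configurable convention for the net headgroup charge at neutral pH; the
precise value only scales the toy simulator's attraction). DOPC head beads
are neutral. Proteins are one backbone bead per residue.

The bilayer builder places each leaflet on a square lattice with a chosen
area per lipid (default 0.7 nm², a typical fluid-phase value) and leaflet
planes a chosen distance apart (default 4 nm). PIP₂ replacement draws
round(fraction × leaflet size) lipids — round half up — uniformly without
replacement under an explicit seed; with 331 lipids per leaflet and a 10 %
fraction this yields 33 PIP₂ and 629 DOPC, the composition of the reference
system. "Membrane surface" is defined throughout as the mean z of the
upper-leaflet head beads; protein placement fixes the gap between the lowest
protein bead and this plane exactly.

The toy protein is a golden-spiral (Fibonacci) shell, randomly rotated under
its seed, with a chosen subset of residues carrying a basic charge. The
elastic network (harmonic bonds between all bead pairs closer than 0.9 nm,
force constant 500 kJ·mol⁻¹·nm⁻², rest length equal to the build-time
distance) records the rigid tertiary structure; because the integrator moves
the protein as a single rigid body, the network's bonds are preserved
exactly and it exerts no force — it exists so that written systems carry a
complete, conventional description.

## 2. Toy Brownian simulator

The simulator is a deliberately minimal overdamped (Euler–Maruyama) Langevin
integrator whose only job is to generate trajectories with the
phenomenology the analyses assume: diffusive approach, transient
electrostatically driven binding with many association/dissociation events,
and simultaneous contact with several PIP₂ molecules. It is not an attempt
to reproduce any production force field's energetics or kinetics.

Forces: pairwise Debye–Hückel screened Coulomb
(k_e q₁q₂ e^(−r/λ_D)/(ε_r r)) plus 12-6 Lennard-Jones between protein beads
and membrane/ion beads, both plainly truncated at 1.2 nm (truncation without
shifting is a documented dialect; energies are not conserved quantities in
Brownian dynamics). Lipid–lipid and ion–lipid interactions are neglected —
the membrane is an ideal in-plane fluid whose head beads are harmonically
restrained in z to their leaflet plane (k = 100 kJ·mol⁻¹·nm⁻²,
σ_z ≈ 0.16 nm at 320 K) and feel the protein's reaction force.

The protein moves as one rigid body: net force → centre translation, net
torque → small-angle axis–angle rotation (Rodrigues), with thermal noise
from the grouped frictions γ_T = Nγ and γ_R = γ Σd². Per-step displacements
are capped at 0.1 nm so the steep LJ core cannot destabilize the
integration; the cap slightly damps diffusion at the default 0.01 ns step
(measurably, ~20 % in MSD), which is irrelevant to contact statistics but
is why the diffusion-law tests use a finer step where the cap never engages.

Defaults and their reasoning:

| parameter | default | why |
|---|---|---|
| timestep | 0.01 ns | thermal step ≈ 0.05 nm/axis, stable under the cap |
| temperature | 320 K | conventional fluid-phase membrane temperature |
| friction γ | 25 kJ·mol⁻¹·ns·nm⁻² | bead D = kT/γ ≈ 0.11 nm²/ns, the accelerated regime typical of coarse-grained dynamics |
| Debye length | 1.0 nm | physiological-range screening |
| dielectric ε_r | 80 | implicit aqueous solvent; with q = +1 vs −5 e this gives a 4–5 kT per-pair well at contact, deep enough to bind and shallow enough to unbind |
| LJ σ, ε | 0.43 nm, 2 kJ·mol⁻¹ | contact minimum near 0.48 nm, i.e. typical bound distances just inside the 0.52 nm criterion, with sub-0.45 nm approaches common enough that tight-cutoff sensitivity analyses have support |
| leaflet restraint k | 100 kJ·mol⁻¹·nm⁻² | fluid in-plane, ~0.16 nm vertical roughness |

With these defaults a charged protein near the membrane binds 20–80 % of
the time depending on seed, shows dozens to hundreds of binding transitions
per 100 ns, touches 1–3 PIP₂ simultaneously (occasionally more), and its
mean bound distance is ≈ 0.47 nm.

z-periodicity is retained (no walls), so an escaping protein can re-enter
from the far side and reach either leaflet; the box is fixed (no barostat).

## 3. Contact analyses

* **Binding criterion**: strictly less than the cutoff (default 0.52 nm);
  a frame exactly at the cutoff is unbound. All distances are minimum-image.
* **n_P**: number of distinct PIP₂ molecules with ≥ 1 phosphate bead within
  cutoff of any protein bead. The stoichiometry distribution is normalized
  over *bound* frames (the classes 1/2/3/4–6 then partition to 100 %, which
  is the convention that makes the published row sums work out).
* **x_i = n_i/N**: n_i counts frames (not contact events — an equivalent
  event-count denominator is not implemented) in which residue *i* touches a
  PIP₂ phosphate bead; N counts frames in which the protein is bound.
  Residue contacts are measured against phosphate beads only by default,
  matching the molecule-level criterion; a switch widens this to all PIP₂
  beads.
* **Lipid census**: a lipid's contact fraction is its contact-frame count
  divided by the number of frames the protein contacts *any* lipid of that
  class (computed separately for PIP₂ and DOPC, both with the same cutoff
  criterion applied to head beads); N_L(threshold) counts lipids strictly
  above the threshold, so N_L(10 %) ≤ N_L(5 %) by construction.
* **Selection rule**: x_i > minor threshold (5 %) in ≥ 2 simulations, OR
  x_i > major threshold (10 %) in any — strict inequalities, applied to an
  occupancy matrix of simulations × residues.
* **Cutoff sweep**: the sweep reports per-residue occupancy normalized by
  the *total* number of analyzed frames. Rationale: with the
  bound-frame denominator N(c) recomputed at each cutoff, x_i is not
  mathematically monotone (N can grow through frames that do not involve
  residue *i*), whereas the fraction-of-time normalization is non-decreasing
  in the cutoff by construction — which is the property the sensitivity
  analysis is meant to exhibit. Single-cutoff tables still use x_i = n_i/N.
* **Equilibration**: analyses default to the full trajectory; an
  `equilibration_skip` (ns) drops early frames when requested.
* Degenerate inputs: a never-binding trajectory yields a flagged
  `defined=False` table with NaN occupancies (never silent zeros); an empty
  stoichiometry distribution is flagged, not NaN.

## 4. Spatial analyses

* **RDF**: standard pair-correlation estimator; counts of target beads
  around reference beads per radial bin, normalized by shell volume (3-D
  mode) or annular area (lateral mode, x-y distances — appropriate for the
  quasi-planar lipid field) and by the mean target density; self-pairs
  excluded. r_max must not exceed half the smallest relevant box edge
  (minimum image). The default mode is 3-D; lateral is used for lipid–lipid
  correlations.
* **Principal axis**: top eigenvector of the bead-coordinate covariance,
  sign-fixed to a non-negative z-component (no physical sign exists for an
  axis); because of the sign convention the *folded* |V_z| histogram is the
  one with a clean isotropic null (uniform on [0, 1]), and both signed and
  folded variants are available.
* **Pose classification**: a bound frame is labelled by which of two
  disjoint residue groups has ≥ 1 residue in PIP₂ contact — I only /
  II only / both / neither; the four labels partition bound frames.
  Calling the classifier on an unbound frame is an error by design
  (classification is conditional on binding). The FAK site groups
  (I: 191, 216, 218, 221, 222, 229, 640, 657, 665;
  II: 508, 514, 515, 578, 621, 627) ship as packaged defaults.
* **COM axis**: unit vector between centroids of two residue sets, equal
  bead masses (coarse-grained beads are near-uniform).

## 5. I/O

GRO is the canonical coordinate format (fixed columns, nm, 3 decimals);
trajectories use the portable concatenated multi-frame dialect with the time
stamp in the title line. GRO carries no charges or flags, so every written
system has a TSV topology sidecar that is authoritative on re-reading;
reading a bare GRO infers classes from residue names and leaflets from head
bead z as a best effort. Readers fail with located errors (file + line) on
malformed input; a charge column containing a unicode minus sign is rejected
rather than guessed. All writers are deterministic, and result tables carry
tool version, config hash and seed in header comments. The packaged
reference contact matrix is checksummed at load.

## 6. The synthetic validation battery

The canonical experiments (module `pipsites.benchmarks`) fix the study
conditions under which the analysis stack is validated:

* bilayer: 36 lipids per leaflet (box ≈ 5 × 5 × 12 nm), 10 % PIP₂ in the
  upper leaflet;
* protein: 16 residues on a 1.3 nm shell — the nearest-neighbour bead
  spacing (≈ 1.1 nm) is double the contact cutoff, so occupancy can
  discriminate a planted residue from its bystander neighbours at
  desk-scale statistics;
* planted hot spots: residues {2, 6, 10, 14} at +1 e; the zero-charge
  control shares the identical geometry and seeds;
* runs: 10 000 steps (100 ns) saved every 10 steps, started 0.15 nm above
  the surface so every seed samples both bound and unbound states within
  the run (rigid-body reorientation is slow compared with desk-scale run
  lengths, so runs started far away occasionally never bind and carry no
  occupancy information);
* aggregation: per-residue occupancies enter cross-seed means only from
  runs with ≥ 25 bound frames — an occupancy estimated from a handful of
  frames is noise, and a fixed support threshold keeps the mean honest.

Under these conditions, across independent ten-seed batteries: the charged
protein's binding fraction exceeds its paired control in ≥ 9/10 seeds; the
four planted residues are the top four by mean occupancy; per-residue sweep
occupancies are non-decreasing over cutoffs 0.42–0.62 nm with a stable
top-4 set; stoichiometry and pose classes each sum to 100 % of bound
frames.

**What this does and does not show.** The battery validates the *analysis
machinery* — that the contact statistics recover planted ground truth from
trajectories with realistic binding phenomenology — and the simulator-level
claim that electrostatics drive binding in this model. It does not validate
force-field accuracy, absolute kinetics (the first-binding times and binding
fractions of any production simulation), lipid–lipid structure (our membrane
is an ideal in-plane fluid: PIP₂–PIP₂ correlations are flat by
construction, so the "no recruitment" null is a calibration of the
estimator, not a discovery), or leaflet asymmetry beyond the geometry
encoded in the builder.

## 7. Numerical choices and degenerate cases

* Distances: vectorized minimum-image arithmetic, checked against O(n²)
  reference loops to 10⁻¹⁰ relative in the test suite.
* Elastic-network neighbour search: k-d tree with a strict `<` filter at
  the cutoff boundary; bonds sorted lexicographically for determinism.
* Rigid-body drift: each step applies an exactly orthogonal Rodrigues
  rotation, so intra-protein distances drift only by floating-point
  round-off (≪ 10⁻⁶ nm over full runs, asserted in tests).
* Random numbers: one `numpy` Generator per run seeded from `SimParams.seed`;
  noise is drawn in a fixed order (protein translation, rotation, lipids,
  ions) so trajectories are bitwise reproducible.
* Ties: a frame exactly at any threshold (contact cutoff, selection
  thresholds, census thresholds) falls on the exclusive side.
* Sample-size caveat: all shipped experiment sizes (bilayer, run lengths,
  seed counts) are the package's chosen desk-scale defaults; every
  statistical check in the tests states its tolerance relative to the
  sampling error of those sizes.

## 8. Known limitations

* Single-bead lipids cannot express headgroup orientation, tail packing or
  membrane deformation; "leaflet surface" is a flat plane by construction.
* The simulator's kinetics are not calibrated; only orderings and
  partitions are meaningful, never absolute rates.
* The rigid protein forbids conformational response to binding — intended,
  since the analyses assume a rigid autoinhibited module.
* PDB reading covers coordinates and residue metadata only.
* The residue-contact event-count denominator (as opposed to frame counts)
  is not implemented; frames are the unit of occupancy throughout.
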
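# Methods

This note records the models, parameters and numerical choices behind
`glyccs`, and what its tests do and do not demonstrate.

## Molecular model and I/O

Molecules are ordered atom lists with explicit hydrogens, integer-order
bonds, and stereo descriptors. Hydrogens are never added implicitly: the
workflow moves protons, so implicit-H ambiguity is unacceptable and inputs
must carry explicit H (structures retrieved from crystallographic sources
must be protonated upstream; the package does not guess).

* Atom indexing is 0-based internally; SDF/PDB serials stay 1-based at the
  I/O boundary. SDF/MOL V2000 and PDB records pass through RDKit; XYZ is
  parsed directly with a `charge=<int>` comment extension and a JSON
  sidecar for partial/formal charges.
* Bond perception fallback (XYZ, CONECT-less PDB): two atoms bond iff
  their distance is below 1.3 × the sum of covalent radii (RDKit periodic
  table values, e.g. H 0.31, C 0.76, N 0.71, O 0.66 Å).
* Monoisotopic masses sum principal-isotope masses; the electron mass of
  ions is ignored (a 0.0005 Da convention, stated rather than corrected at
  the 1e-4 Da tolerances used).
* Stereo labels are computed once at load by atomic-number/graph-traversal
  priorities and *asserted*, not recomputed, after geometry changes. For
  assertions across protonation changes the package compares geometric
  parities (signed volume over index-ordered neighbors) instead of R/S
  labels, because adding or removing a proton changes substituent
  priorities without inverting any geometry.
* Rotatable bonds: single, acyclic, both endpoints heavy and polyvalent,
  excluding locally symmetric rotors (CH₃) and amide C–N. Ring bonds are
  never rotatable — anomeric configuration is stereochemistry, not a
  torsion. Exocyclic glycosidic C–O bonds (the φ/ψ torsions) and C–OH
  bonds are rotatable.

## Charge enumeration

Site classes are perceived from local graph patterns (hydroxyl, carboxyl,
carbonyl, ether/ring O, amine N, amide N). Negative mode removes the
proton of an O–H/N–H site (formal charge −1); positive mode adds a proton
at 0.96 Å from O (1.01 Å from N) along the lone-pair bisector — the
negative of the sum of unit vectors to bonded neighbors — leaving the rest
of the seed geometry untouched for the relaxation stage to polish. Amide N
protonation is off by default (O-protonation of amides is favored in the
gas phase) and toggleable. Ring/glycosidic oxygens are included as
protonation sites by default; both behaviors are reachable through the
site-class filter. Symmetry-equivalent models are merged by graph
isomorphism on (element, formal charge)-labeled graphs, keeping the lowest
enumeration index. Only singly charged species are modeled: no
zwitterions, adducts, or multiple charging.

## Energy backend

Only *relative* energies enter any selection rule, so the backend contract
is: a consistent energy scale (kcal/mol), a relaxed geometry, and per-atom
partial charges. The built-in surrogate is:

* **UFF** (via RDKit) for single-point energies and relaxation. The
  force-field minimizer runs to a force tolerance (default 1e-4, up to
  2000 steps); a fresh single-point at the final geometry defines the
  reported energy, which makes re-evaluating a minimized structure an
  exact fixed point. UFF types every species this workflow creates,
  including deprotonated O⁻ and ring-protonated O⁺ sugars.
* **Gasteiger–Marsili charges** (partial equalization of orbital
  electronegativity) for the partial charges the trajectory method needs.
  They conserve the net charge exactly and are deterministic. They are a
  classical stand-in for the Mulliken charges a QM engine would provide
  and are labeled as the surrogate scheme in outputs.

The surrogate is validated by invariants, not by matching quantum-chemical
numbers (which a classical potential cannot and should not reproduce):
energy invariance under rigid motion, charge-sum conservation, fixed-point
minimization, determinism, and the monotone/inclusive behavior of the
10 kcal/mol retention window. The window is applied after per-model
relaxation (the alternative — screening single points before relaxation —
is reachable by calling `rank_and_filter` on unrelaxed evaluations).
An adapter hook (`register_backend`) admits external engines that write
their own input decks and parse energies/charges back.

## Conformer generation and clustering

The reference workflow relies on external proprietary tools for these
stages; `glyccs` reimplements their *behavioral contract* — target count,
the >50 clustering rule, representative centers — rather than their
internals, and is documented as a faithful-contract, not bit-compatible,
reimplementation.

* Torsion sampling: each rotatable bond is set to a uniform draw from the
  60°-spaced grid with ±15° jitter (covers sp³ rotamer wells; jitter
  avoids grid artifacts), followed by a short UFF minimization for clash
  relief. All randomness flows from one recorded seed.
* Duplicates are removed at 0.1 Å heavy-atom RMSD after optimal
  (Kabsch/SVD) superposition; hydrogens are excluded because their
  positions are noise after minimization. A radius-of-gyration prefilter
  keeps deduplication near-linear in practice.
* Conformers whose geometric parity differs from the parent (a
  minimization pushed a center through planarity from a clashed start)
  are discarded with a warning — stereochemistry is never sampled.
* Ensembles of ≤50 conformers pass through with every conformer a center.
  Larger ensembles build the pairwise aligned heavy-atom RMSD matrix,
  convert it to affinities exp(−r²/2σ²) with σ the median off-diagonal
  RMSD, and partition the affinity graph by greedy modularity
  maximization (deterministic; resolution 1.0, frozen so that a
  calibration fixture of three synthetic conformer bundles yields exactly
  three clusters). Each cluster's energy minimum is its center, so the
  global minimum is a center by construction.
* Order of operations: generate → cluster → optimize centers → score.
  Clustering acts on unoptimized conformers; only centers receive the
  full relaxation.

## CCS engine

The buffer gas is a single-site isotropic N₂ pseudo-atom: mass
28.0134 Da, polarizability α = 1.710 Å³. The N₂ quadrupole and gas
anisotropy are omitted (stated limitation of the single-site model).

**Projection approximation.** Monte-Carlo average over uniformly random
orientations of the exact area of the union of atom disks of radius
(vdW radius + 1.5 Å probe); circles are polygonized at 256 segments
(≈0.01% area bias). PA is the default screen in the pipeline, mirroring
the cost gradient of the workflow; TM is opt-in per run.

**Trajectory method.** Ω(1,1)(T) = ∫₀^∞ Q(1)(g) γ⁵ e^(−γ²) dγ with
γ = g√(μ/2kT), evaluated by Gauss–Legendre quadrature on γ ∈ [0, 6]
(20 nodes by default, the quadrature interpretation of the "velocity
integration" count) with the weight self-normalized so a hard sphere is
exact. Q(1)(g) = π b_max² ⟨1 − cos χ⟩ by stratified Monte-Carlo sampling
of b² with a per-speed b_max searched adaptively until the deflection at
b_max falls below 1e-3 rad (Ω is sensitive to this bound; for ions the
r⁻⁴ induced-dipole tail pushes b_max to tens of Å). Orientations are
drawn per cycle into a pool of the configured size ("rotations") that the
Monte-Carlo samples cycle through. The solute–gas potential is the
per-element 12-6 term plus the charge-induced-dipole term
−(α/2)|E|² with E the field of the partial charges (Coulomb constant
332.0637 kcal·Å/mol·e²).

Trajectories integrate by velocity-Verlet (numba-compiled) with a
per-trajectory adaptive step: η·min(r_near/|v|, √(r_near·μ/|F|)) — the
far-field transit bound and the local harmonic timescale; a speed-based
bound alone collapses at turning points. η = 0.02, step clipped to
[1e-5, 50] internal time units. Start/stop radius is where |V| drops
below 1e-6 kcal/mol (probed on a 26-direction grid). Energy conservation
is checked per trajectory at 1e-4 relative; violators are retried at η/4
and then excluded and counted (`n_failed_trajectories`) — typically the
long-lived orbiting trajectories, ~1.5% at T* = 1 and bias-checked
against tabulated collision integrals. Per-cycle Ω estimates give the
mean and standard error.

Adopted per-element 12-6 parameters for N₂ (kcal/mol, Å): H (0.0189,
2.38), C (0.1072, 3.55), N (0.1072, 3.55), O (0.1072, 3.50) — a
conventional ion-mobility parameterization consistent in magnitude with
the sets used by trajectory-method CCS codes for N₂; the table is the
package's declared compatibility surface and is user-replaceable through
`GasModel`. Validation: a single neutral Lennard-Jones site reproduces
π σ² Ω*(1,1)(T*) from standard tabulations to ≈0.2% at T* = 1 and 3.

**Mason–Schamp.** Low-field form with the ion–gas reduced mass and the
Loschmidt number density; the inverse is provided and round-trips to
1e-9 relative.

## Scoring

k = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298 K exactly. The population
window is 3.0 kcal/mol, inclusive, with weights renormalized over the
included subset (configurable; the pooled set spans all retained charge
states of a system, whose energies are directly comparable because the
ions are isomers). Percent error is |calc − ref|/ref × 100; the
method-discrepancy statistic %Δ is |a − b|/mean(a, b) × 100, verified
against every printed row of the bundled comparison table. The success
threshold is 3% — the margin that absorbs typical calibration error and
inter-laboratory spread of drift-tube measurements; reference policies:
averaged (default), single, stepped, best-of-methods.

Bundled tables store the printed values verbatim, including the printed
parenthetical errors. One stepped-field error cell (mannohexaose, post-
sampling table) does not recompute from its own CCS columns — the
averaged-column value does — and is flagged `printed_inconsistent`;
recomputed statistics use the CCS columns, so the flag only matters for
verbatim-reproduction checks. Per-row table reproduction: rows whose
computed CCS is printed to two decimals recompute exactly; one-decimal
rows to ±0.06; integer-rounded rows are excluded from that check (their
printed errors derive from unrounded values the tables do not carry).
Aggregate means round half-up to integers, matching the tables'
presentation.

## Pipeline and reproducibility

One global seed fans out to every stochastic stage (fixture geometry,
conformer sampling, CCS orientation draws) through fixed integer offsets
recorded in the manifest, so reruns are byte-identical in the report and
individual stages can be bisected. Manifest timing entries are the only
non-deterministic artifact. Stage order matches the cost gradient:
enumeration → ranking → sampling → clustering → center optimization →
CCS → scoring; skipping clustering for ≤50-conformer ensembles is
observable in the manifest.

## Synthetic fixtures

The fixture families (single sphere, dumbbell, n-alkane, cyclohexane
ring, symmetric diol, a disaccharide-like bicyclic ether with one
hydroxyl per ring) exercise every code path at sizes where the whole
pipeline runs in seconds: an analytic PA answer, a 2+ titratable-site
system, a zero-rotatable-bond system, a symmetry-degenerate enumeration.
Real carbohydrates for tests (glucose, cellobiose, melezitose) are built
at run time from connectivity strings via RDKit distance-geometry
embedding with fixed seeds. What passing on these fixtures does *not*
show: surrogate energetics ranking real glycan charge sites the way DFT
would, conformational coverage of large flexible glycans at the default
1000-conformer target, or CCS accuracy for elements outside the H/C/N/O
parameter table.

## Problem sizes used in tests and the acceptance script

Defaults ship at study scale (1000-conformer target; TM at 10 cycles ×
20 velocity nodes × 500 Monte-Carlo points × 1000 orientations). The test
suite and acceptance script exercise the same code at reduced sizes
chosen as the package's own verification budget: conformer targets of
10–60 on the toy fixtures, TM at 3–4 cycles (the Lennard-Jones
collision-integral check converges to well under its 2% band already at
3 cycles), and PA at 150–10 000 orientations depending on the tolerance
being demonstrated.

## Known limitations

* UFF/Gasteiger energetics are qualitative; charge-site rankings and
  Boltzmann weights on real glycans will differ from QM-based ones. The
  bundled computed-CCS tables came from the original QM-scored study and
  are reproduced as *data*, not recomputed.
* Single-site N₂ without quadrupole; no helium parameterization, no
  hard-sphere scattering variants, no diffuse scattering.
* No ring-pucker enumeration or anomerization; stereochemistry is fixed
  at load.
* No raw arrival-time calibration: the tool starts from CCS values.
* XYZ inputs with net charge require a formal-charge sidecar; the charged
  site cannot be inferred from coordinates.
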
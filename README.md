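# glyccs

Gas-phase structure assignment for glycan ions from ion-mobility
mass-spectrometry (IM-MS) collision cross sections.

## The problem

Biologically relevant glycans are riddled with isomers — anomers (α/β at
the acetal carbon), epimers (glucose vs galactose), and linkage isomers
(1→3 vs 1→4) — that share an *m/z* and defeat plain mass spectrometry.
Drift-tube IM-MS separates them by their collision cross section (CCS, Ω,
in Å²) in N₂, but a measured CCS alone carries no structural detail.
`glyccs` implements the in-silico side of the assignment: it proposes the
gas-phase ion structure whose computed CCS explains the measurement.

The workflow, run per analyte and ion mode:

1. **Charge enumeration** — cycle over every titratable site of a 3D seed
   structure (explicit hydrogens required) to build the [M − H]⁻ or
   [M + H]⁺ candidates, one per hydroxyl/carbonyl/ring-oxygen/amine site.
2. **Energy ranking** — relax each charge model and keep every candidate
   with relative energy RE = E − E_min ≤ 10 kcal/mol (boundary inclusive).
3. **Conformer sampling** — up to 1000 conformers per retained charge
   state by torsion sampling; ensembles above 50 conformers are clustered
   on the pairwise heavy-atom RMSD matrix and only representative centers
   (each cluster's energy minimum) continue.
4. **CCS computation** — projection approximation (PA, fast hard-disk
   screen) or the trajectory method (TM): the momentum-transfer collision
   integral Ω(1,1)(T) from classical trajectories of an N₂ pseudo-atom in
   the potential V(r) = Σᵢ 4εᵢ[(σᵢ/rᵢ)¹² − (σᵢ/rᵢ)⁶] − (α/2)|E(r)|²,
   averaged over Maxwell–Boltzmann relative speeds, orientations and
   impact parameters (defaults: 10 cycles, 20 velocity nodes, 500 Monte
   Carlo impact parameters, 1000 orientations, 298 K).
5. **Boltzmann-weighted scoring** — conformers within ~3 kcal/mol of the
   global minimum are populated at 298 K with mole fractions
   Pᵢ = exp(−REᵢ/kT)/Σⱼ exp(−REⱼ/kT); the reported CCS is Σ PᵢΩᵢ and an
   assignment is *successful* when it agrees with the experimental
   reference within 3%.

Mobility data enter through the low-field Mason–Schamp relation
Ω = (3ze/16N₀)·√(2π/μkT)/K₀, implemented with its inverse.

The package bundles the experimental drift-tube reference tables (stepped-
field and single-field CCS per glycan, with the computed CCS of the
assignment study before and after conformational sampling) and recomputes
every statistic — per-row percent errors, the stepped-vs-single %Δ
discrepancy, success rates under several reference policies — from the CCS
columns at run time.

The energy stage is a pluggable backend. The built-in surrogate (UFF
relaxation + Gasteiger partial charges) makes every stage runnable and
testable on a laptop; it is a classical stand-in for the quantum-chemical
scoring of production studies, and an adapter hook is provided for
external engines.

## Worked example

```bash
python examples/04_reference_tables_scoring.py
```

prints

```
stepped vs single field discrepancy: mean %D = 4.4 over 12 glycans
before sampling: 12/27 within 3% of the averaged reference (44%), 52% against the better method; mean %error (single/stepped/avg) = 3/7/6
after sampling: 14/27 within 3% of the averaged reference (52%), 70% against the better method; mean %error (single/stepped/avg) = 3/5/4
```

The first line quantifies how far the two experimental CCS protocols
disagree with each other (4.4% on average — context for the 3% assignment
threshold). The next two lines are the assignment performance before and
after conformational sampling: sampling lifts the success rate from 12/27
to 14/27 against the averaged reference, and to 70% when each system is
compared against whichever experimental protocol agrees better.

The other examples walk the individual stages:

```bash
python examples/01_charge_models.py            # site enumeration + RE filter
python examples/02_conformers_and_clustering.py
python examples/03_ccs_projection_and_trajectory.py
python examples/05_full_pipeline.py            # end-to-end on a toy fixture
```

`examples/01_charge_models.py`, for instance, ranks the five glucose
deprotonation sites and prints their surrogate relative energies (all
retained by the 10 kcal/mol window):

```
glucose: 24 atoms, 5 deprotonatable hydroxyls
model  site  class        RE(kcal/mol)  retained
  III     7  hydroxyl_O       0.00      True
    V    11  hydroxyl_O       0.07      True
   IV     9  hydroxyl_O       1.00      True
    I     0  hydroxyl_O       1.27      True
   II     5  hydroxyl_O       1.42      True
```

A thin CLI mirrors the library: `glyccs run -c config.yaml`,
`glyccs enumerate`, `glyccs ccs`, `glyccs score`, `glyccs fixture`.

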
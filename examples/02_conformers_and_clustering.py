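"""Sample a conformer ensemble for a glucose anion and reduce it to centers.

Torsion sampling on the rotatable bonds (60-degree grid, +/-15-degree
jitter) with clash-relief minimization; ensembles above 50 conformers are
clustered on the pairwise heavy-atom RMSD matrix and each cluster's energy
minimum becomes a representative center.
"""

from glyccs import fixtures
from glyccs.charge import enumerate_charge_models
from glyccs.conformers import cluster_ensemble, generate_conformers
from glyccs.molecule import find_rotatable_bonds

glucose = fixtures.from_smiles(fixtures.SMILES["glucose"], seed=3, label="glucose")
model = enumerate_charge_models(glucose, "neg")[0]

rot = find_rotatable_bonds(model.molecule)
print(f"{model.label}: {rot.n_rotatable} rotatable bonds")

ens = generate_conformers(model, target=60, seed=7)
summary = cluster_ensemble(ens, threshold_count=50)
print(f"{len(ens.conformers)} distinct conformers after dedup "
      f"-> {summary.n_clusters} {summary.method} centers")
for c in ens.centers:
    print(f"  center: RE = {c.relative_energy:6.2f} kcal/mol (cluster {c.cluster})")

# Only the centers move on to full relaxation and CCS scoring; the RE = 0
# center is the candidate gas-phase geometry for this charge model.
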
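"""Enumerate and rank the deprotonation sites of glucose.

Builds beta-D-glucose, cycles over its five hydroxyls to produce one
[M - H]- charge model per site, relaxes each with the surrogate backend,
and applies the 10 kcal/mol relative-energy retention window.
"""

from glyccs import fixtures
from glyccs.charge import enumerate_charge_models, find_titratable_sites
from glyccs.energy import evaluate, rank_and_filter

glucose = fixtures.from_smiles(fixtures.SMILES["glucose"], seed=3, label="glucose")
sites = find_titratable_sites(glucose, "neg")
print(f"glucose: {glucose.n_atoms} atoms, {len(sites)} deprotonatable hydroxyls")

models = enumerate_charge_models(glucose, "neg")
candidates = rank_and_filter([(m, evaluate(m)) for m in models], window_kcal=10.0)

print("model  site  class        RE(kcal/mol)  retained")
for model, re, keep in zip(candidates.models, candidates.relative_energies, candidates.retained):
    print(f"{model.enum_label:>5}  {model.site.atom_index:>4}  "
          f"{model.site.site_class.value:<12} {re:>8.2f}      {keep}")

# RE = 0 marks the most stable anion site on the surrogate energy scale;
# every model within 10 kcal/mol would proceed to conformer sampling.
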
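#!/usr/bin/env python
"""Infer a minimum-migration seeding history for one patient.

Leaves of the sample phylogeny are labeled with their anatomical site; a
Sankoff small-parsimony pass over site labels (root fixed to the primary)
yields the minimum number of migrations, the seeding edges, and a
seeding-pattern classification.
"""

import metroute as mr
from metroute.migration import infer_migration_labels
from metroute.pipeline import site_label
from metroute.simulate import default_sites

# A genomically-stable (GS) patient where the ovarian metastasis was seeded
# from the peritoneum rather than directly from the primary tumor.
sites = default_sites("GS", chain_seeding=True)
cfg = mr.SimConfig(seed=7, subtype="GS", topology="diaspora", sites=sites)
patient = mr.simulate_patient(cfg, patient_id="DEMO2")

kept = mr.filter_variants(patient.variants, patient.normals)
matrix = mr.build_binary_matrix(kept,
                                list(patient.sample_sheet["sample_id"]))
tree = mr.build_parsimony_tree(matrix)

meta = patient.sample_sheet.set_index("sample_id")
leaf_sites = {sid: site_label(meta.loc[sid])
              for sid in patient.sample_sheet["sample_id"]}
history = infer_migration_labels(tree, leaf_sites)

print(f"sites: {sorted(set(leaf_sites.values()))}")
print(f"minimum migrations: {history.n_migrations}")
print(f"comigrations: {history.n_comigrations}")
print("seeding edges (source -> destination):")
for src, dest in sorted(history.migration_edges):
    print(f"  {src} -> {dest}")
print(f"pattern: {history.pattern.value}")
for site, clon in sorted(history.clonality.items()):
    print(f"clonality[{site}]: {clon.value}")

print()
print("simulated truth edges:")
for src, dest in sorted(patient.truth.true_migration_edges):
    print(f"  {src} -> {dest}")
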
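#!/usr/bin/env python
"""Simulate one multi-region patient and walk through the full analysis.

This is the narrative version of what ``analyze_patient`` does in one call:
filter somatic candidates, build the presence/absence matrix, call the
molecular subtype per sample, reconstruct the sample phylogeny, and classify
the mode of progression.
"""

import metroute as mr

# A chromosomal-instability (CIN) patient with branched progression:
# a long shared trunk, then early divergence of the metastatic lineages.
# Decoy calls (germline leakage, low-quality artifacts) are injected so the
# somatic filter has something to remove.
cfg = mr.SimConfig(seed=42, subtype="CIN", topology="branched",
                   inject_decoys=True)
patient = mr.simulate_patient(cfg, patient_id="DEMO1")

print(f"samples: {sorted(patient.sample_sheet['sample_id'])}")
print(f"raw candidate calls: {len(patient.variants)} rows")

# 1. somatic filtering against the matched normal
kept = mr.filter_variants(patient.variants, patient.normals)
n_raw = patient.variants.groupby(["chrom", "pos0", "ref", "alt"]).ngroups
n_kept = kept.groupby(["chrom", "pos0", "ref", "alt"]).ngroups
print(f"filter: {n_raw} candidate variants -> {n_kept} somatic variants")

# 2. per-sample copy-number subtype calls against the reference panel
from metroute import genome

arms = genome.default_arms()
panel = mr.make_reference_panel(arms)
meta = patient.sample_sheet.set_index("sample_id")
for sid in sorted(patient.sample_sheet["sample_id"]):
    row = meta.loc[sid]
    call = mr.classify_subtype(sid, patient.segments,
                               msi_score=float(row["msi_score"]),
                               ebv_positive=bool(row["ebv_positive"]),
                               arms=arms, reference_panel=panel)
    print(f"subtype[{sid}]: {call.subtype.value} "
          f"(cn burden {call.cn_burden_bp} bp)")

# 3. presence/absence matrix and maximum-parsimony phylogeny
matrix = mr.build_binary_matrix(kept,
                                list(patient.sample_sheet["sample_id"]))
tree = mr.build_parsimony_tree(matrix)
print(f"parsimony score: {mr.parsimony_score(tree, matrix)}")

# 4. trunk metrics and progression call
tm = mr.trunk_metrics(tree)
call = mr.classify_progression(tm)
print(f"trunk ratio: {tm.trunk_ratio:.3f} -> {call.progression.value}"
      f"{' (borderline)' if call.borderline else ''}")
print(f"simulated truth: {patient.truth.true_topology_class}")

print()
print("newick tree:")
print(mr.write_newick(tree))
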
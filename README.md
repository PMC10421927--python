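# metroute

Genomic and evolutionary analysis of multi-region metastatic tumors by
anatomical route.

When a primary tumor and several of its metastases are sequenced (multiple
regions per patient, plus a matched normal), a consistent set of questions
follows: which candidate calls are real somatic mutations, what molecular
subtype is each sample, how similar are the samples to each other, in what
order did the lineages diverge, and which site seeded which metastasis.
`metroute` implements that downstream analysis chain for paired
primary/metastatic whole-exome cohorts, modeled on gastric cancer and its
three main dissemination routes (lymphatic, hematogenous,
peritoneal/ovarian):

- **Somatic variant filtering** — caller-quality thresholds (TLOD ≥ 10,
  MMQ ≥ 60, SEQQ ≥ 20, STRANDQ ≥ 20), matched-normal exclusion (normal
  depth ≥ 10 with zero alt reads), tumor depth ≥ 20 in every sample, and
  VAF ≥ 0.05 in at least one sample.
- **Copy-number subtyping** — genome-wide CN burden (|log2| > 0.3),
  gene-level gain/amplification calls, arm-level alteration calls (66 %
  arm coverage at |log2| > 0.1), and a CIN-vs-GS call by Ward/Euclidean
  clustering of arm profiles against a labeled reference panel, gated by
  MSI (score > 5) and EBV status with TCGA-style precedence.
- **Mutational-signature refitting** — least squares on the probability
  simplex against a bundled catalog; samples with artifact exposure
  strictly above 0.5 are excluded from mutation-based analyses.
- **Genomic distances** — Hamming distance and Jaccard similarity on
  per-sample mutation presence/absence profiles, plus route-ratio
  summaries d(A,B)/d(A,C) − 1.
- **Phylogeny** — maximum-parsimony sample trees rooted at the germline
  (exact search up to 6 leaves), trunk metrics, and a
  branched-vs-diaspora progression call (trunk ratio ≥ 0.3 = branched).
- **Migration history** — Sankoff minimum-migration labeling of the tree
  with the primary at the root, seeding-pattern classification
  (parallel single source / single source / multi source / reseeding) and
  per-site clonality.
- **Cohort statistics** — Mann–Whitney route contrasts (exact enumeration
  at small n without ties) and log-rank survival comparison; raw p-values,
  no multiplicity adjustment.
- **Simulator** — a clonal-evolution cohort simulator with full ground
  truth (trunk/shared/private mutations, migration edges, subtype,
  artifact samples, decoy calls) used to validate every stage end to end.

## Worked example

`examples/simulate_and_classify.py` simulates one chromosomal-instability
(CIN) patient with branched progression and runs each stage explicitly:

```python
import metroute as mr
from metroute import genome

cfg = mr.SimConfig(seed=42, subtype="CIN", topology="branched",
                   inject_decoys=True)
patient = mr.simulate_patient(cfg, patient_id="DEMO1")

kept = mr.filter_variants(patient.variants, patient.normals)

arms = genome.default_arms()
panel = mr.make_reference_panel(arms)
meta = patient.sample_sheet.set_index("sample_id")
for sid in sorted(patient.sample_sheet["sample_id"]):
    row = meta.loc[sid]
    call = mr.classify_subtype(sid, patient.segments,
                               msi_score=float(row["msi_score"]),
                               ebv_positive=bool(row["ebv_positive"]),
                               arms=arms, reference_panel=panel)

matrix = mr.build_binary_matrix(kept, list(patient.sample_sheet["sample_id"]))
tree = mr.build_parsimony_tree(matrix)
call = mr.classify_progression(mr.trunk_metrics(tree))
```

Running it prints:

```
samples: ['DEMO1-LN31', 'DEMO1-LN81', 'DEMO1-liver1', 'DEMO1-liver2', 'DEMO1-primary1', 'DEMO1-primary2', 'DEMO1-primary3']
raw candidate calls: 2877 rows
filter: 411 candidate variants -> 407 somatic variants
subtype[DEMO1-LN31]: CIN (cn burden 560000000 bp)
subtype[DEMO1-liver1]: CIN (cn burden 840140000 bp)
...
parsimony score: 407
trunk ratio: 0.600 -> branched
simulated truth: branched

newick tree:
((((((DEMO1-LN31:45,DEMO1-LN81:45):0,(DEMO1-liver1:60,DEMO1-liver2:60):30):0,DEMO1-primary1:30):0,DEMO1-primary2:30):0,DEMO1-primary3:30):77);
```

The four injected decoy variants (germline leakage and low-quality calls)
are removed by the filter; all seven samples are called CIN, with the
hematogenous liver samples carrying the highest copy-number burden; and the
recovered trunk ratio of 0.600 matches the simulated branched topology.

The other example scripts cover migration-history inference
(`migration_history.py` — recovers the simulated
`primary -> peritoneal -> ovarian` seeding chain exactly),
signature refitting and artifact exclusion (`signature_refitting.py` — a
0.70/0.30 mixture of 500 mutations refits to 0.684/0.309, and the two
artifact-spiked liver samples are flagged at exposures 0.742 and 0.748),
and genomic distances (`route_distances.py` — mean within-patient Jaccard
0.450 for branched vs 0.070 for diaspora patients, Mann–Whitney
p = 0.0013).

## Command line

The same stages are available as a thin CLI over the library:

```bash
metroute simulate --seed 42 --out patient1/
metroute filter --variants patient1/variants.tsv --normals patient1/normals.tsv --out kept.tsv
metroute subtype --segments patient1/segments.tsv --samples patient1/samples.tsv --out subtypes.json
metroute signatures --variants kept.tsv --out exposures.json
metroute distances --variants patient1/variants.tsv --normals patient1/normals.tsv --out-prefix dist
metroute phylo --variants patient1/variants.tsv --normals patient1/normals.tsv --out tree.nwk
metroute migrate --variants patient1/variants.tsv --normals patient1/normals.tsv --samples patient1/samples.tsv --out migration.json
metroute run --seed 7 --n-patients 4 --out run1/   # full cohort pipeline
metroute report --run-dir run1/                    # human-readable summary
```

`metroute run` writes one Newick tree, migration JSON and summary JSON per
patient plus `cohort_report.json` and `cohort_summary.tsv`; runs are
byte-identical for the same seed and configuration.

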
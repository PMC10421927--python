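# Methods

This document describes the analysis model implemented by `metroute`, the
default parameters and why they were chosen, the simulator's scope, and the
main numerical/design decisions. The package targets paired
primary/metastatic whole-exome cohorts with multiple regions per patient
and a matched normal, organized around the three dissemination routes of
gastric cancer: lymphatic (lymph-node stations), hematogenous (liver,
lung, ...), and transcoelomic (peritoneum and ovary).

## Input model

Per patient, four tab-separated tables (readers/writers in `metroute.io`):

- `variants.tsv` — one row per candidate variant observation per tumor
  sample: `patient_id, sample_id, chrom, pos (1-based), ref, alt, depth,
  alt_count, vaf, tlod, mmq, seqq, strandq, gene, effect`. In memory
  positions become 0-based (`pos0`); a variant is identified across samples
  by the key `chrom:pos(1-based):ref:alt`.
- `normals.tsv` — matched-normal depth and alt count at each candidate
  locus.
- `segments.tsv` — per-sample copy-number segments with `log2_ratio` and
  `total_cn`; half-open intervals in memory, 1-based inclusive on disk.
- `samples.tsv` — sample sheet: `site_class` (primary / lymphatic /
  hematogenous / peritoneal / ovarian), lymph-node station, organ,
  `msi_score`, `ebv_positive`.

All file errors report the offending file and line.

## Somatic variant filtering

A variant (patient-level key) survives only if every rule holds:

| rule | threshold |
| --- | --- |
| Mutect2 TLOD | ≥ 10 |
| median mapping quality (MMQ) | ≥ 60 |
| sequencing quality (SEQQ) | ≥ 20 |
| strand quality (STRANDQ) | ≥ 20 |
| matched normal | depth ≥ 10 and 0 alt reads |
| tumor depth | ≥ 20 in **every** sample of the patient |
| VAF | ≥ 0.05 in **at least one** sample |

Quality metrics are caller-level per variant, so the maximum over samples
with `alt_count > 0` is used (the caller emits one call per variant; rows
without supporting reads are genotyping back-fills and carry no call
quality). Filtering is key-level: if a variant survives, its zero-alt rows
in other samples are kept, so downstream presence/absence is decided per
sample. A variant is *present* in a sample when `vaf ≥ 0.05` and
`alt_count ≥ 3`.

## Copy-number analysis and molecular subtyping

- **CN burden** — total genomic span (bp) of segments with
  `|log2_ratio| > 0.3` (strict).
- **Gene-level status** — the segment covering the gene midpoint; a total
  CN change over the sample ploidy of more than +1 is a gain, more than +4
  an amplification, less than −1 a loss.
- **Arm calls** — an arm is called gained (lost) when at least 66 % of its
  length lies in segments with `log2_ratio > 0.1` (`< −0.1`, both strict).
- **MSI** — score strictly above 5 is MSI-high; a missing score defaults
  to MSS with a warning.
- **Subtype precedence** — MSI-high first, then EBV positivity, then
  CIN-vs-GS: the sample's arm-level log2 profile is clustered (Ward
  linkage, Euclidean distance, two clusters) jointly with a labeled
  reference panel of CIN and GS exemplars; the cluster with the higher
  mean profile burden is CIN. The bundled panel (`make_reference_panel`)
  is a deterministic synthetic stand-in for a public gastric-cancer panel:
  CIN exemplars alter 9–15 of the 15 recurrent gastric arms (1q, 3q, 5p,
  6p, 7p, 7q, 8q, 13q, 20p, 20q gained; 4q, 9p, 17p, 18q, 21q lost) in
  their canonical direction, GS exemplars are near-flat. Joint clustering
  of CIN profiles works *because* real CIN tumors share those recurrent
  arms; the recurrent-arm set is therefore part of the model, shared
  between the panel and the simulator (`genome.RECURRENT_ARM_EVENTS`).
- **De novo driver events** — gene-level gains/amplifications and driver
  point mutations seen in a metastasis but in no primary region;
  an amplification in a metastasis subsumes a mere gain in the primary.

## Mutational signatures

Mutations are folded to the 96 pyrimidine-centered trinucleotide contexts.
Exposures are refit against a fixed catalog by least squares on the
probability simplex (SLSQP; exposures ≥ 0, summing to 1) — refitting, not
de novo extraction, is appropriate at per-sample mutation counts of a few
hundred. The bundled catalog holds SBS1-like, SBS5-like, SBS10b-like, a
flat background, and an oxidative-artifact signature. A sample whose
artifact exposure is **strictly greater than 0.5** is excluded from all
mutation-based analyses (matrix, distances, tree, migration); the boundary
is exclusive so a sample at exactly 0.5 is retained.

## Distances

On per-sample presence/absence profiles: Hamming distance (symmetric
difference count) and Jaccard similarity (intersection over union; two
empty profiles give 1 with a warning). The identity
`J = 1 − d_H/|A ∪ B|` ties the two and is enforced by tests. Route ratios
`d(A,B)/d(A,C) − 1` quantify, per patient, whether B or C is genomically
closer to anchor A. The per-patient summary `mean_jaccard` (mean
off-diagonal Jaccard) separates branched from diaspora progression.

## Phylogeny and progression mode

Trees are maximum-parsimony over binary mutation profiles with the germline
(all-absent) fixed above the root. Fitch/Sankoff scoring is vectorized over
variants; for ≤ 6 leaves all (2n−3)!! rooted topologies are scored
exhaustively (exactness is tested against an independent oracle), beyond
that stepwise addition plus NNI hill-climbing. Edge lengths are the number
of mutations assigned to the edge.

`trunk_ratio` = trunk length / mean root-to-leaf path length. A patient is
**branched** when trunk_ratio ≥ 0.3 (long shared trunk, late divergence)
and **diaspora** otherwise (early parallel dissemination); calls within
±0.05 of the threshold are flagged borderline.

## Migration history

Leaves carry their anatomical site; internal nodes are labeled by Sankoff
parsimony with unit migration costs and the root fixed to the primary.
Ties are broken toward the parent's label, then the primary, then
lexicographically — biased deliberately toward the most parsimonious
biological default (seeding from the primary). Label-changing edges are
migrations; distinct (source, destination) pairs define the seeding
pattern:

- *parallel single source* — all metastases seeded directly from the
  primary;
- *single source* — every site has one source but seeding is chained
  (metastasis-to-metastasis);
- *multi source* — some site receives migrations from multiple sources;
- *reseeding* — any cycle, e.g. metastasis back to primary.

A destination seeded by more than one migration (from one source or
several) is polyclonal, otherwise monoclonal.

## Statistics

Route contrasts use the two-sided Mann–Whitney U test, with exact
enumeration when the combined sample size is ≤ 12 and there are no ties,
and the tie-corrected normal approximation otherwise; Welch's t-test is
selectable. Survival uses the log-rank test (lifelines). All p-values are
reported raw, with `no_multiplicity_adjustment: true` recorded in the
cohort report.

## Simulator

`metroute.simulate` generates cohorts with complete ground truth and is
first-class, tested code. Per patient:

- **Clone structure** — germline → founder (trunk mutations) → one
  site-founder clone per metastatic site (site-shared mutations) →
  one private clone per sample. Chained seeding attaches a site's founder
  under the last sample clone of the source site, which makes the seeding
  chain recoverable by the migration solver.
- **Trunk length** — derived from `trunk_fraction` (default 0.6 branched /
  0.1 diaspora) and the realized mean private path length, so the
  recovered trunk_ratio matches the configured fraction by construction at
  high depth.
- **Reads** — depths Poisson around `depth_mean` (150), alt counts
  binomial with expected VAF `purity / (purity·cn + 2(1−purity))` at the
  local total copy number (purity 0.7 → ≈ 0.35 at cn 2). Normals are
  clean with depth ≥ 11. Optional decoys (germline leakage, low-quality
  calls) violate exactly one filter rule each.
- **Copy number** — CIN patients draw clonal arm events over the recurrent
  gastric arm set in the canonical direction (rate 0.6, floor of 8
  recurrent events) plus sporadic arms at 0.15× that rate; hematogenous
  samples add further arm events (rate 0.45) and focal amplifications of
  driver genes (total CN 8). Arm gains use total CN 3, below the
  gene-level gain threshold, so focal amplifications are the only
  gene-level gain/amp events and de novo driver recovery is exact. GS
  patients are near-flat (one clonal arm event). The CIN rates reflect the
  defining property of the subtype — high, recurrent aneuploidy — and make
  subtype recovery a test of the clustering rule rather than of borderline
  profiles.
- **Route effects** — per-site mutation-rate scaling (site founder and
  private clones): hematogenous ×2.0 under CIN, peritoneal/ovarian ×0.4
  under GS, reproducing the directional route contrasts. De novo driver
  point mutations are injected in peritoneal/ovarian sites under GS.
- **Signatures** — mutation contexts drawn from a configurable mixture
  (default 0.25 SBS1-like / 0.60 SBS5-like / 0.15 SBS10b-like); artifact
  sites draw ~75 % of contexts from the artifact signature.
- **Determinism** — all child seeds derive from
  `numpy.random.SeedSequence(seed, spawn_key=(i,))`, reduced mod 2³¹;
  the same seed yields byte-identical pipeline output bundles.

**Scope and limits.** The simulator models clone structure, read counts,
arm/focal copy number, signatures and seeding topology. It does not model
subclonal copy-number interplay with VAF (expected VAF uses local total CN
only), kataegis/clustered mutations, sequencing error in normals, purity
variation between regions of one sample, or indel realignment artifacts.
Site-level effects are piecewise-constant scalings, not a mechanistic
mutation-rate model.

## Numerical and design decisions

- All thresholds are strict or non-strict exactly as stated above;
  boundary behavior is pinned by fixture tests (a variant exactly at every
  filter boundary survives; artifact exposure exactly 0.5 is retained).
- Exact parsimony and exact migration labeling are verified against
  independent exhaustive oracles in the test suite (all rooted topologies;
  all kᵐ internal site labelings).
- JSON outputs are written with sorted keys and fixed indentation; TSVs
  with fixed column order — byte-identical reruns are a tested guarantee.
- Newick IO delegates to dendropy; statistics delegate to scipy and
  lifelines rather than reimplementing them.
- No multiple-testing adjustment is applied anywhere; consumers see raw
  p-values and the cohort report says so explicitly.

## Limitations

- The reference panel is synthetic; on real data, substitute a real
  labeled arm-profile panel (same DataFrame shape, `label` column) for
  `make_reference_panel(arms)`.
- The progression threshold (trunk ratio 0.3) and borderline margin
  (±0.05) are fixed conventions, not fitted quantities.
- Migration inference assumes the sample tree is correct and sites are
  monophyletically sampled enough for parsimony labeling; heavily mixed
  sites with single samples can be ambiguous (ties resolve toward the
  primary).
- Exact tree search is limited to 6 leaves; beyond that the heuristic may
  return a near-optimal tree (the parsimony score is still reported).
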
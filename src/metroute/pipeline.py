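"""End-to-end orchestration: filter -> matrix -> subtyping -> signatures
-> distances -> phylogeny -> migration -> cohort comparisons.

`analyze_patient` runs the per-patient stages on in-memory tables;
`run_pipeline` drives a whole cohort (simulated or loaded from disk) and
writes a report bundle: per-patient newick trees, migration histories
and summaries, cohort tables, and a run log.  All stages are pure
functions of their inputs plus the seed, so re-running with the same
configuration produces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome
from .distances import (
    DistanceMatrix,
    SimilarityMatrix,
    jaccard_matrix,
    mean_patient_jaccard,
    pairwise_distance,
)
from .io import (
    build_binary_matrix,
    filter_variants,
    read_normal_table,
    read_sample_sheet,
    read_segments,
    read_variant_table,
)
from .migration import infer_migration_labels
from .phylogeny import (
    PhyloTree,
    ProgressionCall,
    build_parsimony_tree,
    classify_progression,
    trunk_metrics,
    write_newick,
)
from .signatures import (
    SignatureCatalog,
    context_count_vector,
    default_catalog,
    flag_artifact_samples,
    refit_signature_exposures,
)
from .simulate import SimConfig, simulate_cohort, simulate_survival
from .stats import logrank_test, route_comparison
from .subtyping import (
    SubtypeCall,
    classify_subtype,
    de_novo_driver_events,
    make_reference_panel,
    sample_driver_events,
)
from .types import (
    NONSYNONYMOUS_EFFECTS,
    FilterConfig,
    MigrationHistory,
    SiteClass,
    TrunkMetrics,
)

__version__ = "0.1.0"


def site_label(row: pd.Series) -> str:
    """Anatomical site label for migration inference, from sample metadata."""
    sc = row["site_class"]
    if sc == SiteClass.PRIMARY.value:
        return "primary"
    if sc == SiteClass.LYMPH_NODE.value:
        return f"LN{int(row['ln_station'])}"
    if sc == SiteClass.HEMATOGENOUS.value:
        organ = row.get("organ", "NA")
        return organ if organ and organ != "NA" else "hematogenous"
    return sc  # peritoneal / ovarian


@dataclass
class PatientResult:
    patient_id: str
    filtered_variants: pd.DataFrame
    n_variants_raw: int
    n_variants_filtered: int
    subtype_calls: dict[str, SubtypeCall]
    exposures: dict[str, dict[str, float]]
    excluded_samples: list[str]
    distance: DistanceMatrix
    similarity: SimilarityMatrix
    mean_jaccard: float
    tree: PhyloTree
    trunk: TrunkMetrics
    progression: ProgressionCall
    migration: MigrationHistory
    de_novo_events: list
    nonsyn_counts: dict[str, int]
    sample_sites: dict[str, str]
    site_classes: dict[str, str]

    def summary_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "n_variants_raw": self.n_variants_raw,
            "n_variants_filtered": self.n_variants_filtered,
            "excluded_samples": sorted(self.excluded_samples),
            "subtypes": {s: c.subtype.value
                         for s, c in sorted(self.subtype_calls.items())},
            "cn_burden_bp": {s: c.cn_burden_bp
                             for s, c in sorted(self.subtype_calls.items())},
            "ploidy": {s: c.ploidy for s, c in sorted(self.subtype_calls.items())},
            "nonsyn_counts": dict(sorted(self.nonsyn_counts.items())),
            "mean_jaccard": self.mean_jaccard,
            "trunk_len": self.trunk.trunk_len,
            "trunk_ratio": self.trunk.trunk_ratio,
            "progression": self.progression.progression.value,
            "progression_borderline": self.progression.borderline,
            "migration": {
                "n_migrations": self.migration.n_migrations,
                "n_comigrations": self.migration.n_comigrations,
                "pattern": self.migration.pattern.value,
                "clonality": {k: v.value
                              for k, v in sorted(self.migration.clonality.items())},
                "edges": sorted(map(list, self.migration.migration_edges)),
            },
            "de_novo_events": sorted(
                (dataclasses.asdict(e) for e in self.de_novo_events
                 if e.de_novo),
                key=lambda d: (d["sample_id"], d["gene"], d["kind"]),
            ),
        }


def analyze_patient(variants: pd.DataFrame, normals: pd.DataFrame,
                    segments: pd.DataFrame, sample_sheet: pd.DataFrame,
                    *,
                    filter_config: FilterConfig | None = None,
                    arms: pd.DataFrame | None = None,
                    reference_panel: pd.DataFrame | None = None,
                    catalog: SignatureCatalog | None = None,
                    gene_intervals: pd.DataFrame | None = None,
                    driver_list: list[str] | None = None) -> PatientResult:
    """Run every per-patient analysis stage on in-memory tables."""
    filter_config = filter_config or FilterConfig()
    arms = arms if arms is not None else genome.default_arms()
    if reference_panel is None:
        reference_panel = make_reference_panel(arms)
    catalog = catalog or default_catalog()
    gene_intervals = (gene_intervals if gene_intervals is not None
                      else genome.default_gene_intervals())
    driver_list = driver_list or genome.default_driver_list()

    patient_id = str(variants["patient_id"].iloc[0])
    tumor_samples = sorted(sample_sheet.loc[
        sample_sheet["site_class"] != SiteClass.NORMAL.value, "sample_id"])

    filtered = filter_variants(variants, normals, filter_config)

    # signature exposures and artifact exclusion
    exposures = {}
    exposure_vectors = []
    for sid in tumor_samples:
        counts = context_count_vector(filtered, sid)
        if counts.sum() == 0:
            continue
        ev = refit_signature_exposures(counts, catalog, sample_id=sid)
        exposures[sid] = ev.exposures
        exposure_vectors.append(ev)
    excluded = sorted(flag_artifact_samples(exposure_vectors, catalog))
    kept_samples = [s for s in tumor_samples if s not in excluded]

    kept_variants = filtered[filtered["sample_id"].isin(kept_samples)]
    matrix = build_binary_matrix(kept_variants, kept_samples, filter_config)

    dist = pairwise_distance(matrix)
    sim = jaccard_matrix(matrix)
    mean_j = mean_patient_jaccard(sim, kept_samples)

    tree = build_parsimony_tree(matrix)
    trunk = trunk_metrics(tree)
    progression = classify_progression(trunk)

    meta = sample_sheet.set_index("sample_id")
    sample_sites = {sid: site_label(meta.loc[sid]) for sid in tumor_samples}
    site_classes = {sid: str(meta.loc[sid, "site_class"])
                    for sid in tumor_samples}
    leaf_sites = {sid: sample_sites[sid] for sid in kept_samples}
    migration = infer_migration_labels(tree, leaf_sites, primary_site="primary")

    # per-sample molecular subtype
    subtype_calls = {}
    for sid in tumor_samples:
        row = meta.loc[sid]
        subtype_calls[sid] = classify_subtype(
            sid, segments, msi_score=float(row["msi_score"]),
            ebv_positive=bool(row["ebv_positive"]),
            arms=arms, reference_panel=reference_panel)

    # de novo driver events in metastases
    primary_samples = [s for s in tumor_samples
                       if site_classes[s] == SiteClass.PRIMARY.value]
    met_samples = [s for s in tumor_samples
                   if site_classes[s] != SiteClass.PRIMARY.value]
    primary_events = pd.concat(
        [sample_driver_events(filtered, segments, s, gene_intervals, driver_list)
         for s in primary_samples],
        ignore_index=True) if primary_samples else pd.DataFrame(
            columns=["sample_id", "gene", "kind"])
    met_events = pd.concat(
        [sample_driver_events(filtered, segments, s, gene_intervals, driver_list)
         for s in met_samples],
        ignore_index=True) if met_samples else pd.DataFrame(
            columns=["sample_id", "gene", "kind"])
    events = de_novo_driver_events(primary_events, met_events, driver_list)

    nonsyn = {
        sid: int(((filtered["sample_id"] == sid)
                  & (filtered["alt_count"] > 0)
                  & filtered["effect"].isin(NONSYNONYMOUS_EFFECTS)).sum())
        for sid in tumor_samples
    }

    n_keys = lambda df: df.groupby(  # noqa: E731
        ["chrom", "pos0", "ref", "alt"]).ngroups if not df.empty else 0
    return PatientResult(
        patient_id=patient_id,
        filtered_variants=filtered,
        n_variants_raw=n_keys(variants),
        n_variants_filtered=n_keys(filtered),
        subtype_calls=subtype_calls,
        exposures=exposures,
        excluded_samples=excluded,
        distance=dist,
        similarity=sim,
        mean_jaccard=mean_j,
        tree=tree,
        trunk=trunk,
        progression=progression,
        migration=migration,
        de_novo_events=events,
        nonsyn_counts=nonsyn,
        sample_sites=sample_sites,
        site_classes=site_classes,
    )


@dataclass
class PipelineConfig:
    """Cohort run configuration: either a simulation block or a list of
    patient input directories (each holding variants.tsv, normals.tsv,
    segments.tsv, samples.tsv)."""

    seed: int = 0
    n_patients: int = 4
    branched_fraction: float = 0.5
    cin_fraction: float = 0.5
    sim: SimConfig | None = None
    input_dirs: list[str] = field(default_factory=list)
    with_survival: bool = True


def _load_patient_tables(d: Path):
    for name in ("variants.tsv", "normals.tsv", "segments.tsv", "samples.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing required input {d / name}")
    return (read_variant_table(d / "variants.tsv"),
            read_normal_table(d / "normals.tsv"),
            read_segments(d / "segments.tsv"),
            read_sample_sheet(d / "samples.tsv"))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full cohort pipeline and write the report bundle.

    Returns the cohort report dictionary.  Deterministic: the same
    configuration and seed give a byte-identical bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truths = {}
    survival = None
    if config.input_dirs:
        tables = [_load_patient_tables(Path(d)) for d in config.input_dirs]
    else:
        patients = simulate_cohort(
            config.n_patients, config.sim, seed=config.seed,
            branched_fraction=config.branched_fraction,
            cin_fraction=config.cin_fraction)
        tables = [(p.variants, p.normals, p.segments, p.sample_sheet)
                  for p in patients]
        truths = {p.patient_id: p.truth for p in patients}
        if config.with_survival:
            survival = simulate_survival(patients, seed=config.seed)

    results: list[PatientResult] = []
    for variants, normals, segments, sheet in tables:
        res = analyze_patient(variants, normals, segments, sheet)
        results.append(res)
        write_newick(res.tree, outdir / f"{res.patient_id}.nwk")
        (outdir / f"{res.patient_id}.migration.json").write_text(
            json.dumps(res.summary_dict()["migration"], indent=1,
                       sort_keys=True) + "\n")
        (outdir / f"{res.patient_id}.summary.json").write_text(
            json.dumps(res.summary_dict(), indent=1, sort_keys=True) + "\n")

    report = cohort_report(results, survival=survival, truths=truths)
    report["run_log"] = {
        "seed": config.seed,
        "n_patients": len(results),
        "version": __version__,
        "stages": ["filter", "matrix", "subtyping", "signatures",
                   "distances", "phylogeny", "migration", "comparisons"],
    }
    (outdir / "cohort_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n")

    rows = [r.summary_dict() for r in results]
    cohort_df = pd.DataFrame([{
        "patient_id": r["patient_id"],
        "progression": r["progression"],
        "trunk_ratio": r["trunk_ratio"],
        "mean_jaccard": r["mean_jaccard"],
        "pattern": r["migration"]["pattern"],
        "n_migrations": r["migration"]["n_migrations"],
    } for r in rows])
    cohort_df.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    return report


def cohort_report(results: list[PatientResult],
                  survival: pd.DataFrame | None = None,
                  truths: dict | None = None) -> dict:
    """Cohort-level route comparisons and (optional) recovery scores."""
    report: dict = {"patients": {r.patient_id: r.summary_dict()["progression"]
                                 for r in results}}

    # copy-number burden: hematogenous vs primary samples
    burden_values, burden_labels = {}, {}
    count_values, count_labels = {}, {}
    for r in results:
        for sid, call in r.subtype_calls.items():
            burden_values[sid] = float(call.cn_burden_bp)
            burden_labels[sid] = r.site_classes[sid]
        for sid, n in r.nonsyn_counts.items():
            count_values[sid] = float(n)
            count_labels[sid] = r.site_classes[sid]

    def maybe_compare(values, labels, a, b, name):
        try:
            c = route_comparison(values, labels, a, b, metric_name=name)
        except ValueError:
            return None
        return dataclasses.asdict(c)

    report["comparisons"] = {
        "cn_burden_hematogenous_vs_primary": maybe_compare(
            burden_values, burden_labels, SiteClass.HEMATOGENOUS.value,
            SiteClass.PRIMARY.value, "cn_burden_bp"),
        "nonsyn_peritoneal_vs_primary": maybe_compare(
            count_values, count_labels, SiteClass.PERITONEAL.value,
            SiteClass.PRIMARY.value, "nonsyn_count"),
        "nonsyn_ovarian_vs_primary": maybe_compare(
            count_values, count_labels, SiteClass.OVARIAN.value,
            SiteClass.PRIMARY.value, "nonsyn_count"),
    }

    # mean Jaccard by inferred progression class
    j_values = {r.patient_id: r.mean_jaccard for r in results}
    j_labels = {r.patient_id: r.progression.progression.value for r in results}
    report["comparisons"]["jaccard_branched_vs_diaspora"] = maybe_compare(
        j_values, j_labels, "branched", "diaspora", "mean_jaccard")

    if survival is not None and survival["event"].any() \
            and survival["progression"].nunique() > 1:
        stat, p = logrank_test(survival, "progression")
        report["survival_logrank"] = {"statistic": stat, "p_value": p}

    if truths:
        correct = sum(
            1 for r in results
            if truths[r.patient_id].true_topology_class
            == r.progression.progression.value)
        report["progression_recovery"] = correct / len(results)
    report["no_multiplicity_adjustment"] = True
    return report
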
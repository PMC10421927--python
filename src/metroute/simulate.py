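"""Clonal-evolution cohort simulator with full ground truth.

Each simulated patient carries a known clone tree, molecular subtype,
migration graph and de novo driver events, so every downstream stage
(filtering, subtyping, signature refitting, distances, phylogeny,
migration inference) can be scored against truth.

Clone model
-----------
germline -> founder (trunk mutations, clonal in every tumor sample) ->
per-site founder clones (site-shared mutations) -> per-sample clones
(sample-private mutations).  A metastatic site seeded from another
metastatic site attaches below the last sample clone of its source, so
its samples are nested inside the source site's clade; with two or more
source samples this makes the seeding source identifiable by
minimum-migration labeling.

Route-specific effects emulate the contrasts observed in metastatic
gastric cancer: chromosomally unstable (CIN) patients accumulate
arm-level copy-number events — more in hematogenous samples — and focal
driver amplifications private to hematogenous sites, while genomically
stable (GS) patients stay copy-number quiet (a single clonal arm event)
and instead acquire de novo driver point mutations in peritoneal/ovarian
sites, which also carry fewer private mutations overall.

Read counts are binomial with expected VAF
``purity * ccf * m / (purity * cn_t + 2 (1 - purity))`` with one mutated
copy (m = 1), clonal mutations (ccf = 1) and the sample's local total
copy number ``cn_t``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome
from .io import (
    variant_key,
    write_normal_table,
    write_sample_sheet,
    write_segments,
    write_variant_table,
)
from .signatures import CONTEXTS_96, default_catalog
from .types import STATION_TIER, SiteClass, Subtype, Topology

_EFFECTS = ["missense", "nonsense", "splice_site", "nonstop", "indel", "synonymous"]
_EFFECT_PROBS = [0.74, 0.06, 0.02, 0.005, 0.06, 0.115]

#: default per-site mutation-rate scaling by subtype and route, applied to
#: both the site founder's shared mutations and each sample's private
#: mutations; reproduces the direction of the route contrasts (more
#: nonsynonymous mutations in hematogenous metastases under CIN, fewer in
#: peritoneal/ovarian metastases under GS).
DEFAULT_ROUTE_PRIVATE_SCALE = {
    Subtype.CIN.value: {SiteClass.HEMATOGENOUS.value: 2.0},
    Subtype.GS.value: {SiteClass.PERITONEAL.value: 0.4,
                       SiteClass.OVARIAN.value: 0.4},
}


@dataclass
class SiteSpec:
    """One anatomical site and how it was seeded."""

    name: str
    site_class: str
    n_samples: int = 1
    layers: list[str] | None = None          # primary only
    ln_station: int | None = None            # lymph node only
    organ: str | None = None
    seed_from: str | None = None             # None for primary, else site name
    private_scale: float | None = None       # site mutation-rate scale;
                                             # overrides subtype/route default
    artifact: bool = False                   # inject artifact calls in samples


@dataclass
class SimConfig:
    """Per-patient simulation parameters.

    ``trunk_fraction`` is the target ratio of trunk length to mean
    root-to-leaf path length (long trunk = branched progression, short
    trunk = diaspora); the trunk mutation count is derived from it unless
    ``n_clonal_mut`` is given explicitly.
    """

    topology: str = Topology.BRANCHED.value
    subtype: str = Subtype.CIN.value
    n_clonal_mut: int | None = None
    n_private_mut_per_site: int = 30
    n_site_shared_mut: int | None = None     # default: half the private count
    trunk_fraction: float | None = None      # default 0.6 branched / 0.1 diaspora
    sites: list[SiteSpec] = field(default_factory=list)
    depth_mean: int = 150
    purity: float = 0.7
    cin_clonal_arm_rate: float = 0.6
    cin_min_clonal_events: int = 8
    cin_arm_event_rate: float = 0.12
    cin_hema_arm_event_rate: float = 0.45
    gs_n_clonal_arm_events: int = 1
    focal_amp_rate: float = 1.5
    de_novo_mut_rate: float = 1.0
    driver_genes: list[str] = field(default_factory=genome.default_driver_list)
    sig_mixture: dict[str, float] = field(default_factory=lambda: {
        "SBS1_like": 0.25, "SBS5_like": 0.60, "SBS10b_like": 0.15,
    })
    inject_decoys: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trunk_fraction is None:
            self.trunk_fraction = 0.6 if self.topology == Topology.BRANCHED.value else 0.1
        if not (0.0 <= self.trunk_fraction <= 1.0):
            raise ValueError("trunk_fraction must lie in [0,1]")
        if self.n_site_shared_mut is None:
            self.n_site_shared_mut = self.n_private_mut_per_site // 2
        if not self.sites:
            self.sites = default_sites(self.subtype)
        classes = {s.site_class for s in self.sites}
        if SiteClass.PRIMARY.value not in classes:
            raise ValueError("config must include a primary site")
        if classes <= {SiteClass.PRIMARY.value}:
            raise ValueError("config must include at least one metastatic site")


def default_sites(subtype: str, chain_seeding: bool = False) -> list[SiteSpec]:
    """Default anatomical layout.

    Three primary regions by invasion layer (T1a/b, T2, T3) and two lymph
    nodes (stations #3 = D1 and #8 = D2).  CIN patients add two
    hematogenous samples (liver); GS patients add two peritoneal samples
    and one ovarian sample.  With ``chain_seeding`` the ovarian site is
    seeded from the peritoneal site instead of the primary tumor.
    """
    sites = [
        SiteSpec("primary", SiteClass.PRIMARY.value, n_samples=3,
                 layers=["T1ab", "T2", "T3"]),
        SiteSpec("LN3", SiteClass.LYMPH_NODE.value, ln_station=3,
                 seed_from="primary"),
        SiteSpec("LN8", SiteClass.LYMPH_NODE.value, ln_station=8,
                 seed_from="primary"),
    ]
    if subtype == Subtype.CIN.value:
        sites.append(SiteSpec("liver", SiteClass.HEMATOGENOUS.value,
                              n_samples=2, organ="liver", seed_from="primary"))
    else:
        sites.append(SiteSpec("peritoneal", SiteClass.PERITONEAL.value,
                              n_samples=2, organ="peritoneum",
                              seed_from="primary"))
        sites.append(SiteSpec(
            "ovarian", SiteClass.OVARIAN.value, organ="ovary",
            seed_from="peritoneal" if chain_seeding else "primary"))
    return sites


@dataclass
class GroundTruth:
    """Everything the simulator knows; the recovery oracle."""

    patient_id: str
    clone_parent: dict[str, str | None]
    clone_site: dict[str, str]
    clone_mutations: dict[str, list[str]]
    sample_clone_map: dict[str, str]
    sample_site: dict[str, str]
    site_class: dict[str, str]
    true_topology_class: str
    true_subtype_per_sample: dict[str, str]
    true_migration_edges: list[tuple[str, str]]
    true_de_novo_events: list[dict]
    trunk_mutations: list[str]
    artifact_samples: list[str]
    trunk_fraction: float

    def sample_mutation_set(self, sample_id: str) -> set[str]:
        """Ancestral mutation union for a sample's clone (true presence)."""
        muts: set[str] = set()
        node: str | None = self.sample_clone_map[sample_id]
        while node is not None:
            muts.update(self.clone_mutations.get(node, ()))
            node = self.clone_parent.get(node)
        return muts

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["true_migration_edges"] = [list(e) for e in self.true_migration_edges]
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SimulatedPatient:
    patient_id: str
    config: SimConfig
    variants: pd.DataFrame
    normals: pd.DataFrame
    segments: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# mutation drawing
# ---------------------------------------------------------------------------

class _MutationFactory:
    """Draws mutations with positions, effects and signature-consistent
    trinucleotide contexts."""

    def __init__(self, rng: np.random.Generator, config: SimConfig):
        self.rng = rng
        catalog = default_catalog()
        self.names = list(config.sig_mixture)
        probs = np.array([config.sig_mixture[n] for n in self.names], dtype=float)
        self.sig_probs = probs / probs.sum()
        cols = [catalog.names.index(n) for n in self.names]
        self.matrix = catalog.matrix[:, cols]
        self.artifact_col = catalog.column("ARTIFACT")
        self.used_positions: set[tuple[str, int]] = set()
        self.counter = 0

    def _position(self) -> tuple[str, int]:
        while True:
            chrom = genome.CHROMOSOMES[self.rng.integers(len(genome.CHROMOSOMES))]
            pos0 = int(self.rng.integers(genome.CHROM_LEN))
            if (chrom, pos0) not in self.used_positions:
                self.used_positions.add((chrom, pos0))
                return chrom, pos0

    def _context(self, artifact: bool) -> tuple[str, str, str]:
        if artifact:
            ctx_i = int(self.rng.choice(96, p=self.artifact_col))
        else:
            k = int(self.rng.choice(len(self.names), p=self.sig_probs))
            ctx_i = int(self.rng.choice(96, p=self.matrix[:, k]))
        cls = CONTEXTS_96[ctx_i]          # e.g. 'A[C>T]G'
        ref, alt = cls[2], cls[4]
        return ref, alt, f"{cls[0]}{ref}{cls[6]}"

    def new(self, gene: str | None = None, effect: str | None = None,
            artifact: bool = False) -> dict:
        chrom, pos0 = self._position()
        ref, alt, trinuc = self._context(artifact)
        if effect is None:
            effect = str(self.rng.choice(_EFFECTS, p=_EFFECT_PROBS))
        if effect == "indel":
            ref, alt = ref + "A", ref     # single-base deletion
        if gene is None:
            self.counter += 1
            gene = f"PSG{self.counter:05d}"
        return {
            "chrom": chrom, "pos0": pos0, "ref": ref, "alt": alt,
            "gene": gene, "effect": effect, "trinuc_context": trinuc,
            "key": variant_key(chrom, pos0, ref, alt),
        }


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def _mixed_log2(total_cn: float, purity: float) -> float:
    """Observed log2 ratio of a clonal copy-number state at given purity."""
    return math.log2((purity * total_cn + 2.0 * (1.0 - purity)) / 2.0)


def _build_segments(rng: np.random.Generator, config: SimConfig,
                    sample_ids_by_site: dict[str, list[str]],
                    site_specs: dict[str, SiteSpec]) -> tuple[pd.DataFrame, dict]:
    """Per-sample segment tables with arm events and focal driver amps.

    Returns the segment DataFrame and the de novo focal-amp map
    ``{(site, gene): [sample_ids]}``.  Arm gains use total_cn = 3, which
    stays below the gene-level gain threshold (+1 change), so focal
    amplifications (total_cn = 8) are the only gene-level events.
    """
    arms = genome.default_arms()
    arm_list = list(arms.itertuples(index=False))
    n_arms = len(arm_list)
    purity = config.purity
    is_cin = config.subtype == Subtype.CIN.value

    def draw_cn() -> int:  # gained arm -> cn 3, lost arm -> cn 1
        return 3 if rng.random() < 0.6 else 1

    # CIN arm events favor the recurrent gastric-CIN arms in their
    # canonical direction; sporadic arms are altered at a reduced rate
    arm_names = [f"{a.chrom}{a.arm}" for a in arm_list]
    canonical = {i: genome.RECURRENT_ARM_EVENTS.get(name)
                 for i, name in enumerate(arm_names)}

    def draw_arm_events(rate: float, skip: set[int]) -> dict[int, int]:
        events: dict[int, int] = {}
        for i in range(n_arms):
            if i in skip:
                continue
            sign = canonical[i]
            if sign is not None:
                if rng.random() < rate:
                    events[i] = 3 if sign > 0 else 1
            elif rng.random() < rate * 0.15:
                events[i] = draw_cn()
        return events

    # clonal arm events shared by all tumor samples; CIN tumors carry at
    # least cin_min_clonal_events recurrent-arm events (high aneuploidy is
    # what defines the subtype)
    if is_cin:
        clonal_events = draw_arm_events(config.cin_clonal_arm_rate, set())
        recurrent_pool = [i for i, s in canonical.items() if s is not None]
        n_recurrent = sum(1 for i in clonal_events if canonical[i] is not None)
        if n_recurrent < config.cin_min_clonal_events:
            missing = [i for i in recurrent_pool if i not in clonal_events]
            extra = rng.choice(missing,
                               size=config.cin_min_clonal_events - n_recurrent,
                               replace=False)
            for i in extra:
                clonal_events[int(i)] = 3 if canonical[int(i)] > 0 else 1
    else:
        clonal_events = {}
        for i in rng.choice(n_arms, size=config.gs_n_clonal_arm_events,
                            replace=False):
            clonal_events[int(i)] = draw_cn()

    focal_amps: dict[tuple[str, str], list[str]] = {}
    rows = []
    for site, samples in sample_ids_by_site.items():
        spec = site_specs[site]
        site_amp_genes: list[str] = []
        if is_cin and spec.site_class == SiteClass.HEMATOGENOUS.value:
            n_amp = int(min(rng.poisson(config.focal_amp_rate), 3))
            n_amp = max(n_amp, 1)
            site_amp_genes = sorted(
                (str(g) for g in rng.choice(config.driver_genes, size=n_amp,
                                            replace=False)),
                key=lambda g: genome.DRIVER_GENES[g][1])
            for g in site_amp_genes:
                focal_amps[(site, g)] = list(samples)
        for sample in samples:
            events = dict(clonal_events)
            if is_cin:
                rate = (config.cin_hema_arm_event_rate
                        if spec.site_class == SiteClass.HEMATOGENOUS.value
                        else config.cin_arm_event_rate)
                events.update(draw_arm_events(rate, set(events)))
            for i, arm in enumerate(arm_list):
                cn = events.get(i, 2)
                seg = {"sample_id": sample, "chrom": arm.chrom,
                       "start": arm.start, "end": arm.end,
                       "log2_ratio": round(_mixed_log2(cn, purity), 6),
                       "total_cn": cn,
                       "major_cn": max(cn - 1, 1) if cn > 1 else cn,
                       "minor_cn": min(1, cn)}
                carved = [seg]
                for g in site_amp_genes:
                    gc, gs_, ge = genome.DRIVER_GENES[g]
                    if gc == arm.chrom and arm.start <= gs_ and ge <= arm.end:
                        base = carved.pop()
                        amp_cn = 8
                        for piece in (
                            {**base, "end": gs_},
                            {**base, "start": gs_, "end": ge,
                             "log2_ratio": round(_mixed_log2(amp_cn, purity), 6),
                             "total_cn": amp_cn, "major_cn": amp_cn - 1,
                             "minor_cn": 1},
                            {**base, "start": ge},
                        ):
                            if piece["end"] > piece["start"]:
                                carved.append(piece)
                rows.extend(carved)
    return pd.DataFrame(rows), focal_amps


# ---------------------------------------------------------------------------
# patient simulation
# ---------------------------------------------------------------------------

def simulate_patient(config: SimConfig, seed: int | None = None,
                     patient_id: str = "SIM01") -> SimulatedPatient:
    """Simulate one patient; deterministic given ``seed`` (defaults to
    ``config.seed``)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    factory = _MutationFactory(rng, config)

    site_specs = {s.name: s for s in config.sites}
    scale_map = DEFAULT_ROUTE_PRIVATE_SCALE.get(config.subtype, {})

    # ---- samples ----------------------------------------------------------
    sample_ids_by_site: dict[str, list[str]] = {}
    sample_rows = []
    for spec in config.sites:
        ids = []
        for i in range(spec.n_samples):
            sid = f"{patient_id}-{spec.name}{i + 1}"
            ids.append(sid)
            layer = "NA"
            if spec.site_class == SiteClass.PRIMARY.value:
                layers = spec.layers or ["T3"]
                layer = layers[i % len(layers)]
            tier = "NA"
            if spec.site_class == SiteClass.LYMPH_NODE.value:
                tier = STATION_TIER[spec.ln_station].value
            sample_rows.append({
                "sample_id": sid, "patient_id": patient_id,
                "site_class": spec.site_class, "layer": layer,
                "ln_station": spec.ln_station, "ln_tier": tier,
                "organ": spec.organ or "NA",
                "chemo_exposed": False, "purity": config.purity,
                "msi_score": round(float(rng.uniform(0.1, 2.0)), 3),
                "ebv_positive": False,
            })
        sample_ids_by_site[spec.name] = ids
    sample_sheet = pd.DataFrame(sample_rows)
    sample_sheet["ln_station"] = pd.array(sample_sheet["ln_station"], dtype="Int64")
    tumor_samples = list(sample_sheet["sample_id"])

    # ---- clone tree -------------------------------------------------------
    clone_parent: dict[str, str | None] = {"germline": None, "founder": "germline"}
    clone_site: dict[str, str] = {"germline": "primary", "founder": "primary"}
    clone_mutations: dict[str, list[dict]] = {"germline": [], "founder": []}
    sample_clone: dict[str, str] = {}
    migration_edges: list[tuple[str, str]] = []
    de_novo_events: list[dict] = []

    def add_clone(name: str, parent: str, site: str) -> None:
        clone_parent[name] = parent
        clone_site[name] = site
        clone_mutations[name] = []

    # order sites so that seed sources are created before their children
    ordered: list[SiteSpec] = []
    placed: set[str] = set()
    pending = list(config.sites)
    while pending:
        progressed = False
        for spec in list(pending):
            src = spec.seed_from
            if (spec.site_class == SiteClass.PRIMARY.value
                    or src is None or src == "primary" or src in placed):
                ordered.append(spec)
                placed.add(spec.name)
                pending.remove(spec)
                progressed = True
        if not progressed:
            raise ValueError("cyclic or unresolvable seed_from chain in sites")

    last_sample_clone_of_site: dict[str, str] = {}
    for spec in ordered:
        scale = spec.private_scale
        if scale is None:
            scale = scale_map.get(spec.site_class, 1.0)
        n_priv = int(round(config.n_private_mut_per_site * scale))

        if spec.site_class == SiteClass.PRIMARY.value:
            site_clone = "founder"
        else:
            src = spec.seed_from or "primary"
            attach = ("founder" if src == "primary"
                      else last_sample_clone_of_site[src])
            site_clone = f"site:{spec.name}"
            add_clone(site_clone, attach, spec.name)
            migration_edges.append((src, spec.name))
            # the site founder accrues mutations under the same
            # site-specific rate scaling as the per-sample clones
            for _ in range(int(round(config.n_site_shared_mut * scale))):
                clone_mutations[site_clone].append(factory.new())
            # de novo driver point mutations in peritoneal/ovarian (GS)
            if (config.subtype == Subtype.GS.value
                    and spec.site_class in (SiteClass.PERITONEAL.value,
                                            SiteClass.OVARIAN.value)):
                n_dn = int(min(rng.poisson(config.de_novo_mut_rate) + 1, 3))
                genes = rng.choice(config.driver_genes, size=n_dn, replace=False)
                for g in genes:
                    clone_mutations[site_clone].append(
                        factory.new(gene=str(g), effect="missense"))
                    de_novo_events.append({
                        "gene": str(g), "site": spec.name,
                        "samples": list(sample_ids_by_site[spec.name]),
                        "kind": "mutation",
                    })
        for sid in sample_ids_by_site[spec.name]:
            clone = f"clone:{sid}"
            add_clone(clone, site_clone, spec.name)
            for _ in range(n_priv):
                clone_mutations[clone].append(factory.new())
            sample_clone[sid] = clone
            last_sample_clone_of_site[spec.name] = clone

    artifact_samples = [sid for spec in config.sites if spec.artifact
                        for sid in sample_ids_by_site[spec.name]]

    # ---- trunk sizing -----------------------------------------------------
    def path_len(sid: str) -> int:
        """Non-trunk mutation count from founder down to the sample clone."""
        n, node = 0, sample_clone[sid]
        while node != "founder":
            n += len(clone_mutations[node])
            node = clone_parent[node]  # type: ignore[assignment]
        return n

    mean_path = float(np.mean([path_len(s) for s in tumor_samples]))
    f = float(config.trunk_fraction)
    if config.n_clonal_mut is not None:
        n_trunk = config.n_clonal_mut
    elif f >= 1.0 or mean_path == 0.0:
        n_trunk = 60 if mean_path == 0.0 else int(round(mean_path * 20))
    else:
        n_trunk = int(round(mean_path * f / (1.0 - f)))
    if n_trunk > 0:
        clone_mutations["founder"].append(
            factory.new(gene="TP53", effect="missense"))
        for _ in range(n_trunk - 1):
            clone_mutations["founder"].append(factory.new())

    # artifact mutations (false calls), private per artifact sample
    artifact_mut_by_sample: dict[str, list[dict]] = {}
    for sid in artifact_samples:
        n_art = max(3 * (n_trunk + path_len(sid)), 10)
        artifact_mut_by_sample[sid] = [factory.new(artifact=True)
                                       for _ in range(n_art)]

    # ---- copy number ------------------------------------------------------
    segments, focal_amps = _build_segments(rng, config, sample_ids_by_site,
                                           site_specs)
    for (site, gene), samples in sorted(focal_amps.items()):
        de_novo_events.append({"gene": gene, "site": site,
                               "samples": samples, "kind": "amp"})

    cn_lookup: dict[str, list[tuple[str, int, int, int]]] = {}
    for sid, grp in segments.groupby("sample_id"):
        cn_lookup[str(sid)] = list(zip(grp["chrom"], grp["start"], grp["end"],
                                       grp["total_cn"]))

    def local_cn(sid: str, chrom: str, pos0: int) -> int:
        for c, s, e, cn in cn_lookup[sid]:
            if c == chrom and s <= pos0 < e:
                return int(cn)
        return 2

    # ---- mutation presence & read counts ----------------------------------
    all_muts: list[dict] = [m for ms in clone_mutations.values() for m in ms]

    ancestry: dict[str, set[str]] = {}
    for sid in tumor_samples:
        keys: set[str] = set()
        node: str | None = sample_clone[sid]
        while node is not None:
            keys.update(m["key"] for m in clone_mutations[node])
            node = clone_parent[node]
        ancestry[sid] = keys

    qual_by_key: dict[str, dict[str, float]] = {}

    def quality(key: str) -> dict[str, float]:
        if key not in qual_by_key:
            qual_by_key[key] = {
                "tlod": round(float(rng.uniform(15, 80)), 2),
                "mmq": round(float(rng.uniform(60, 70)), 2),
                "seqq": round(float(rng.uniform(30, 90)), 2),
                "strandq": round(float(rng.uniform(25, 60)), 2),
            }
        return qual_by_key[key]

    variant_rows: list[dict] = []

    def observe(mut: dict, sid: str, present: bool) -> None:
        depth = max(int(rng.poisson(config.depth_mean)), 1)
        if present:
            cn_t = local_cn(sid, mut["chrom"], mut["pos0"])
            p = config.purity / (config.purity * cn_t
                                 + 2.0 * (1.0 - config.purity))
            alt = int(rng.binomial(depth, min(p, 1.0)))
        else:
            alt = 0
        q = quality(mut["key"])
        variant_rows.append({
            "patient_id": patient_id, "sample_id": sid,
            "chrom": mut["chrom"], "pos0": mut["pos0"],
            "ref": mut["ref"], "alt": mut["alt"],
            "gene": mut["gene"], "effect": mut["effect"],
            "alt_count": alt, "depth": depth,
            "vaf": round(alt / depth, 6) if depth else 0.0,
            **q,
            "trinuc_context": mut["trinuc_context"],
        })

    for mut in all_muts:
        for sid in tumor_samples:
            observe(mut, sid, mut["key"] in ancestry[sid])
    artifact_muts = [m for ms in artifact_mut_by_sample.values() for m in ms]
    for sid, muts in artifact_mut_by_sample.items():
        for mut in muts:
            for other in tumor_samples:
                observe(mut, other, other == sid)

    # threshold-failing decoy variants, removed by the filter
    decoy_muts: list[dict] = []
    if config.inject_decoys:
        passing = {"tlod": 30.0, "mmq": 65.0, "seqq": 50.0, "strandq": 40.0}
        for fail in ({"tlod": 5.0}, {"mmq": 40.0}, {"seqq": 10.0},
                     {"strandq": 10.0}):
            mut = factory.new()
            decoy_muts.append(mut)
            qual_by_key[mut["key"]] = {**passing, **fail}
            for sid in tumor_samples:
                observe(mut, sid, sid == tumor_samples[0])

    variants = pd.DataFrame(variant_rows)

    # matched-normal observations
    normal_rows = []
    for mut in all_muts + artifact_muts + decoy_muts:
        normal_rows.append({
            "patient_id": patient_id, "chrom": mut["chrom"],
            "pos0": mut["pos0"], "ref": mut["ref"], "alt": mut["alt"],
            "depth": max(int(rng.poisson(config.depth_mean)), 11),
            "alt_count": 0,
        })
    normals = pd.DataFrame(normal_rows)

    truth = GroundTruth(
        patient_id=patient_id,
        clone_parent=clone_parent,
        clone_site=clone_site,
        clone_mutations={c: [m["key"] for m in ms]
                         for c, ms in clone_mutations.items()},
        sample_clone_map=sample_clone,
        sample_site={sid: site for site, ids in sample_ids_by_site.items()
                     for sid in ids},
        site_class={s.name: s.site_class for s in config.sites},
        true_topology_class=config.topology,
        true_subtype_per_sample={sid: config.subtype for sid in tumor_samples},
        true_migration_edges=migration_edges,
        true_de_novo_events=de_novo_events,
        trunk_mutations=[m["key"] for m in clone_mutations["founder"]],
        artifact_samples=artifact_samples,
        trunk_fraction=f,
    )
    return SimulatedPatient(patient_id, config, variants, normals,
                            segments, sample_sheet, truth)


def child_seed(seed: int, index: int) -> int:
    """Deterministic per-patient seed derived from (seed, index)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(n_patients: int, base_config: SimConfig | None = None,
                    seed: int = 0, branched_fraction: float = 0.5,
                    cin_fraction: float = 0.5) -> list[SimulatedPatient]:
    """Simulate a cohort; patient topologies/subtypes drawn per the given
    proportions, child seeds derived deterministically from (seed, index)."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    assign_rng = np.random.default_rng(child_seed(seed, 10**6))
    patients = []
    for i in range(n_patients):
        topology = (Topology.BRANCHED.value
                    if assign_rng.random() < branched_fraction
                    else Topology.DIASPORA.value)
        subtype = (Subtype.CIN.value if assign_rng.random() < cin_fraction
                   else Subtype.GS.value)
        if base_config is None:
            cfg = SimConfig(topology=topology, subtype=subtype)
        else:
            cfg = dataclasses.replace(
                base_config, topology=topology, subtype=subtype,
                trunk_fraction=None, sites=[],
            )
        patients.append(simulate_patient(
            cfg, seed=child_seed(seed, i), patient_id=f"GCS{i + 1:02d}"))
    return patients


def simulate_survival(patients: list[SimulatedPatient], seed: int = 0,
                      follow_up_days: float = 3000.0) -> pd.DataFrame:
    """Overall-survival table with a worse outcome for diaspora
    progression (exponential survival times, censored at end of
    follow-up)."""
    rng = np.random.default_rng(child_seed(seed, 2 * 10**6))
    rows = []
    for p in patients:
        scale = (1500.0 if p.truth.true_topology_class == Topology.BRANCHED.value
                 else 500.0)
        t = float(rng.exponential(scale))
        rows.append({
            "patient_id": p.patient_id,
            "time": round(min(t, follow_up_days), 1),
            "event": bool(t <= follow_up_days),
            "progression": p.truth.true_topology_class,
            "subtype": p.config.subtype,
        })
    return pd.DataFrame(rows)


def write_patient(patient: SimulatedPatient, outdir: str | Path) -> None:
    """Write a simulated patient's tables, ground truth and clone tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_variant_table(patient.variants, outdir / "variants.tsv")
    write_normal_table(patient.normals, outdir / "normals.tsv")
    write_segments(patient.segments, outdir / "segments.tsv")
    write_sample_sheet(patient.sample_sheet, outdir / "samples.tsv")
    (outdir / "ground_truth.json").write_text(patient.truth.to_json() + "\n")
    (outdir / "clone_tree.nwk").write_text(clone_tree_newick(patient.truth) + "\n")


def clone_tree_newick(truth: GroundTruth) -> str:
    """Newick rendering of the true clone tree (edge lengths = mutation
    counts)."""
    children: dict[str, list[str]] = {}
    for node, parent in truth.clone_parent.items():
        if parent is not None:
            children.setdefault(parent, []).append(node)

    def render(node: str) -> str:
        length = len(truth.clone_mutations.get(node, []))
        kids = sorted(children.get(node, []))
        label = node.replace(":", "_")
        if not kids:
            return f"{label}:{length}"
        return f"({','.join(render(k) for k in kids)}){label}:{length}"

    return render("germline") + ";"
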
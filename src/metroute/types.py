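"""Shared domain types for the metastatic-route genomics pipeline.

Coordinate convention: files are read and written as 1-based inclusive
(MAF/SEG style); in memory every interval is 0-based half-open and variant
positions are stored in a ``pos0`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Effect(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    NONSTOP = "nonstop"
    SPLICE_SITE = "splice_site"
    INDEL = "indel"
    SYNONYMOUS = "synonymous"


#: effect classes counted as nonsynonymous (everything but synonymous)
NONSYNONYMOUS_EFFECTS = frozenset(
    e.value for e in Effect if e is not Effect.SYNONYMOUS
)


class SiteClass(str, Enum):
    PRIMARY = "primary"
    LYMPH_NODE = "lymph_node"
    HEMATOGENOUS = "hematogenous"
    PERITONEAL = "peritoneal"
    OVARIAN = "ovarian"
    NORMAL = "normal"


class Layer(str, Enum):
    T1AB = "T1ab"
    T2 = "T2"
    T3 = "T3"
    NA = "NA"


class LNTier(str, Enum):
    D1 = "D1"
    D2 = "D2"
    D4 = "D4"
    NA = "NA"


#: lymph-node station -> tier mapping: D1 perigastric (#1-7),
#: D2 extra-perigastric (#8-12), D4 distant (#14 [14v], 16).
STATION_TIER = {**{s: LNTier.D1 for s in range(1, 8)},
                **{s: LNTier.D2 for s in range(8, 13)},
                14: LNTier.D4, 16: LNTier.D4}


class MSIStatus(str, Enum):
    MSI_H = "MSI_H"
    MSS = "MSS"


class Subtype(str, Enum):
    MSI = "MSI"
    EBV = "EBV"
    CIN = "CIN"
    GS = "GS"


class ArmCall(str, Enum):
    GAIN = "gain"
    LOSS = "loss"
    NEUTRAL = "neutral"


class GeneCNStatus(str, Enum):
    NEUTRAL = "neutral"
    GAIN = "gain"
    AMP = "amp"
    LOSS = "loss"
    NA = "NA"


class Topology(str, Enum):
    BRANCHED = "branched"
    DIASPORA = "diaspora"


class SeedingPattern(str, Enum):
    PARALLEL_SINGLE_SOURCE = "parallel_single_source"
    SINGLE_SOURCE = "single_source"
    MULTI_SOURCE = "multi_source"
    RESEEDING = "reseeding"


class Clonality(str, Enum):
    MONOCLONAL = "monoclonal"
    POLYCLONAL = "polyclonal"


@dataclass(frozen=True)
class FilterConfig:
    """Somatic variant filter thresholds.

    Per-call quality gates (Mutect2 annotations) plus per-patient cohort
    gates: matched-normal coverage with zero alt reads, minimum tumor
    coverage in every tumor sample, and a minimum VAF in at least one
    tumor sample.  ``presence_*`` thresholds govern the per-sample
    presence call used to build the binary mutation matrix; they are
    stricter than the cohort-level filter by design (alt >= 3 guards
    against FFPE noise).
    """

    min_tlod: float = 10.0
    min_mmq: float = 60.0
    min_seqq: float = 20.0
    min_strandq: float = 20.0
    min_normal_depth: int = 10
    max_normal_alt: int = 0
    min_tumor_depth: int = 20
    min_vaf_any_sample: float = 0.05
    presence_min_vaf: float = 0.05
    presence_min_alt: int = 3

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"FilterConfig.{name} must be >= 0, got {value}")


@dataclass
class BinaryMutationMatrix:
    """Sample x variant boolean presence grid.

    ``variant_keys`` are ``chrom:pos:ref:alt`` with a 1-based position.
    Columns that are false in every sample are dropped at construction.
    """

    sample_ids: list[str]
    variant_keys: list[str]
    presence: np.ndarray  # bool, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def profile(self, sample_id: str) -> set[str]:
        """Set of variant keys present in one sample."""
        i = self.sample_ids.index(sample_id)
        mask = self.presence[i]
        return {k for k, m in zip(self.variant_keys, mask) if m}


@dataclass
class GroupComparison:
    """Two-group comparison result (Mann-Whitney U or Welch t)."""

    metric_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    direction: str  # 'a_higher' | 'b_higher' | 'none'

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


@dataclass
class TrunkMetrics:
    """Trunk length, mean root-to-leaf length and their ratio.

    The trunk is the edge path from the germline root to the most recent
    common ancestor of all tumor leaves; its mutations are clonal across
    the patient.
    """

    trunk_len: int
    mean_root_leaf_len: float
    trunk_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.trunk_ratio <= 1.0 + 1e-12):
            raise ValueError(f"trunk_ratio out of [0,1]: {self.trunk_ratio}")


@dataclass
class MigrationHistory:
    """Minimum-migration anatomical labeling of a patient tree."""

    node_site_labels: dict[str, str]
    migration_edges: list[tuple[str, str]]
    n_migrations: int
    n_comigrations: int  # number of distinct ordered (source, dest) site pairs
    pattern: SeedingPattern
    clonality: dict[str, Clonality] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_comigrations > self.n_migrations:
            raise ValueError("n_comigrations cannot exceed n_migrations")
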
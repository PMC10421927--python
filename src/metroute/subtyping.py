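"""Copy-number burden, arm-level calls, MSI gating and CIN/GS subtyping.

Follows the TCGA gastric-cancer scheme: MSI-high tumors (instability
score > 5) are called MSI; EBV-positive non-MSI tumors are called EBV;
the remainder are split into chromosomal-instability (CIN) and
genomically stable (GS) subtypes by hierarchical clustering (Ward
linkage, Euclidean distance) of arm-level mean log2 copy-number profiles
against a labeled reference panel, assigning CIN to the cluster with the
higher copy-number burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import genome
from .types import ArmCall, GeneCNStatus, MSIStatus, Subtype


@dataclass
class SubtypeCall:
    sample_id: str
    msi_status: MSIStatus
    ebv_status: bool
    cn_burden_bp: int
    ploidy: float | None
    arm_calls: dict[str, str] = field(default_factory=dict)
    subtype: Subtype = Subtype.GS

    def __post_init__(self) -> None:
        if (self.subtype == Subtype.MSI) != (self.msi_status == MSIStatus.MSI_H):
            raise ValueError("subtype is MSI iff msi_status is MSI_H")
        if self.subtype == Subtype.EBV and (
                not self.ebv_status or self.msi_status == MSIStatus.MSI_H):
            raise ValueError("EBV subtype requires ebv_positive and not MSI-H")


@dataclass(frozen=True)
class DriverEvent:
    gene: str
    sample_id: str
    kind: str  # 'mutation' | 'gain' | 'amp'
    de_novo: bool


def _sample_segments(segments: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    sub = segments[segments["sample_id"] == sample_id]
    for (_, chrom), grp in sub.groupby(["sample_id", "chrom"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(
                f"overlapping segments for sample {sample_id} chrom {chrom}")
    return sub


def cn_burden(segments: pd.DataFrame, sample_id: str,
              log2_threshold: float = 0.3) -> int:
    """Total base pairs in segments with |log2 ratio| above the threshold.

    Additive over disjoint segment sets and invariant to splitting a
    segment at an interior point.  Returns 0 for a sample with no
    segments.
    """
    sub = _sample_segments(segments, sample_id)
    if sub.empty:
        return 0
    mask = sub["log2_ratio"].abs() > log2_threshold
    return int((sub.loc[mask, "end"] - sub.loc[mask, "start"]).sum())


def ploidy_estimate(segments: pd.DataFrame, sample_id: str) -> float | None:
    """Length-weighted mean total copy number; None if total_cn is absent."""
    sub = _sample_segments(segments, sample_id)
    if "total_cn" not in sub.columns or sub["total_cn"].isna().any():
        return None
    lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id}: zero total segment length")
    return float((lengths * sub["total_cn"].to_numpy(dtype=float)).sum() / total)


def gene_cn_status(segments: pd.DataFrame, sample_id: str,
                   gene_intervals: pd.DataFrame,
                   baseline: float = 2.0) -> dict[str, GeneCNStatus]:
    """Gene-level copy-number status from the segment overlapping each
    gene's midpoint: change = total_cn - baseline; gain for change > 1,
    amplification for change > 4 (amp subsumes gain), loss for
    change < -1.  Genes outside all segments get NA with a warning.
    """
    sub = _sample_segments(segments, sample_id)
    out: dict[str, GeneCNStatus] = {}
    for row in gene_intervals.itertuples(index=False):
        mid = (row.start + row.end) // 2
        hit = sub[(sub["chrom"] == row.chrom) & (sub["start"] <= mid)
                  & (mid < sub["end"])]
        if hit.empty or "total_cn" not in hit.columns or pd.isna(hit.iloc[0]["total_cn"]):
            warnings.warn(f"gene {row.gene} not covered by any segment of "
                          f"{sample_id}; status NA")
            out[row.gene] = GeneCNStatus.NA
            continue
        change = float(hit.iloc[0]["total_cn"]) - baseline
        if change > 4:
            out[row.gene] = GeneCNStatus.AMP
        elif change > 1:
            out[row.gene] = GeneCNStatus.GAIN
        elif change < -1:
            out[row.gene] = GeneCNStatus.LOSS
        else:
            out[row.gene] = GeneCNStatus.NEUTRAL
    return out


def arm_alteration_calls(segments: pd.DataFrame, sample_id: str,
                         arms: pd.DataFrame, min_fraction: float = 0.66,
                         log2_threshold: float = 0.1) -> dict[str, ArmCall]:
    """Arm-level gain/loss calls.

    An arm is gained (lost) if segments with log2 ratio above +0.1
    (below -0.1) cover at least 66% of the arm.  Gain and loss are
    mutually exclusive since 2 x 66% > 100%.
    """
    sub = _sample_segments(segments, sample_id)
    calls: dict[str, ArmCall] = {}
    for row in arms.itertuples(index=False):
        arm_id = f"{row.chrom}{row.arm}"
        arm_len = row.end - row.start
        on_arm = sub[(sub["chrom"] == row.chrom) & (sub["end"] > row.start)
                     & (sub["start"] < row.end)]
        gained = lost = 0
        for seg in on_arm.itertuples(index=False):
            overlap = min(seg.end, row.end) - max(seg.start, row.start)
            if seg.log2_ratio > log2_threshold:
                gained += overlap
            elif seg.log2_ratio < -log2_threshold:
                lost += overlap
        if gained >= min_fraction * arm_len:
            calls[arm_id] = ArmCall.GAIN
        elif lost >= min_fraction * arm_len:
            calls[arm_id] = ArmCall.LOSS
        else:
            calls[arm_id] = ArmCall.NEUTRAL
    return calls


def msi_status(score: float | None) -> MSIStatus:
    """MSI-high iff the instability score strictly exceeds 5; a missing
    score is treated as MSS with a warning."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        warnings.warn("missing MSI score; assuming MSS")
        return MSIStatus.MSS
    if score < 0:
        raise ValueError(f"MSI score must be >= 0, got {score}")
    return MSIStatus.MSI_H if score > 5 else MSIStatus.MSS


def arm_log2_profile(segments: pd.DataFrame, sample_id: str,
                     arms: pd.DataFrame) -> np.ndarray:
    """Length-weighted mean log2 ratio per arm, in arm-table order."""
    sub = _sample_segments(segments, sample_id)
    values = []
    for row in arms.itertuples(index=False):
        on_arm = sub[(sub["chrom"] == row.chrom) & (sub["end"] > row.start)
                     & (sub["start"] < row.end)]
        if on_arm.empty:
            values.append(0.0)
            continue
        w = (np.minimum(on_arm["end"], row.end)
             - np.maximum(on_arm["start"], row.start)).to_numpy(dtype=float)
        values.append(float((w * on_arm["log2_ratio"].to_numpy()).sum() / w.sum()))
    return np.array(values)


def make_reference_panel(arms: pd.DataFrame, n_cin: int = 20, n_gs: int = 20,
                         seed: int = 1234) -> pd.DataFrame:
    """Labeled synthetic reference panel of arm-level log2 profiles.

    Stand-in for a public gastric-cancer copy-number reference: CIN
    exemplars carry many altered arms, GS exemplars are near-flat.
    Columns: one per arm; plus a ``label`` column.
    """
    rng = np.random.default_rng(seed)
    n_arms = len(arms)
    arm_names = [f"{r.chrom}{r.arm}" for r in arms.itertuples(index=False)]
    recurrent = [(i, genome.RECURRENT_ARM_EVENTS[name])
                 for i, name in enumerate(arm_names)
                 if name in genome.RECURRENT_ARM_EVENTS]
    rows = []
    for _ in range(n_cin):
        profile = rng.normal(0.0, 0.02, size=n_arms)
        # CIN tumors alter a shared set of recurrent arms in a canonical
        # direction, plus a few sporadic arms
        k = int(rng.integers(9, len(recurrent) + 1))
        for j in rng.choice(len(recurrent), size=k, replace=False):
            i, sign = recurrent[j]
            mag = rng.uniform(0.4, 0.65) if sign > 0 else rng.uniform(0.5, 0.75)
            profile[i] += sign * mag
        sporadic = rng.choice(n_arms, size=int(rng.integers(0, 4)),
                              replace=False)
        profile[sporadic] += rng.choice([-0.6, 0.45], size=len(sporadic))
        rows.append(list(profile) + ["CIN"])
    for _ in range(n_gs):
        profile = rng.normal(0.0, 0.02, size=n_arms)
        n_alt = int(rng.integers(0, 3))
        if n_alt:
            altered = rng.choice(n_arms, size=n_alt, replace=False)
            profile[altered] += rng.choice([-0.5, 0.45], size=n_alt)
        rows.append(list(profile) + ["GS"])
    cols = [f"{r.chrom}{r.arm}" for r in arms.itertuples(index=False)] + ["label"]
    return pd.DataFrame(rows, columns=cols)


def _profile_burden(profile: np.ndarray, arm_lengths: np.ndarray,
                    log2_threshold: float = 0.3) -> float:
    return float(arm_lengths[np.abs(profile) > log2_threshold].sum())


def classify_subtype(sample_id: str, segments: pd.DataFrame,
                     msi_score: float | None, ebv_positive: bool,
                     arms: pd.DataFrame, reference_panel: pd.DataFrame) -> SubtypeCall:
    """Molecular subtype call with TCGA-style precedence.

    MSI-high wins; then EBV positivity; otherwise the sample's arm-level
    log2 profile is clustered jointly with the labeled reference panel
    (Ward linkage, Euclidean distance, two-cluster cut) and CIN is
    assigned to the cluster with the higher mean copy-number burden.
    Deterministic and invariant to the order of panel rows.
    """
    if len(reference_panel) < 4:
        raise ValueError("reference panel must contain at least 4 profiles")
    status = msi_status(msi_score)
    burden = cn_burden(segments, sample_id)
    ploidy = ploidy_estimate(segments, sample_id)
    calls = arm_alteration_calls(segments, sample_id, arms)
    base = dict(sample_id=sample_id, msi_status=status, ebv_status=ebv_positive,
                cn_burden_bp=burden, ploidy=ploidy,
                arm_calls={k: v.value for k, v in calls.items()})
    if status == MSIStatus.MSI_H:
        return SubtypeCall(subtype=Subtype.MSI, **base)
    if ebv_positive:
        return SubtypeCall(subtype=Subtype.EBV, **base)

    arm_cols = [f"{r.chrom}{r.arm}" for r in arms.itertuples(index=False)]
    panel = reference_panel.sort_values(arm_cols).reset_index(drop=True)
    profile = arm_log2_profile(segments, sample_id, arms)
    X = np.vstack([panel[arm_cols].to_numpy(dtype=float), profile])
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    assignments = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    arm_lengths = (arms["end"] - arms["start"]).to_numpy(dtype=float)
    burdens = np.array([_profile_burden(x, arm_lengths) for x in X])
    mean_burden = {c: burdens[assignments == c].mean() for c in (1, 2)}
    cin_cluster = max(mean_burden, key=lambda c: mean_burden[c])
    subtype = Subtype.CIN if assignments[-1] == cin_cluster else Subtype.GS
    return SubtypeCall(subtype=subtype, **base)


def de_novo_driver_events(primary_events: pd.DataFrame,
                          met_events: pd.DataFrame,
                          driver_list: list[str]) -> list[DriverEvent]:
    """Flag metastasis-only driver events.

    Both tables carry columns ``sample_id``, ``gene``, ``kind`` (mutation
    / gain / amp).  An event (gene, kind) in a metastatic sample is de
    novo iff it is absent from every primary region of the patient; an
    amplification also counts a primary gain of the same gene as prior
    presence (amp subsumes gain).  Raises if there is no primary sample.
    """
    if primary_events is None or "sample_id" not in getattr(primary_events, "columns", []):
        raise ValueError("primary event table required")
    if primary_events["sample_id"].nunique() == 0:
        raise ValueError("patient has no primary sample; cannot assess de novo status")
    drivers = set(driver_list)
    primary_pairs = {
        (g, k) for g, k in zip(primary_events["gene"], primary_events["kind"])
        if g in drivers
    }
    primary_genes_cn = {g for g, k in primary_pairs if k in ("gain", "amp")}
    events: list[DriverEvent] = []
    for row in met_events.itertuples(index=False):
        if row.gene not in drivers:
            continue
        if row.kind in ("gain", "amp"):
            seen = row.gene in primary_genes_cn
        else:
            seen = (row.gene, row.kind) in primary_pairs
        events.append(DriverEvent(gene=row.gene, sample_id=row.sample_id,
                                  kind=row.kind, de_novo=not seen))
    return events


def sample_driver_events(variants: pd.DataFrame, segments: pd.DataFrame,
                         sample_id: str, gene_intervals: pd.DataFrame,
                         driver_list: list[str]) -> pd.DataFrame:
    """Per-sample driver event table (mutations + gene-level gain/amp)."""
    drivers = set(driver_list)
    rows = []
    sub = variants[(variants["sample_id"] == sample_id)
                   & (variants["alt_count"] > 0)
                   & (variants["effect"] != "synonymous")]
    for gene in sorted(set(sub["gene"]) & drivers):
        rows.append({"sample_id": sample_id, "gene": gene, "kind": "mutation"})
    status = gene_cn_status(segments, sample_id, gene_intervals)
    for gene, st in status.items():
        if gene in drivers and st in (GeneCNStatus.GAIN, GeneCNStatus.AMP):
            rows.append({"sample_id": sample_id, "gene": gene,
                         "kind": st.value})
    return pd.DataFrame(rows, columns=["sample_id", "gene", "kind"])
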
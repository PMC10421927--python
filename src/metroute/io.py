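"""Readers, writers, variant filtering and the binary mutation matrix.

Tabular formats
---------------
MAF-like variant TSV
    required columns: patient_id, sample_id, chrom, pos, ref, alt, gene,
    effect, alt_count, depth, vaf, tlod, mmq, seqq, strandq,
    trinuc_context.  Tab-separated, ``#`` comment lines allowed.  One row
    per (sample, variant) observation; rows with alt_count = 0 are
    depth-checked reference observations of a variant called elsewhere in
    the patient.
SEG segment table
    sample_id, chrom, start, end, log2_ratio[, total_cn, major_cn,
    minor_cn].
Sample sheet TSV
    mirrors the per-sample metadata fields (site class, primary layer,
    lymph-node station/tier, purity, MSI score, EBV flag).

Files are 1-based inclusive; in memory variant positions live in a
``pos0`` column and segment intervals are 0-based half-open.  Writers
re-emit 1-based coordinates.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    STATION_TIER,
    BinaryMutationMatrix,
    Effect,
    FilterConfig,
    LNTier,
    SiteClass,
)

VARIANT_FILE_COLUMNS = [
    "patient_id", "sample_id", "chrom", "pos", "ref", "alt", "gene",
    "effect", "alt_count", "depth", "vaf", "tlod", "mmq", "seqq",
    "strandq", "trinuc_context",
]

NORMAL_FILE_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "depth", "alt_count",
]

SEGMENT_FILE_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio"]
SEGMENT_OPTIONAL_COLUMNS = ["total_cn", "major_cn", "minor_cn"]

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "patient_id", "site_class", "layer", "ln_station",
    "ln_tier", "organ", "chemo_exposed", "purity", "msi_score",
    "ebv_positive",
]

_VALID_EFFECTS = {e.value for e in Effect}
_TRINUC_ALPHABET = set("ACGT")


class TableFormatError(ValueError):
    """Malformed input table; message names the offending file line."""


def variant_key(chrom: str, pos0: int, ref: str, alt: str) -> str:
    """Canonical ``chrom:pos:ref:alt`` key with a 1-based position."""
    return f"{chrom}:{pos0 + 1}:{ref}:{alt}"


def _data_line_numbers(path: Path) -> list[int]:
    """1-based physical line numbers of non-comment, non-blank lines
    after the header, so validation errors can name the real line."""
    numbers = []
    header_seen = False
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if not header_seen:
                header_seen = True
                continue
            numbers.append(i)
    return numbers


def _read_tsv(path: str | Path, required: list[str]) -> tuple[pd.DataFrame, list[int]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"chrom": str},
        keep_default_na=False, na_values=["NA"],
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    return df, _data_line_numbers(path)


def _validate_variants(df: pd.DataFrame, lines: list[int] | None, source: str) -> None:
    def where(i: int) -> str:
        if lines is not None and i < len(lines):
            return f"{source} line {lines[i]}"
        return f"{source} row {i}"

    for i, row in enumerate(df.itertuples(index=False)):
        if row.alt_count < 0 or row.depth < 0:
            raise TableFormatError(f"{where(i)}: negative counts")
        if row.alt_count > row.depth:
            raise TableFormatError(
                f"{where(i)}: alt_count {row.alt_count} exceeds depth {row.depth}"
            )
        if row.effect not in _VALID_EFFECTS:
            raise TableFormatError(
                f"{where(i)}: unknown effect {row.effect!r}; "
                f"allowed values: {sorted(_VALID_EFFECTS)}"
            )
        if not (0.0 <= row.vaf <= 1.0):
            raise TableFormatError(f"{where(i)}: vaf {row.vaf} outside [0,1]")
        if row.depth > 0 and abs(row.vaf - row.alt_count / row.depth) > 0.01:
            raise TableFormatError(
                f"{where(i)}: vaf {row.vaf} inconsistent with "
                f"{row.alt_count}/{row.depth}"
            )
        ctx = str(row.trinuc_context)
        if len(ctx) != 3 or not set(ctx) <= _TRINUC_ALPHABET | {"N"}:
            raise TableFormatError(f"{where(i)}: bad trinucleotide context {ctx!r}")


def read_variant_table(path: str | Path, dialect: str = "maf_tsv") -> pd.DataFrame:
    """Read per-sample somatic variant observations.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``maf_tsv`` (tab-separated, see module docstring) or
        ``minimal_vcf`` (single- or multi-sample VCF with AD/DP FORMAT
        fields and PATIENT/GENE/EFFECT/TRINUC/TLOD/MMQ/SEQQ/STRANDQ INFO
        keys).

    Returns a DataFrame with a 0-based ``pos0`` column; row order of the
    file is preserved.
    """
    if dialect == "maf_tsv":
        df, lines = _read_tsv(path, VARIANT_FILE_COLUMNS)
        _validate_variants(df, lines, str(path))
        df = df.rename(columns={"pos": "pos0"})
        df["pos0"] = df["pos0"].astype(int) - 1
        return df.reset_index(drop=True)
    if dialect == "minimal_vcf":
        df = _read_minimal_vcf(path)
        _validate_variants(df, None, str(path))
        return df
    raise ValueError(f"unknown dialect {dialect!r}; use 'maf_tsv' or 'minimal_vcf'")


def _read_minimal_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal annotated VCF reader (plain text, uncompressed)."""
    path = Path(path)
    samples: list[str] = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                samples = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise TableFormatError(
                    f"{path} line {lineno}: expected FORMAT and sample columns"
                )
            chrom, pos, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            info = dict(
                kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
            )
            fmt = fields[8].split(":")
            try:
                i_ad, i_dp = fmt.index("AD"), fmt.index("DP")
            except ValueError as exc:
                raise TableFormatError(
                    f"{path} line {lineno}: FORMAT must include AD and DP"
                ) from exc
            for sample, column in zip(samples, fields[9:]):
                parts = column.split(":")
                ad = parts[i_ad].split(",")
                alt_count = int(ad[1]) if len(ad) > 1 else int(ad[0])
                depth = int(parts[i_dp])
                rows.append({
                    "patient_id": info.get("PATIENT", "NA"),
                    "sample_id": sample,
                    "chrom": chrom,
                    "pos0": int(pos) - 1,
                    "ref": ref,
                    "alt": alt,
                    "gene": info.get("GENE", "NA"),
                    "effect": info.get("EFFECT", "missense"),
                    "alt_count": alt_count,
                    "depth": depth,
                    "vaf": alt_count / depth if depth else 0.0,
                    "tlod": float(info.get("TLOD", "nan")),
                    "mmq": float(info.get("MMQ", "nan")),
                    "seqq": float(info.get("SEQQ", "nan")),
                    "strandq": float(info.get("STRANDQ", "nan")),
                    "trinuc_context": info.get("TRINUC", "NNN"),
                })
    return pd.DataFrame(rows)


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write variants as MAF-like TSV (positions re-emitted 1-based)."""
    out = df.copy()
    out["pos"] = out["pos0"].astype(int) + 1
    out = out[VARIANT_FILE_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_normal_table(path: str | Path) -> pd.DataFrame:
    """Matched-normal observations per variant key."""
    df, lines = _read_tsv(path, NORMAL_FILE_COLUMNS)
    df = df.rename(columns={"pos": "pos0"})
    df["pos0"] = df["pos0"].astype(int) - 1
    return df.reset_index(drop=True)


def write_normal_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["pos"] = out["pos0"].astype(int) + 1
    out = out[NORMAL_FILE_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-dialect copy-number table (1-based inclusive in the file)."""
    df, lines = _read_tsv(path, SEGMENT_FILE_COLUMNS)
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1  # to 0-based half-open
    df["end"] = df["end"].astype(int)
    validate_segments(df, source=str(path), lines=lines)
    return df.reset_index(drop=True)


def validate_segments(df: pd.DataFrame, source: str = "<segments>",
                      lines: list[int] | None = None) -> None:
    bad = df["end"] <= df["start"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        loc = f"line {lines[i]}" if lines else f"row {i}"
        raise TableFormatError(f"{source} {loc}: segment end <= start")
    if {"major_cn", "minor_cn"} <= set(df.columns):
        both = df.dropna(subset=["major_cn", "minor_cn"])
        if (both["minor_cn"] > both["major_cn"]).any():
            raise TableFormatError(f"{source}: minor_cn exceeds major_cn")
    for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise TableFormatError(
                f"{source}: overlapping segments for sample {sample} chrom {chrom}"
            )


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    cols = SEGMENT_FILE_COLUMNS + [c for c in SEGMENT_OPTIONAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df, _ = _read_tsv(path, SAMPLE_SHEET_COLUMNS)
    df = df.copy()
    df["ln_station"] = pd.array(
        [int(v) if pd.notna(v) and str(v) != "" else None for v in df["ln_station"]],
        dtype="Int64",
    )
    for col in ("chemo_exposed", "ebv_positive"):
        df[col] = df[col].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes"}
        )
    validate_sample_sheet(df, source=str(path))
    return df.reset_index(drop=True)


def validate_sample_sheet(df: pd.DataFrame, source: str = "<sample sheet>") -> None:
    for i, row in df.iterrows():
        sc = row["site_class"]
        if sc not in {s.value for s in SiteClass}:
            raise TableFormatError(f"{source}: unknown site_class {sc!r}")
        is_primary = sc == SiteClass.PRIMARY.value
        has_layer = pd.notna(row["layer"]) and row["layer"] != "NA"
        if is_primary != has_layer:
            raise TableFormatError(
                f"{source}: sample {row['sample_id']}: layer must be set "
                "iff site_class is primary"
            )
        is_ln = sc == SiteClass.LYMPH_NODE.value
        has_station = pd.notna(row["ln_station"])
        has_tier = pd.notna(row["ln_tier"]) and row["ln_tier"] != "NA"
        if is_ln != (has_station and has_tier):
            raise TableFormatError(
                f"{source}: sample {row['sample_id']}: ln_station/ln_tier "
                "must be set iff site_class is lymph_node"
            )
        if is_ln:
            station = int(row["ln_station"])
            expected = STATION_TIER.get(station)
            if expected is None or expected != LNTier(row["ln_tier"]):
                raise TableFormatError(
                    f"{source}: sample {row['sample_id']}: station "
                    f"#{station} inconsistent with tier {row['ln_tier']}"
                )
        if not (0.0 < row["purity"] <= 1.0):
            raise TableFormatError(
                f"{source}: sample {row['sample_id']}: purity outside (0,1]"
            )


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["ln_station"] = out["ln_station"].map(
        lambda v: "NA" if pd.isna(v) else str(int(v))
    )
    out[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def filter_variants(variants: pd.DataFrame, normals: pd.DataFrame,
                    config: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the somatic variant filter and return surviving observations.

    A variant key (patient, chrom, pos, ref, alt) is retained iff

    * caller quality: TLOD, MMQ, SEQQ, STRANDQ (taken from the strongest
      observation of the key) each meet their thresholds;
    * its patient-matched normal has depth >= 10 with zero alt reads;
    * tumor depth >= 20 in every tumor sample of the patient;
    * VAF >= 0.05 in at least one tumor sample.

    All rows of surviving keys (including zero-alt reference
    observations) are returned, preserving input order.  The operation is
    idempotent and monotone in every threshold.

    Raises if a variant key has no matched-normal record or is missing a
    depth observation for some tumor sample of its patient (reference
    depth cannot be imputed).
    """
    if config is None:
        config = FilterConfig()
    if variants.empty:
        return variants.copy()

    def make_keys(df: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [f"{p}|{variant_key(c, q, r, a)}"
             for p, c, q, r, a in zip(df["patient_id"], df["chrom"],
                                      df["pos0"], df["ref"], df["alt"])],
            index=df.index,
        )

    v = variants.copy()
    v["_key"] = make_keys(v)
    n = normals.copy()
    n["_key"] = make_keys(n)
    normal_by_key = n.drop_duplicates("_key").set_index("_key")

    # quality metrics from the strongest observations (alt>0 rows if any;
    # a key never called anywhere falls back to all its rows)
    called = v[v["alt_count"] > 0]
    qual = called.groupby("_key")[["tlod", "mmq", "seqq", "strandq"]].max()
    qual_all = v.groupby("_key")[["tlod", "mmq", "seqq", "strandq"]].max()
    qual = qual.reindex(qual_all.index).fillna(qual_all)

    samples_per_patient = v.groupby("patient_id")["sample_id"].agg(
        lambda s: frozenset(s))

    grouped = v.groupby("_key")
    agg = grouped.agg(
        patient=("patient_id", "first"),
        n_samples=("sample_id", "nunique"),
        min_depth=("depth", "min"),
        max_vaf=("vaf", "max"),
    )

    missing_normal = agg.index.difference(normal_by_key.index)
    if len(missing_normal):
        key = missing_normal[0]
        raise ValueError(
            f"variant {key.split('|', 1)[1]} of patient "
            f"{key.split('|', 1)[0]} has no matched-normal record; cannot "
            "evaluate normal criteria")
    expected_n = agg["patient"].map(lambda p: len(samples_per_patient[p]))
    incomplete = agg.index[agg["n_samples"] != expected_n]
    if len(incomplete):
        key = incomplete[0]
        raise ValueError(
            f"variant {key.split('|', 1)[1]} of patient "
            f"{key.split('|', 1)[0]} lacks depth observations in some tumor "
            "samples; reference depth is not imputed")

    nrm = normal_by_key.loc[agg.index]
    q = qual.loc[agg.index]
    keep = (
        (q["tlod"] >= config.min_tlod)
        & (q["mmq"] >= config.min_mmq)
        & (q["seqq"] >= config.min_seqq)
        & (q["strandq"] >= config.min_strandq)
        & (nrm["depth"].to_numpy() >= config.min_normal_depth)
        & (nrm["alt_count"].to_numpy() <= config.max_normal_alt)
        & (agg["min_depth"] >= config.min_tumor_depth)
        & (agg["max_vaf"] >= config.min_vaf_any_sample)
    )
    keep_keys = set(keep.index[keep])
    kept = v[v["_key"].isin(keep_keys)].drop(columns="_key")
    return kept.reset_index(drop=True)


def build_binary_matrix(filtered_variants: pd.DataFrame,
                        cohort: list[str],
                        config: FilterConfig | None = None) -> BinaryMutationMatrix:
    """Binary presence matrix over tumor samples.

    A variant is present in a sample iff VAF >= ``presence_min_vaf`` and
    alt_count >= ``presence_min_alt`` in that sample (stricter than the
    cohort-level filter: trees and distances need a per-sample call).
    Columns absent from every sample are dropped.
    """
    if config is None:
        config = FilterConfig()
    if not cohort:
        raise ValueError("cohort must list at least one tumor sample")
    unknown = set(filtered_variants["sample_id"]) - set(cohort)
    if unknown:
        raise ValueError(f"samples in variant table absent from cohort: {sorted(unknown)}")

    keys = sorted({
        (c, q, r, a)
        for c, q, r, a in zip(filtered_variants["chrom"], filtered_variants["pos0"],
                              filtered_variants["ref"], filtered_variants["alt"])
    })
    key_index = {k: j for j, k in enumerate(keys)}
    sample_index = {s: i for i, s in enumerate(cohort)}

    presence = np.zeros((len(cohort), len(keys)), dtype=bool)
    present_mask = (
        (filtered_variants["vaf"] >= config.presence_min_vaf)
        & (filtered_variants["alt_count"] >= config.presence_min_alt)
    )
    hit = filtered_variants[present_mask]
    for s, c, q, r, a in zip(hit["sample_id"], hit["chrom"], hit["pos0"],
                             hit["ref"], hit["alt"]):
        presence[sample_index[s], key_index[(c, q, r, a)]] = True

    nonzero = presence.any(axis=0)
    presence = presence[:, nonzero]
    kept_keys = [variant_key(*k) for k, nz in zip(keys, nonzero) if nz]
    return BinaryMutationMatrix(list(cohort), kept_keys, presence)
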
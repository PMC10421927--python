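"""Copy-number metrics, MSI gating and CIN/GS classification tests."""

import numpy as np
import pandas as pd
import pytest

from metroute import genome
from metroute.subtyping import (
    arm_alteration_calls,
    classify_subtype,
    cn_burden,
    de_novo_driver_events,
    gene_cn_status,
    make_reference_panel,
    msi_status,
    ploidy_estimate,
)
from metroute.types import ArmCall, GeneCNStatus, MSIStatus, Subtype

from conftest import make_segment


def seg_frame(rows):
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cn_burden
# ---------------------------------------------------------------------------

def test_cn_burden_simple_sum():
    segs = seg_frame([
        make_segment(start=0, end=100, log2_ratio=0.5),
        make_segment(start=100, end=250, log2_ratio=-0.4),
        make_segment(start=250, end=400, log2_ratio=0.1),
    ])
    assert cn_burden(segs, "S1") == 100 + 150


def test_cn_burden_threshold_is_strict():
    segs = seg_frame([make_segment(start=0, end=100, log2_ratio=0.3)])
    assert cn_burden(segs, "S1") == 0
    segs = seg_frame([make_segment(start=0, end=100, log2_ratio=0.300001)])
    assert cn_burden(segs, "S1") == 100


def test_cn_burden_invariant_to_splitting():
    whole = seg_frame([make_segment(start=0, end=1000, log2_ratio=0.7)])
    split = seg_frame([make_segment(start=0, end=333, log2_ratio=0.7),
                       make_segment(start=333, end=1000, log2_ratio=0.7)])
    assert cn_burden(whole, "S1") == cn_burden(split, "S1")


def test_cn_burden_no_segments_is_zero():
    segs = seg_frame([make_segment(sample_id="OTHER")])
    assert cn_burden(segs, "S1") == 0


def test_cn_burden_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = int(rng.integers(1, 8))
        edges = np.sort(rng.choice(np.arange(1, 500), size=n + 1,
                                   replace=False))
        rows, expected = [], 0
        for s, e in zip(edges[:-1], edges[1:]):
            lr = float(rng.normal(0, 0.5))
            rows.append(make_segment(start=int(s), end=int(e), log2_ratio=lr))
            if abs(lr) > 0.3:
                expected += int(e) - int(s)   # independent per-segment tally
        assert cn_burden(seg_frame(rows), "S1") == expected


def test_cn_burden_overlap_is_an_error():
    segs = seg_frame([make_segment(start=0, end=100),
                      make_segment(start=50, end=150)])
    with pytest.raises(ValueError, match="overlapping"):
        cn_burden(segs, "S1")


# ---------------------------------------------------------------------------
# ploidy / gene status
# ---------------------------------------------------------------------------

def test_ploidy_length_weighted():
    segs = seg_frame([make_segment(start=0, end=100, total_cn=2),
                      make_segment(start=100, end=200, total_cn=4)])
    assert ploidy_estimate(segs, "S1") == pytest.approx(3.0)


def test_ploidy_none_without_total_cn():
    segs = seg_frame([make_segment()]).drop(columns=["total_cn"])
    assert ploidy_estimate(segs, "S1") is None


def test_gene_cn_status_thresholds():
    genes = pd.DataFrame([
        {"gene": "G_NEUTRAL", "chrom": "1", "start": 0, "end": 10},
        {"gene": "G_GAIN", "chrom": "1", "start": 100, "end": 110},
        {"gene": "G_AMP", "chrom": "1", "start": 200, "end": 210},
        {"gene": "G_LOSS", "chrom": "1", "start": 300, "end": 310},
        {"gene": "G_EDGE", "chrom": "1", "start": 400, "end": 410},
    ])
    segs = seg_frame([
        make_segment(start=0, end=50, total_cn=3),      # +1, not > 1
        make_segment(start=100, end=150, total_cn=4),   # +2 -> gain
        make_segment(start=200, end=250, total_cn=7),   # +5 -> amp
        make_segment(start=300, end=350, total_cn=0),   # -2 -> loss
        make_segment(start=400, end=450, total_cn=6),   # +4, not > 4 -> gain
    ])
    out = gene_cn_status(segs, "S1", genes)
    assert out == {"G_NEUTRAL": GeneCNStatus.NEUTRAL,
                   "G_GAIN": GeneCNStatus.GAIN,
                   "G_AMP": GeneCNStatus.AMP,
                   "G_LOSS": GeneCNStatus.LOSS,
                   "G_EDGE": GeneCNStatus.GAIN}


def test_gene_cn_status_uncovered_gene_is_na():
    genes = pd.DataFrame([{"gene": "G", "chrom": "9", "start": 0, "end": 10}])
    segs = seg_frame([make_segment()])
    with pytest.warns(UserWarning, match="not covered"):
        out = gene_cn_status(segs, "S1", genes)
    assert out["G"] == GeneCNStatus.NA


# ---------------------------------------------------------------------------
# arm calls
# ---------------------------------------------------------------------------

def test_arm_calls_examples(toy_arms):
    segs = seg_frame([
        # 1p: 70/100 gained -> gain
        make_segment(chrom="1", start=0, end=70, log2_ratio=0.5),
        make_segment(chrom="1", start=70, end=100, log2_ratio=0.0),
        # 1q: 50/100 lost -> neutral (below 66%)
        make_segment(chrom="1", start=100, end=150, log2_ratio=-0.5),
        make_segment(chrom="1", start=150, end=200, log2_ratio=0.0),
        # 2p: fully lost -> loss
        make_segment(chrom="2", start=0, end=100, log2_ratio=-0.2),
        # 2q: log2 exactly at +0.1 does not count as gained
        make_segment(chrom="2", start=100, end=200, log2_ratio=0.1),
    ])
    calls = arm_alteration_calls(segs, "S1", toy_arms)
    assert calls == {"1p": ArmCall.GAIN, "1q": ArmCall.NEUTRAL,
                     "2p": ArmCall.LOSS, "2q": ArmCall.NEUTRAL}


def test_arm_calls_base_level_oracle(toy_arms):
    """Arm calls equal a per-basepair recomputation on random fixtures."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        rows = []
        base = {}  # (chrom, pos) -> log2
        for chrom in ("1", "2"):
            edges = np.sort(rng.choice(np.arange(1, 200), size=4,
                                       replace=False))
            edges = [0, *[int(x) for x in edges], 200]
            for s, e in zip(edges[:-1], edges[1:]):
                if s == e:
                    continue
                lr = float(rng.choice([-0.5, -0.1, 0.0, 0.1, 0.5]))
                rows.append(make_segment(chrom=chrom, start=s, end=e,
                                         log2_ratio=lr))
                for pos in range(s, e):
                    base[(chrom, pos)] = lr
        calls = arm_alteration_calls(seg_frame(rows), "S1", toy_arms)
        for arm in toy_arms.itertuples(index=False):
            span = range(arm.start, arm.end)
            gained = sum(base.get((arm.chrom, p), 0.0) > 0.1 for p in span)
            lost = sum(base.get((arm.chrom, p), 0.0) < -0.1 for p in span)
            arm_len = arm.end - arm.start
            if gained >= 0.66 * arm_len:
                expected = ArmCall.GAIN
            elif lost >= 0.66 * arm_len:
                expected = ArmCall.LOSS
            else:
                expected = ArmCall.NEUTRAL
            assert calls[f"{arm.chrom}{arm.arm}"] == expected


# ---------------------------------------------------------------------------
# MSI gate
# ---------------------------------------------------------------------------

def test_msi_boundaries():
    assert msi_status(5.1) == MSIStatus.MSI_H
    assert msi_status(5.0) == MSIStatus.MSS
    assert msi_status(0.0) == MSIStatus.MSS


def test_msi_missing_score_warns_mss():
    with pytest.warns(UserWarning, match="missing MSI"):
        assert msi_status(None) == MSIStatus.MSS
    with pytest.warns(UserWarning):
        assert msi_status(float("nan")) == MSIStatus.MSS


def test_msi_negative_score_errors():
    with pytest.raises(ValueError):
        msi_status(-1.0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _flat_segments(arms, sample_id="S1", log2=0.0, cn=2):
    return seg_frame([
        make_segment(sample_id=sample_id, chrom=a.chrom, start=a.start,
                     end=a.end, log2_ratio=log2, total_cn=cn)
        for a in arms.itertuples(index=False)
    ])


def test_msi_precedence_over_cn():
    arms = genome.default_arms()
    panel = make_reference_panel(arms)
    segs = _flat_segments(arms, log2=0.6, cn=4)  # heavily altered
    call = classify_subtype("S1", segs, msi_score=7.0, ebv_positive=False,
                            arms=arms, reference_panel=panel)
    assert call.subtype == Subtype.MSI


def test_ebv_precedence_after_msi():
    arms = genome.default_arms()
    panel = make_reference_panel(arms)
    segs = _flat_segments(arms)
    call = classify_subtype("S1", segs, msi_score=1.0, ebv_positive=True,
                            arms=arms, reference_panel=panel)
    assert call.subtype == Subtype.EBV


def test_flat_profile_is_gs():
    arms = genome.default_arms()
    panel = make_reference_panel(arms)
    segs = _flat_segments(arms)
    call = classify_subtype("S1", segs, msi_score=1.0, ebv_positive=False,
                            arms=arms, reference_panel=panel)
    assert call.subtype == Subtype.GS


def test_recurrently_altered_profile_is_cin():
    arms = genome.default_arms()
    panel = make_reference_panel(arms)
    rows = []
    for a in arms.itertuples(index=False):
        sign = genome.RECURRENT_ARM_EVENTS.get(f"{a.chrom}{a.arm}", 0)
        lr = 0.45 * sign if sign else 0.0
        cn = 3 if sign > 0 else (1 if sign < 0 else 2)
        rows.append(make_segment(chrom=a.chrom, start=a.start, end=a.end,
                                 log2_ratio=lr, total_cn=cn))
    call = classify_subtype("S1", seg_frame(rows), msi_score=1.0,
                            ebv_positive=False, arms=arms,
                            reference_panel=panel)
    assert call.subtype == Subtype.CIN


def test_classification_invariant_to_panel_row_order():
    arms = genome.default_arms()
    panel = make_reference_panel(arms)
    shuffled = panel.sample(frac=1.0, random_state=3).reset_index(drop=True)
    segs = _flat_segments(arms)
    a = classify_subtype("S1", segs, msi_score=1.0, ebv_positive=False,
                         arms=arms, reference_panel=panel)
    b = classify_subtype("S1", segs, msi_score=1.0, ebv_positive=False,
                         arms=arms, reference_panel=shuffled)
    assert a.subtype == b.subtype


def test_tiny_panel_rejected():
    arms = genome.default_arms()
    panel = make_reference_panel(arms).head(3)
    segs = _flat_segments(arms)
    with pytest.raises(ValueError, match="at least 4"):
        classify_subtype("S1", segs, msi_score=1.0, ebv_positive=False,
                         arms=arms, reference_panel=panel)


# ---------------------------------------------------------------------------
# de novo driver events
# ---------------------------------------------------------------------------

def _events(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene", "kind"])


def test_de_novo_flags_met_only_events():
    primary = _events([("P_1", "TP53", "mutation")])
    met = _events([("M_1", "TP53", "mutation"), ("M_1", "KRAS", "mutation")])
    out = de_novo_driver_events(primary, met, ["TP53", "KRAS"])
    flags = {(e.sample_id, e.gene): e.de_novo for e in out}
    assert flags[("M_1", "TP53")] is False
    assert flags[("M_1", "KRAS")] is True


def test_de_novo_amp_subsumes_primary_gain():
    primary = _events([("P_1", "MYC", "gain")])
    met = _events([("M_1", "MYC", "amp")])
    out = de_novo_driver_events(primary, met, ["MYC"])
    assert [e.de_novo for e in out] == [False]


def test_de_novo_requires_primary_sample():
    met = _events([("M_1", "TP53", "mutation")])
    with pytest.raises(ValueError, match="no primary sample"):
        de_novo_driver_events(_events([]), met, ["TP53"])
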
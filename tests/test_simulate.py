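"""Simulator tests: determinism, ground-truth consistency, read-count
model, decoys and cohort generation."""

import numpy as np
import pandas as pd
import pytest

import metroute as mr
from metroute.simulate import SiteSpec, child_seed, default_sites


def test_same_seed_identical_tables():
    a = mr.simulate_patient(mr.SimConfig(seed=123), patient_id="X")
    b = mr.simulate_patient(mr.SimConfig(seed=123), patient_id="X")
    pd.testing.assert_frame_equal(a.variants, b.variants)
    pd.testing.assert_frame_equal(a.normals, b.normals)
    pd.testing.assert_frame_equal(a.segments, b.segments)
    pd.testing.assert_frame_equal(a.sample_sheet, b.sample_sheet)
    assert a.truth.to_json() == b.truth.to_json()


def test_different_seed_different_variants():
    a = mr.simulate_patient(mr.SimConfig(seed=1), patient_id="X")
    b = mr.simulate_patient(mr.SimConfig(seed=2), patient_id="X")
    assert set(zip(a.variants["chrom"], a.variants["pos0"])) != \
        set(zip(b.variants["chrom"], b.variants["pos0"]))


def test_trunk_mutations_shared_by_all_samples():
    p = mr.simulate_patient(mr.SimConfig(seed=3), patient_id="X")
    trunk = set(p.truth.trunk_mutations)
    assert trunk
    for sid in p.sample_sheet["sample_id"]:
        assert trunk <= p.truth.sample_mutation_set(sid)


def test_private_mutations_are_private():
    p = mr.simulate_patient(mr.SimConfig(seed=4), patient_id="X")
    t = p.truth
    samples = list(p.sample_sheet["sample_id"])
    for sid in samples:
        own_clone = t.sample_clone_map[sid]
        private = set(t.clone_mutations[own_clone])
        for other in samples:
            if other != sid:
                assert not (private & t.sample_mutation_set(other))


def test_expected_vaf_at_high_depth():
    # GS config keeps most of the genome at cn = 2, so present calls should
    # concentrate near vaf = purity / (purity*2 + 2*(1-purity)) = 0.35
    cfg = mr.SimConfig(seed=5, subtype="GS", depth_mean=10_000)
    p = mr.simulate_patient(cfg, patient_id="X")
    trunk = set(p.truth.trunk_mutations)
    v = p.variants
    keys = [mr.variant_key(c, q, r, a) for c, q, r, a in
            zip(v["chrom"], v["pos0"], v["ref"], v["alt"])]
    v = v.assign(key=keys)
    called = v[(v["key"].isin(trunk)) & (v["alt_count"] > 0)]
    assert len(called) > 50
    assert abs(called["vaf"].mean() - 0.35) < 0.02


def test_trunk_fraction_one_gives_long_trunk():
    p = mr.simulate_patient(mr.SimConfig(seed=6, trunk_fraction=1.0),
                            patient_id="X")
    n_trunk = len(p.truth.trunk_mutations)
    sizes = [len(p.truth.sample_mutation_set(s))
             for s in p.sample_sheet["sample_id"]]
    assert n_trunk / np.mean(sizes) > 0.9


def test_explicit_clonal_count_overrides_fraction():
    p = mr.simulate_patient(mr.SimConfig(seed=7, n_clonal_mut=5),
                            patient_id="X")
    assert len(p.truth.trunk_mutations) == 5


def test_chain_seeding_records_chain_edge():
    sites = default_sites("GS", chain_seeding=True)
    p = mr.simulate_patient(mr.SimConfig(seed=8, subtype="GS", sites=sites),
                            patient_id="X")
    assert ("peritoneal", "ovarian") in p.truth.true_migration_edges


def test_cyclic_seed_from_rejected():
    sites = [
        SiteSpec("primary", "primary", n_samples=1, layers=["T3"]),
        SiteSpec("a", "hematogenous", organ="liver", seed_from="b"),
        SiteSpec("b", "hematogenous", organ="lung", seed_from="a"),
    ]
    with pytest.raises(ValueError, match="cyclic"):
        mr.simulate_patient(mr.SimConfig(seed=9, sites=sites))


def test_config_requires_primary_and_met():
    with pytest.raises(ValueError, match="primary"):
        mr.SimConfig(sites=[SiteSpec("liver", "hematogenous", organ="liver",
                                     seed_from="primary")])
    with pytest.raises(ValueError, match="metastatic"):
        mr.SimConfig(sites=[SiteSpec("primary", "primary", layers=["T3"])])


def test_decoys_removed_by_filter():
    cfg = mr.SimConfig(seed=10, inject_decoys=True)
    clean = mr.simulate_patient(mr.SimConfig(seed=10), patient_id="X")
    noisy = mr.simulate_patient(cfg, patient_id="X")
    kept = mr.filter_variants(noisy.variants, noisy.normals)
    n_keys = lambda df: df.groupby(  # noqa: E731
        ["chrom", "pos0", "ref", "alt"]).ngroups
    assert n_keys(noisy.variants) == n_keys(clean.variants) + 4
    assert n_keys(kept) == n_keys(clean.variants)


def test_artifact_site_flagged_in_truth_and_spectrum():
    sites = default_sites("CIN")
    sites[-1].artifact = True  # liver samples carry artifact calls
    p = mr.simulate_patient(mr.SimConfig(seed=11, sites=sites),
                            patient_id="X")
    assert p.truth.artifact_samples
    sid = p.truth.artifact_samples[0]
    counts = mr.context_count_vector(p.variants, sid)
    cat = mr.default_catalog()
    ev = mr.refit_signature_exposures(counts, cat, sample_id=sid)
    assert ev.exposures["ARTIFACT"] > 0.5


def test_normals_have_clean_deep_coverage():
    p = mr.simulate_patient(mr.SimConfig(seed=12), patient_id="X")
    assert (p.normals["alt_count"] == 0).all()
    assert (p.normals["depth"] >= 11).all()


def test_child_seed_deterministic_and_in_range():
    assert child_seed(42, 3) == child_seed(42, 3)
    assert child_seed(42, 3) != child_seed(42, 4)
    for i in range(20):
        assert 0 <= child_seed(1, i) < 2**31


def test_simulate_cohort_shapes_and_determinism():
    a = mr.simulate_cohort(3, seed=99)
    b = mr.simulate_cohort(3, seed=99)
    assert [p.patient_id for p in a] == ["GCS01", "GCS02", "GCS03"]
    for pa, pb in zip(a, b):
        pd.testing.assert_frame_equal(pa.variants, pb.variants)
    with pytest.raises(ValueError):
        mr.simulate_cohort(0)


def test_simulate_survival_censoring():
    patients = mr.simulate_cohort(6, seed=5)
    surv = mr.simulate_survival(patients, seed=5, follow_up_days=100.0)
    assert (surv["time"] <= 100.0).all()
    assert set(surv["progression"]) <= {"branched", "diaspora"}
    censored = surv[~surv["event"]]
    assert (censored["time"] == 100.0).all()


def test_write_patient_round_trips_through_readers(tmp_path):
    from metroute.simulate import write_patient

    p = mr.simulate_patient(mr.SimConfig(seed=13), patient_id="X")
    write_patient(p, tmp_path)
    v = mr.read_variant_table(tmp_path / "variants.tsv")
    n = mr.read_normal_table(tmp_path / "normals.tsv")
    s = mr.read_segments(tmp_path / "segments.tsv")
    sheet = mr.read_sample_sheet(tmp_path / "samples.tsv")
    assert len(v) == len(p.variants)
    assert len(n) == len(p.normals)
    assert len(s) == len(p.segments)
    assert list(sheet["sample_id"]) == list(p.sample_sheet["sample_id"])
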
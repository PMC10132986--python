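"""Synthetic-cohort generator: reproducibility, generative invariants and
agreement with the closed-form expectations."""

import numpy as np
import pytest

from tumortime.ccf import expected_vaf
from tumortime.errors import ConfigError
from tumortime.genome import ARMS, GENOME_MB, N_ARMS, ARM_LENGTHS_MB
from tumortime.synthetic import (EventSpec, SimConfig, WgdParams,
                                 simulate_clock_cohort, simulate_cohort,
                                 simulate_pi_cohort, simulate_tumor)


def test_genome_abstraction():
    assert N_ARMS == 39
    assert 2600 < GENOME_MB < 3100
    for arm in ("13p", "14p", "15p", "21p", "22p"):
        assert arm not in ARM_LENGTHS_MB     # acrocentric short arms


def test_config_validation_names_field():
    with pytest.raises(ConfigError, match="n_tumors"):
        simulate_cohort(SimConfig(n_tumors=0))
    with pytest.raises(ConfigError, match="purity_range"):
        SimConfig(purity_range=(0.0, 0.5)).validate()
    with pytest.raises(ConfigError, match="coverage_mean"):
        SimConfig(coverage_mean=-1).validate()
    with pytest.raises(ConfigError, match="prevalence"):
        SimConfig(event_menu=[EventSpec("+1q", 1.5, (0, 1))]).validate()
    with pytest.raises(ConfigError, match="immune_fraction"):
        SimConfig(wgd_params=WgdParams(immune_fraction=2.0)).validate()


def test_same_seed_byte_identical(tmp_path):
    cfg = SimConfig(n_tumors=3, seed=9)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_cohort(cfg).write(a)
    simulate_cohort(cfg).write(b)
    for name in ("mutations.tsv", "segments.tsv", "metadata.tsv",
                 "truth.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes()


def test_cohort_file_shapes(small_bundle):
    b = small_bundle
    assert b.metadata.shape[0] == 6
    assert set(b.mutations["tumor_id"]) == set(b.metadata["tumor_id"])
    assert b.segments.groupby("tumor_id").size().eq(N_ARMS).all()
    ledger = b.truth_ledger()
    assert len(ledger["tumors"]) == 6
    for t in ledger["tumors"]:
        times = [e["t"] for e in t["events"]]
        assert times == sorted(times)         # weakly increasing order


def test_pure_diploid_expected_vaf(rng):
    """Purity 1, neutral genome, no copy events: every clonal mutation has
    expected VAF 0.5."""
    cfg = SimConfig(n_tumors=1, purity_range=(1.0, 1.0), event_menu=[],
                    subclone_ccf=None)
    _, muts, segs, _ = simulate_tumor(cfg, rng)
    assert (muts["true_multiplicity"] == 1).all()
    assert (segs["major_cn"] == 1).all() and (segs["minor_cn"] == 1).all()
    maf = muts["alt_count"] / (muts["alt_count"] + muts["ref_count"])
    se = 3 * 0.5 / np.sqrt(muts["alt_count"].add(muts["ref_count"]).sum())
    assert maf.mean() == pytest.approx(0.5, abs=max(3 * se, 0.01))


def test_forced_wgd_multiplicity_rule(rng):
    """WGD at t = 0.5 on a 2:2 outcome: pre-doubling mutations have
    multiplicity 2, post-doubling multiplicity 1."""
    cfg = SimConfig(n_tumors=1, purity_range=(1.0, 1.0),
                    event_menu=[EventSpec("WGD", 1.0, (0.5, 0.5))],
                    wgd_params=WgdParams(immune_fraction=1.0),
                    subclone_ccf=None)
    history, muts, segs, _ = simulate_tumor(cfg, rng)
    assert history.wge_label == "WGD"
    assert (segs["major_cn"] == 2).all() and (segs["minor_cn"] == 2).all()
    pre = muts[muts["true_t"] < 0.5]
    post = muts[muts["true_t"] > 0.5]
    assert (pre["true_multiplicity"] == 2).all()
    assert (post["true_multiplicity"] == 1).all()


def test_clock_accrual_slope():
    """Across 1,000 tumors the regression of true clonal CpG>T per Mb on
    age recovers the configured clock rate (law of large numbers)."""
    rng = np.random.default_rng(77)
    burdens, ages = simulate_clock_cohort(1000, 0.37, (40, 80), 30.0, rng)
    slope = float(ages @ burdens / (ages @ ages))
    assert slope == pytest.approx(0.37, abs=0.02)


def test_full_simulator_clock_mean(rng):
    """The per-tumor clonal CpG>T count from the full simulator has mean
    close to clock_rate * age * covered Mb on a neutral genome."""
    cfg = SimConfig(n_tumors=1, purity_range=(1.0, 1.0), event_menu=[],
                    subclone_ccf=None, age_range=(60.0, 60.0))
    counts = []
    for _ in range(30):
        _, muts, _, _ = simulate_tumor(cfg, rng)
        counts.append((muts["context"] == "ACG").sum())
    expected = 0.37 * 60 * 30
    se = np.sqrt(expected / 30)
    assert np.mean(counts) == pytest.approx(expected, abs=4 * se)


def test_event_prevalence_matches_menu():
    menu = [EventSpec("-9p", 0.8, (0.0, 0.2)),
            EventSpec("+3q", 0.3, (0.4, 0.6))]
    cfg = SimConfig(n_tumors=150, seed=21, event_menu=menu,
                    subclone_ccf=None)
    bundle = simulate_cohort(cfg)
    for spec in menu:
        carried = sum(any(e.name == spec.name for e in h.events)
                      for h in bundle.histories)
        se = np.sqrt(spec.prevalence * (1 - spec.prevalence) / 150)
        assert carried / 150 == pytest.approx(spec.prevalence,
                                              abs=4 * se)


def test_observed_vaf_matches_closed_form(rng):
    """Mean observed VAF over many binomial draws converges to
    expected_vaf within 3 standard errors."""
    cfg = SimConfig(n_tumors=1, purity_range=(0.6, 0.6), event_menu=[],
                    subclone_ccf=None)
    _, muts, _, _ = simulate_tumor(cfg, rng)
    depth = muts["alt_count"] + muts["ref_count"]
    want = expected_vaf(1, 1.0, 0.6, 2)
    got = muts["alt_count"].sum() / depth.sum()
    se = np.sqrt(want * (1 - want) / depth.sum())
    assert got == pytest.approx(want, abs=3 * se)


def test_subclone_truth_labels(rng):
    cfg = SimConfig(n_tumors=1, subclone_ccf=0.35, event_menu=[])
    _, muts, _, _ = simulate_tumor(cfg, rng)
    sub = muts[muts["true_ccf"] < 1.0]
    assert len(sub) > 0
    assert (sub["true_ccf"] == 0.35).all()


def test_driver_snv_menu_entry(rng):
    cfg = SimConfig(
        n_tumors=1, purity_range=(1.0, 1.0),
        event_menu=[EventSpec("TP53", 1.0, (0.1, 0.2), arm="17p")],
        subclone_ccf=None)
    history, muts, _, _ = simulate_tumor(cfg, rng)
    drv = muts[muts["driver"] == "TP53"]
    assert len(drv) == 1
    assert any(e.name == "TP53" and e.kind == "driver_snv"
               for e in history.events)


def test_pi_cohort_shapes(rng):
    menu = [EventSpec("A", 1.0, (0.1, 0.3)), EventSpec("B", 0.5, (0.6, 0.9))]
    cohort = simulate_pi_cohort(20, menu, rng)
    assert len(cohort) == 20
    a_means = [ev["A"].mean() for ev in cohort.values() if "A" in ev]
    b_means = [ev["B"].mean() for ev in cohort.values() if "B" in ev]
    assert np.mean(a_means) < np.mean(b_means)
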
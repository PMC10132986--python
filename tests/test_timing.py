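"""Per-tumor timing: gain posteriors, whole-genome pooling, constrained
driver timing and whole-tumor assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tumortime.ccf import annotate_mutations
from tumortime.errors import DomainError
from tumortime.synthetic import SimConfig, simulate_cohort
from tumortime.timing import (ArmGainCounts, PiDistribution,
                              assemble_patient_timing, phi_of_t,
                              representative_integration,
                              time_hpv_integration, time_segment_gain,
                              time_snv_driver, time_wgd)


def grid_posterior_mean(n_hi, n_1, d, u, c, n_grid=2000):
    """Independent oracle: numeric integration of the exact likelihood on a
    t grid, with the same uniform-in-phi prior (density |dphi/dt|)."""
    t = (np.arange(n_grid) + 0.5) / n_grid
    phi = phi_of_t(t, d, u, c)
    w = phi ** n_hi * (1 - phi) ** n_1 * np.gradient(phi, t)
    return float((t * w).sum() / w.sum())


def test_gain_posterior_extremes():
    """No pre-gain mutations -> early gain; all pre-gain -> late gain."""
    assert time_segment_gain(0, 20, 1, 0, 2).mean() < 0.15
    assert time_segment_gain(20, 0, 1, 0, 2).mean() > 0.85


@pytest.mark.parametrize("profile", [(1, 0, 2), (1, 1, 3), (2, 0, 4)])
@pytest.mark.parametrize("n_hi,n_1", [(0, 5), (5, 15), (15, 5), (30, 30),
                                      (1, 0), (0, 30)])
def test_gain_posterior_matches_grid_oracle(profile, n_hi, n_1):
    got = time_segment_gain(n_hi, n_1, *profile).mean()
    want = grid_posterior_mean(n_hi, n_1, *profile)
    assert got == pytest.approx(want, abs=0.01)


def test_unpowered_gain_is_uniform():
    d = time_segment_gain(0, 0, 1, 1, 3)
    assert d.mean() == pytest.approx(0.5, abs=0.01)
    assert d.credible_interval(0.9)[1] > 0.9


def test_gain_domain_errors():
    with pytest.raises(DomainError):
        time_segment_gain(1, 1, 0, 0, 2)      # no duplicated copies
    with pytest.raises(DomainError):
        time_segment_gain(1, 1, 1, 1, 2)      # C must exceed d + u
    with pytest.raises(DomainError):
        time_segment_gain(-1, 1, 1, 0, 2)


def test_pi_distribution_normalization():
    for d in (PiDistribution.uniform(), PiDistribution.delta_one(),
              time_segment_gain(5, 10, 1, 1, 3)):
        assert d.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (d.probs >= 0).all()
    assert PiDistribution.delta_one().is_delta_one


def test_wgd_single_arm_equals_segment_gain():
    single = time_segment_gain(8, 12, 2, 0, 4)
    pooled, qc = time_wgd([ArmGainCounts("1p", 8, 12, 2, 0, 4)])
    assert pooled.mean() == pytest.approx(single.mean(), abs=1e-9)
    assert not qc


def test_wgd_pooling_narrows_interval():
    """Two arms with identical counts give a tighter credible interval
    than either alone (Beta variance shrinks with pooled counts)."""
    one = time_segment_gain(8, 12, 2, 0, 4)
    arms = [ArmGainCounts(a, 8, 12, 2, 0, 4) for a in ("1p", "1q")]
    pooled, qc = time_wgd(arms)
    lo1, hi1 = one.credible_interval(0.75)
    lo2, hi2 = pooled.credible_interval(0.75)
    assert hi2 - lo2 < hi1 - lo1
    assert not qc


def test_wgd_contradictory_arms_flagged():
    arms = [ArmGainCounts("1p", 25, 0, 2, 0, 4),
            ArmGainCounts("1q", 0, 25, 2, 0, 4)]
    _, qc = time_wgd(arms)
    assert qc


def test_wgd_requires_arms():
    with pytest.raises(DomainError):
        time_wgd([])


def test_snv_driver_rules(rng):
    gain = time_segment_gain(5, 15, 1, 1, 3)
    gain_samples = gain.sample(rng, 500)
    # Subclonal -> delta at 1.
    assert time_snv_driver(False, 1, gain_samples, rng).is_delta_one
    # Multiplicity > 1 on a gained segment -> before the gain, jointly.
    pre = time_snv_driver(True, 2, gain_samples, rng, n_samples=500)
    assert (pre.samples <= gain_samples).all()
    # Multiplicity 1 -> after the gain.
    post = time_snv_driver(True, 1, gain_samples, rng, n_samples=500)
    assert (post.samples >= gain_samples).all()
    # No informative copy context -> uniform.
    flat = time_snv_driver(True, 1, None, rng, n_samples=2000)
    assert flat.mean() == pytest.approx(0.5, abs=0.05)


def _annotate(bundle, tumor_id):
    meta = bundle.metadata.set_index("tumor_id")
    muts = bundle.mutations[bundle.mutations["tumor_id"] == tumor_id]
    segs = bundle.segments[bundle.segments["tumor_id"] == tumor_id]
    return (annotate_mutations(muts, segs,
                               float(meta.loc[tumor_id, "purity"])), segs)


def test_assemble_empty_without_clonal_mutations():
    ann = pd.DataFrame({"chrom_arm": [], "pos": [], "alt_count": [],
                        "ref_count": [], "clonal": [], "powered": [],
                        "map_multiplicity": [], "p_detect": []})
    segs = pd.DataFrame([{"chrom_arm": "1p", "start": 0, "end": 100,
                          "major_cn": 1, "minor_cn": 1}])
    result = assemble_patient_timing(ann, segs, "t")
    assert not result.events
    assert result.diagnostics


def test_assemble_joint_constraint_consistency(small_bundle, annotated_small):
    """In every joint posterior sample, a pre-gain driver mutation
    precedes its gain (checked on a constructed driver)."""
    # Construct a tumor with one gained arm carrying a multiplicity-2
    # clonal driver.
    rng = np.random.default_rng(5)
    n = 30
    depth = rng.poisson(150, size=n + 1)
    purity = 1.0
    vaf_m2 = 2 * purity / (2 * (1 - purity) + purity * 3)
    vaf_m1 = purity / (2 * (1 - purity) + purity * 3)
    m_true = np.array([2] * 10 + [1] * 20)
    alt = rng.binomial(depth[:n], np.where(m_true == 2, vaf_m2, vaf_m1))
    muts = pd.DataFrame({
        "tumor_id": "t", "chrom_arm": "3q", "pos": np.arange(n),
        "ref": "C", "alt": "T", "alt_count": alt,
        "ref_count": depth[:n] - alt, "context": "ACA", "driver": ""})
    drv_alt = rng.binomial(depth[n], vaf_m2)
    muts.loc[len(muts)] = ["t", "3q", n + 1, "C", "T", drv_alt,
                           depth[n] - drv_alt, "ACA", "PIK3CA"]
    segs = pd.DataFrame(
        [{"tumor_id": "t", "chrom_arm": "3q", "start": 0,
          "end": 10 ** 6, "major_cn": 2, "minor_cn": 1}]
        + [{"tumor_id": "t", "chrom_arm": a, "start": 0, "end": 10 ** 6,
            "major_cn": 1, "minor_cn": 1}
           for a in ("1p", "1q", "2p", "2q", "3p")])
    ann = annotate_mutations(muts, segs, purity)
    result = assemble_patient_timing(ann, segs, "t", seed=1)
    gain = result["+3q"].pi.samples
    driver = result["PIK3CA"].pi.samples
    assert ann.loc[len(ann) - 1, "map_multiplicity"] == 2
    assert (driver <= gain).all()


def test_assemble_rank_recovery():
    """Posterior-mean pi order correlates with the true event order in
    simulated tumors (average Kendall tau over the cohort)."""
    bundle = simulate_cohort(SimConfig(n_tumors=20, seed=17))
    taus = []
    for h in bundle.histories:
        ann, segs = _annotate(bundle, h.tumor_id)
        result = assemble_patient_timing(ann, segs, h.tumor_id, seed=2)
        truth = {e.name: e.t for e in h.events}
        names = [e.name for e in result.events
                 if e.name in truth or
                 (e.name == "WGT" and "WGD" in truth)]
        est = {e.name: e.pi.mean() for e in result.events}
        pairs = [(truth.get(n, truth.get("WGD")), est[n]) for n in names]
        if len(pairs) >= 3:
            t = stats.kendalltau([p[0] for p in pairs],
                                 [p[1] for p in pairs]).statistic
            if np.isfinite(t):
                taus.append(t)
    assert len(taus) >= 8
    assert np.mean(taus) >= 0.5


def test_hpv_integration_timing(rng):
    local = pd.DataFrame({
        "chrom_arm": "3q", "pos": np.arange(20), "ref": "C", "alt": "T",
        "context": "ACA", "clonal": True, "powered": True,
        "map_multiplicity": [1] * 18 + [2] * 2, "p_detect": 1.0})
    # High-multiplicity integration on an early gain -> early pi mass.
    early = time_hpv_integration(70, 30, 1.0, 2, 1, local, seed=4)
    assert early.mean() < 0.3
    # Subclonal integration -> delta at 1.
    sub = time_hpv_integration(5, 195, 1.0, 2, 1, local, seed=4)
    assert sub.is_delta_one


def test_hpv_apobec_exclusion():
    """APOBEC-context mutations do not contribute to the local gain
    timing counts at an integration site."""
    base = {"chrom_arm": "3q", "clonal": True, "powered": True,
            "p_detect": 1.0, "ref": "C"}
    apobec_heavy = pd.DataFrame(
        [dict(base, pos=i, alt="G", context="TCA", map_multiplicity=2)
         for i in range(30)]
        + [dict(base, pos=100 + i, alt="T", context="ACA",
                map_multiplicity=1) for i in range(10)])
    # With APOBEC excluded only the 10 multiplicity-1 mutations remain,
    # so the local gain is timed early and a multiplicity-2 integration
    # lands before it.
    pi = time_hpv_integration(70, 30, 1.0, 2, 1, apobec_heavy, seed=4)
    assert pi.mean() < 0.2


def test_representative_integration_site():
    sites = [("site_a", 12.0), ("site_b", 31.0), ("site_c", 2.5)]
    assert representative_integration(sites) == "site_b"
    with pytest.raises(DomainError):
        representative_integration([])
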
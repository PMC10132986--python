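"""MATH, ploidy classes, whole-genome-event calls and FGA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tumortime.errors import DomainError
from tumortime.genome import ARMS
from tumortime.heterogeneity import (MAD_SCALE, call_whole_genome_event,
                                     compute_fga, math_pre_post_wgd,
                                     math_score, merge_paired_samples,
                                     normal_mad_scale, ploidy_fractions,
                                     HeterogeneityProfile, PloidyFractions)


def test_math_examples():
    assert math_score([0.3, 0.3, 0.3, 0.3]) == pytest.approx(0.0)
    # MAD 0.2, median 0.4 -> 100 * 1.4826 * 0.5.
    assert math_score([0.2, 0.4, 0.6]) == pytest.approx(74.13)


def test_math_normal_consistency(rng):
    """For Normal(0.5, 0.1) MAFs the scaled MAD equals sigma, giving
    MATH = 100 * 0.1 / 0.5 = 20."""
    mafs = rng.normal(0.5, 0.1, size=40000)
    assert math_score(mafs) == pytest.approx(20.0, rel=0.05)


def test_math_depth_floor_and_errors():
    mafs = [0.2, 0.4, 0.6, 0.9]
    depths = [100, 100, 100, 5]
    assert math_score(mafs, depths) == pytest.approx(74.13)
    assert np.isnan(math_score([0.0, 0.0, 0.0]))
    with pytest.raises(DomainError):
        math_score([0.5])


@settings(deadline=None, max_examples=40)
@given(scale=st.floats(0.1, 2.0),
       seed=st.integers(0, 10 ** 6))
def test_math_scale_invariance(scale, seed):
    mafs = np.random.default_rng(seed).uniform(0.05, 0.6, size=30)
    scaled = np.clip(mafs * scale, None, None)
    assert math_score(scaled) == pytest.approx(math_score(mafs), rel=1e-9)


def test_mad_scale_constant():
    assert round(normal_mad_scale(), 4) == MAD_SCALE


def _segments(states, length=10 ** 6):
    """Segment table from a list of (major, minor) arm states."""
    return pd.DataFrame(
        [{"chrom_arm": ARMS[i], "start": 0, "end": length,
          "major_cn": mj, "minor_cn": mn}
         for i, (mj, mn) in enumerate(states)])


@pytest.mark.parametrize("fracs,expected", [
    ((0.80, 0.10, 0.10), "diploid"),     # diploid fraction > 0.65
    ((0.30, 0.50, 0.20), "triploid"),    # non-diploid, triploid > 0.35
    ((0.40, 0.20, 0.40), "tetraploid"),  # non-diploid, triploid <= 0.35
])
def test_ploidy_class_cascade(fracs, expected):
    n = 20
    counts = [round(f * n) for f in fracs]
    states = ([(1, 1)] * counts[0] + [(2, 1)] * counts[1]
              + [(2, 2)] * counts[2])
    pf = ploidy_fractions(_segments(states))
    assert pf.aneuploidy_class == expected
    assert pf.diploid == pytest.approx(fracs[0], abs=0.03)


def test_ploidy_partition_is_total(rng):
    """Every copy profile lands in exactly one of the three classes."""
    for _ in range(25):
        states = [tuple(sorted(rng.integers(0, 4, size=2))[::-1])
                  for _ in range(15)]
        pf = ploidy_fractions(_segments(states))
        assert pf.aneuploidy_class in ("diploid", "triploid", "tetraploid")


def test_ploidy_empty_segments_error():
    with pytest.raises(DomainError):
        ploidy_fractions(_segments([(1, 1)], length=0))


def test_wge_call_half_arms_amplified():
    states = [(2, 1)] * 22 + [(1, 1)] * 17     # 22 of 39 arms amplified
    call = call_whole_genome_event(_segments(states))
    assert call.event
    assert call.n_amplified == 22


def test_wge_call_four_biallelic_arms():
    states = [(2, 2)] * 4 + [(2, 1)] * 1 + [(1, 1)] * 34
    call = call_whole_genome_event(_segments(states))
    assert call.event
    assert call.n_biallelic == 4


def test_wge_call_below_both_thresholds():
    states = [(2, 2)] * 3 + [(2, 1)] * 3 + [(1, 1)] * 33
    call = call_whole_genome_event(_segments(states))
    assert not call.event
    assert call.label == "none"


def test_wge_labels_follow_ploidy_class():
    wgt = call_whole_genome_event(_segments([(2, 1)] * 30 + [(1, 1)] * 9))
    assert wgt.label == "WGT"
    wgd = call_whole_genome_event(_segments([(2, 2)] * 30 + [(1, 1)] * 9))
    assert wgd.label == "WGD"


def test_fga_baselines():
    assert compute_fga(_segments([(1, 1)] * 10), False) == 0.0
    assert compute_fga(_segments([(2, 1)] * 3 + [(1, 1)] * 7), False) == \
        pytest.approx(0.3)
    assert compute_fga(_segments([(2, 2)] * 10), True) == 0.0
    assert 0.0 <= compute_fga(_segments([(3, 0)] * 5 + [(1, 1)] * 5),
                              True) <= 1.0


def _annotated(mult, maf, maj=2, depth=100):
    n = len(mult)
    return pd.DataFrame({
        "alt_count": (np.asarray(maf) * depth).astype(int),
        "ref_count": depth - (np.asarray(maf) * depth).astype(int),
        "maf": maf, "clonal": [True] * n, "map_multiplicity": mult,
        "major_cn": [maj] * n})


def test_math_pre_post_wgd_split(rng):
    """Doubling splits MAF modes: post-doubling MATH is at least the
    pre-doubling MATH in an early-doubled tumor."""
    pre_maf = rng.normal(0.5, 0.02, 40)       # multiplicity-2 mutations
    post_maf = rng.normal(0.25, 0.02, 40)     # multiplicity-1 mutations
    ann = _annotated([2] * 40 + [1] * 40,
                     np.concatenate([pre_maf, post_maf]))
    pre, post = math_pre_post_wgd(ann)
    assert pre is not None and post is not None
    assert post >= pre


def test_math_pre_post_absent_sets():
    ann = _annotated([2] * 15, list(np.linspace(0.4, 0.6, 15)))
    pre, post = math_pre_post_wgd(ann)
    assert pre is not None
    assert post is None                        # all mutations pre-doubling


def _profile(math, fga, cls="diploid", wge="none"):
    return HeterogeneityProfile(
        "t", math, fga, PloidyFractions(0.8, 0.1, 0.1, cls), wge)


def test_merge_paired_samples():
    merged = merge_paired_samples([_profile(30, 0.2), _profile(40, 0.4)])
    assert merged.math == pytest.approx(35.0)
    assert merged.fga == pytest.approx(0.3)
    assert not merged.qc_flags
    same = merge_paired_samples([_profile(30, 0.2), _profile(30, 0.2)])
    assert same.math == 30.0
    discordant = merge_paired_samples(
        [_profile(30, 0.2, "diploid"), _profile(40, 0.4, "triploid", "WGT")])
    assert "discordant_aneuploidy_class" in discordant.qc_flags
    assert "discordant_wge_call" in discordant.qc_flags
    with pytest.raises(DomainError):
        merge_paired_samples([_profile(30, 0.2)])
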
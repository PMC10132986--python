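"""Multiplicity and cancer-cell-fraction (CCF) inference for somatic SNVs.

Each mutation is annotated with a joint posterior over (multiplicity m,
CCF c) given its alt/ref read counts, the sample purity p and the local
allelic copy number.  The observation model is the standard purity-dilution
identity

    VAF = m * c * p / (2 * (1 - p) + p * N)

where N is the total local copy number in cancer cells, combined with a
binomial read-count likelihood and a prior over the admissible (m, c)
grid that is uniform plus a point mass at c = 1 (the clonal spike; see
``CLONAL_PRIOR_SPIKE``).  The spike is essential: the likelihood is a
ridge in the product m*c, and under a flat prior the broad (m=2, c~0.5)
branch of the ridge swamps the boundary-pinned (m=1, c=1) peak whenever
binomial noise pushes the observed VAF above its clonal expectation,
mislabeling clonal mutations as subclonal.  A mutation is called clonal
when the posterior probability
that its CCF exceeds the clonality threshold (default 0.85) is at least
one half; ties at exactly one half are called clonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

#: CCF grid: 101 uniform points on [0, 1].
CCF_GRID = np.linspace(0.0, 1.0, 101)

#: Posterior CCF mass above this value determines clonality.
CLONAL_CCF_THRESHOLD = 0.85

#: Prior mass on the c = 1 grid column, relative to the uniform rest.
#: 0.5 splits prior mass evenly between "exactly clonal" and the open CCF
#: continuum.
CLONAL_PRIOR_SPIKE = 0.5

#: Sites with fewer reads are marked unpowered and excluded from timing.
MIN_POWERED_DEPTH = 10

#: Minimum alt reads for a variant caller to detect a site (power model).
MIN_ALT_READS = 3


def expected_vaf(multiplicity: int, ccf: float, purity: float,
                 local_total_cn: int) -> float:
    """Expected variant allele fraction under the purity-dilution identity.

    Parameters
    ----------
    multiplicity : int
        Copies per cancer cell carrying the mutation, 1..local_total_cn.
    ccf : float
        Fraction of cancer cells carrying the mutation, in [0, 1].
    purity : float
        Cancer-cell fraction of the sample, in (0, 1].
    local_total_cn : int
        Total copy number of the locus in cancer cells.
    """
    if not 0.0 < purity <= 1.0:
        raise DomainError(f"purity must be in (0, 1], got {purity}")
    if not 0.0 <= ccf <= 1.0:
        raise DomainError(f"ccf must be in [0, 1], got {ccf}")
    if multiplicity < 1 or multiplicity > local_total_cn:
        raise DomainError(
            f"multiplicity {multiplicity} outside 1..{local_total_cn}")
    return multiplicity * ccf * purity / (2.0 * (1.0 - purity)
                                          + purity * local_total_cn)


def detection_power(depth, vaf, min_alt: int = MIN_ALT_READS):
    """P(detect) = P(Binomial(depth, vaf) >= min_alt).

    Used both to mark unpowered sites and to weight mutation counts when
    timing copy gains (each observed mutation counts 1/P(detect)).
    """
    depth = np.asarray(depth)
    vaf = np.asarray(vaf)
    return 1.0 - stats.binom.cdf(min_alt - 1, depth, vaf)


def _log_prior(m_max: int) -> np.ndarray:
    """Log prior over the (m, ccf) grid: uniform plus the clonal spike."""
    prior = np.ones((m_max, CCF_GRID.size))
    spike_total = CLONAL_PRIOR_SPIKE / (1.0 - CLONAL_PRIOR_SPIKE) \
        * prior.sum()
    prior[:, -1] += spike_total / m_max
    return np.log(prior / prior.sum())


@dataclass
class MutationAnnotation:
    """Posterior summaries for one somatic SNV."""

    multiplicity_posterior: np.ndarray  # P(m), m = 1..m_max
    ccf_posterior: np.ndarray           # histogram over CCF_GRID
    map_multiplicity: int
    ccf_mean: float
    p_clonal: float                     # P(ccf >= threshold)
    clonal: bool
    powered: bool
    total_cn: int

    def __post_init__(self) -> None:
        if self.multiplicity_posterior is not None:
            s = float(self.multiplicity_posterior.sum())
            if abs(s - 1.0) > 1e-6:
                raise ValueError("multiplicity posterior must sum to 1")


def annotate_mutation(alt_count: int, ref_count: int, purity: float,
                      major_cn: int, minor_cn: int,
                      clonal_threshold: float = CLONAL_CCF_THRESHOLD,
                      ) -> MutationAnnotation:
    """Annotate a single mutation from read counts and local copy number.

    The admissible multiplicity range is 1..max(major, minor): a point
    mutation arises on one parental allele and can be amplified at most to
    that allele's copy number.
    """
    depth = alt_count + ref_count
    total_cn = int(major_cn + minor_cn)
    m_max = max(int(major_cn), int(minor_cn), 1)
    if depth <= 0:
        # Zero-depth sites carry no information: unpowered, flat posteriors.
        return MutationAnnotation(
            multiplicity_posterior=np.full(m_max, 1.0 / m_max),
            ccf_posterior=np.full(CCF_GRID.size, 1.0 / CCF_GRID.size),
            map_multiplicity=1, ccf_mean=0.5, p_clonal=np.nan,
            clonal=False, powered=False, total_cn=total_cn)

    denom = 2.0 * (1.0 - purity) + purity * total_cn
    m_grid = np.arange(1, m_max + 1)
    # vaf[m, c] grid; likelihood is binomial in the alt count.
    vaf = (m_grid[:, None] * CCF_GRID[None, :] * purity) / denom
    loglik = stats.binom.logpmf(alt_count, depth, vaf) + _log_prior(m_max)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()

    mult_post = post.sum(axis=1)
    ccf_post = post.sum(axis=0)
    ccf_mean = float(ccf_post @ CCF_GRID)
    p_clonal = float(ccf_post[CCF_GRID >= clonal_threshold].sum())
    # The likelihood is a ridge in m*ccf, so the multiplicity of a clonal
    # mutation is called conditional on clonality: within the clonal CCF
    # region the ridge degeneracy (m=1, c=1) vs (m=2, c=0.5) disappears.
    if p_clonal >= 0.5:
        clonal_mass = post[:, CCF_GRID >= clonal_threshold].sum(axis=1)
        map_m = int(m_grid[np.argmax(clonal_mass)])
    else:
        map_m = int(m_grid[np.argmax(mult_post)])
    return MutationAnnotation(
        multiplicity_posterior=mult_post,
        ccf_posterior=ccf_post,
        map_multiplicity=map_m,
        ccf_mean=ccf_mean,
        p_clonal=p_clonal,
        clonal=bool(p_clonal >= 0.5),
        powered=bool(depth >= MIN_POWERED_DEPTH),
        total_cn=total_cn,
    )


def classify_clonal(annotation: MutationAnnotation,
                    threshold: float = CLONAL_CCF_THRESHOLD) -> bool:
    """Clonal iff posterior P(ccf >= threshold) >= 0.5 (ties are clonal)."""
    p = float(annotation.ccf_posterior[CCF_GRID >= threshold].sum())
    return p >= 0.5


def _segment_lookup(segments: pd.DataFrame):
    """Return a function (arm, pos) -> (major, minor) or None."""
    by_arm: dict[str, np.ndarray] = {}
    for arm, sub in segments.groupby("chrom_arm"):
        by_arm[arm] = sub[["start", "end", "major_cn", "minor_cn"]].to_numpy()

    def lookup(arm, pos):
        rows = by_arm.get(arm)
        if rows is None:
            return None
        hit = rows[(rows[:, 0] <= pos) & (pos < rows[:, 1])]
        if hit.size == 0:
            return None
        return int(hit[0, 2]), int(hit[0, 3])

    return lookup


def annotate_mutations(mutations: pd.DataFrame, segments: pd.DataFrame,
                       purity: float,
                       clonal_threshold: float = CLONAL_CCF_THRESHOLD,
                       ) -> pd.DataFrame:
    """Vectorized annotation of a mutation table for one tumor.

    Expects the mutation TSV dialect (chrom_arm, pos, alt_count, ref_count,
    ...) and a SEG-style table (chrom_arm, start, end, major_cn, minor_cn).
    Returns a copy of ``mutations`` with added columns: major_cn, minor_cn,
    total_cn, map_multiplicity, ccf_mean, p_clonal, clonal, powered, maf,
    p_detect.
    """
    out = mutations.reset_index(drop=True).copy()
    lookup = _segment_lookup(segments)
    cn = [lookup(a, p) for a, p in zip(out["chrom_arm"], out["pos"])]
    out["major_cn"] = [c[0] if c else 1 for c in cn]
    out["minor_cn"] = [c[1] if c else 1 for c in cn]
    out["total_cn"] = out["major_cn"] + out["minor_cn"]

    depth = (out["alt_count"] + out["ref_count"]).to_numpy()
    alt = out["alt_count"].to_numpy()
    with np.errstate(invalid="ignore"):
        out["maf"] = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)

    n = len(out)
    map_mult = np.ones(n, dtype=int)
    ccf_mean = np.full(n, 0.5)
    p_clonal = np.full(n, np.nan)

    # Group mutations by local copy state so the (m, ccf) grid is shared.
    for (maj, mnr), idx in out.groupby(["major_cn", "minor_cn"]).groups.items():
        idx = np.asarray(idx)
        total = int(maj + mnr)
        m_max = max(int(maj), int(mnr), 1)
        denom = 2.0 * (1.0 - purity) + purity * total
        m_grid = np.arange(1, m_max + 1)
        vaf = (m_grid[:, None] * CCF_GRID[None, :] * purity) / denom
        d = depth[idx]
        a = alt[idx]
        ok = d > 0
        if not ok.any():
            continue
        ll = stats.binom.logpmf(a[ok, None, None], d[ok, None, None],
                                vaf[None, :, :]) + _log_prior(m_max)
        ll -= ll.max(axis=(1, 2), keepdims=True)
        post = np.exp(ll)
        post /= post.sum(axis=(1, 2), keepdims=True)
        mp = post.sum(axis=2)          # (n_ok, m)
        cp = post.sum(axis=1)          # (n_ok, ccf)
        sel = idx[ok]
        ccf_mean[sel] = cp @ CCF_GRID
        pc = cp[:, CCF_GRID >= clonal_threshold].sum(axis=1)
        p_clonal[sel] = pc
        # Multiplicity conditional on clonality for clonal calls (the
        # m*ccf ridge degeneracy otherwise inflates m); marginal otherwise.
        clonal_mass = post[:, :, CCF_GRID >= clonal_threshold].sum(axis=2)
        cond = np.where(pc[:, None] >= 0.5, clonal_mass, mp)
        map_mult[sel] = m_grid[np.argmax(cond, axis=1)]

    out["map_multiplicity"] = map_mult
    out["ccf_mean"] = ccf_mean
    out["p_clonal"] = p_clonal
    out["clonal"] = p_clonal >= 0.5
    out["powered"] = depth >= MIN_POWERED_DEPTH
    # Detection power at the MAP multiplicity, assuming a clonal mutation.
    denom = 2.0 * (1.0 - purity) + purity * out["total_cn"].to_numpy()
    vaf_map = map_mult * purity / denom
    out["p_detect"] = detection_power(np.maximum(depth, 1), vaf_map)
    return out
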
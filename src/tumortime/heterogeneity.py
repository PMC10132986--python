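"""Intratumor heterogeneity and aneuploidy metrics.

MATH (mutant-allele tumor heterogeneity) is the median-normalized width of
the distribution of mutant allele fractions:

    MATH = 100 * k * median(|MAF - median(MAF)|) / median(MAF)

with k = 1.4826, the factor that makes the median absolute deviation of a
normal distribution equal its standard deviation (1 / Phi^-1(0.75)).

The aneuploidy class is assigned from length-weighted genome fractions at
total copy 2/3/4: diploid fraction > 0.65 -> diploid; otherwise triploid
fraction > 0.35 -> triploid; otherwise tetraploid.  A whole-genome event is
called when at least half of the chromosome arms are amplified or at least
four arms are amplified on both alleles, and labeled WGT or WGD from the
ploidy class.  FGA is the length fraction of the genome whose allelic copy
number deviates by more than 0.2 from one copy per allele (two copies per
allele after a whole-genome event).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

#: MAD-to-sigma scale factor of a normal distribution, 1/Phi^-1(0.75).
MAD_SCALE = 1.4826

#: MATH uses raw MAFs at sites with at least this many reads.
MATH_DEPTH_FLOOR = 20

#: Allelic copy deviation from baseline counted as altered by FGA.
FGA_DEVIATION = 0.2


def normal_mad_scale() -> float:
    """Compute 1 / Phi^-1(0.75) from the normal quantile function."""
    return float(1.0 / stats.norm.ppf(0.75))


def math_score(mafs, depths=None, depth_floor: int = MATH_DEPTH_FLOOR) -> float:
    """MATH score of a set of mutant allele fractions.

    Raw observed MAFs are used, without purity correction.  When ``depths``
    is given, sites below ``depth_floor`` reads are excluded first.
    Returns NaN when the median MAF is zero (undefined score).
    """
    mafs = np.asarray(mafs, dtype=float)
    if depths is not None:
        mafs = mafs[np.asarray(depths) >= depth_floor]
    mafs = mafs[np.isfinite(mafs)]
    if mafs.size < 2:
        raise DomainError("MATH requires at least 2 mutations above the "
                          "depth floor")
    med = np.median(mafs)
    if med == 0:
        return float("nan")
    mad = np.median(np.abs(mafs - med))
    return float(100.0 * MAD_SCALE * mad / med)


@dataclass
class PloidyFractions:
    diploid: float
    triploid: float
    tetraploid: float
    aneuploidy_class: str  # diploid | triploid | tetraploid


def _lengths(segments: pd.DataFrame) -> np.ndarray:
    lengths = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    if lengths.sum() <= 0:
        raise DomainError("segments cover zero length")
    return lengths


def ploidy_fractions(segments: pd.DataFrame) -> PloidyFractions:
    """Length-weighted genome fractions at total copy 2, 3 and 4, plus the
    aneuploidy class by the fixed cascade."""
    lengths = _lengths(segments)
    total = (segments["major_cn"] + segments["minor_cn"]).to_numpy(dtype=float)
    total = np.rint(total)
    w = lengths / lengths.sum()
    dip = float(w[total == 2].sum())
    tri = float(w[total == 3].sum())
    tet = float(w[total == 4].sum())
    if dip > 0.65:
        cls = "diploid"
    elif tri > 0.35:
        cls = "triploid"
    else:
        cls = "tetraploid"
    return PloidyFractions(dip, tri, tet, cls)


@dataclass
class WholeGenomeCall:
    event: bool
    label: str          # none | WGD | WGT
    n_arms: int
    n_amplified: int
    n_biallelic: int
    qc_flag: bool = False


def call_whole_genome_event(segments: pd.DataFrame) -> WholeGenomeCall:
    """Call a whole-genome amplification from arm-level copy states.

    An arm is amplified when total copy exceeds 2 over at least half its
    covered length, and amplified on both alleles when both allelic copies
    are >= 2 over at least half its length.  The event is called when at
    least half of the arms are amplified or at least four arms are
    amplified on both alleles; the label follows the ploidy class (WGT for
    triploid, WGD for tetraploid).  An event call in a diploid-class tumor
    is QC-flagged and labeled none.
    """
    n_amp = 0
    n_bi = 0
    arms = segments.groupby("chrom_arm")
    for _, sub in arms:
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        total = (sub["major_cn"] + sub["minor_cn"]).to_numpy(dtype=float)
        both = ((sub["major_cn"].to_numpy(dtype=float) >= 2)
                & (sub["minor_cn"].to_numpy(dtype=float) >= 2))
        lt = lengths.sum()
        if lt <= 0:
            continue
        if lengths[total > 2].sum() >= 0.5 * lt:
            n_amp += 1
        if lengths[both].sum() >= 0.5 * lt:
            n_bi += 1
    n_arms = arms.ngroups
    if n_arms == 0:
        raise DomainError("no arms in segment table")
    event = (n_amp >= 0.5 * n_arms) or (n_bi >= 4)
    if not event:
        return WholeGenomeCall(False, "none", n_arms, n_amp, n_bi)
    cls = ploidy_fractions(segments).aneuploidy_class
    if cls == "triploid":
        return WholeGenomeCall(True, "WGT", n_arms, n_amp, n_bi)
    if cls == "tetraploid":
        return WholeGenomeCall(True, "WGD", n_arms, n_amp, n_bi)
    # Diploid-class tumors cannot carry a genome-wide amplification label.
    return WholeGenomeCall(True, "none", n_arms, n_amp, n_bi, qc_flag=True)


def compute_fga(segments: pd.DataFrame, whole_genome_event: bool) -> float:
    """Fraction of the genome altered relative to the allelic baseline.

    Baseline is one copy per allele, or two per allele when a whole-genome
    event was called; a segment counts as altered when either allele
    deviates from baseline by more than 0.2 copies.  Allelic values may be
    purity-corrected real numbers.
    """
    lengths = _lengths(segments)
    base = 2.0 if whole_genome_event else 1.0
    maj = segments["major_cn"].to_numpy(dtype=float)
    mnr = segments["minor_cn"].to_numpy(dtype=float)
    altered = (np.abs(maj - base) > FGA_DEVIATION) | \
              (np.abs(mnr - base) > FGA_DEVIATION)
    return float(lengths[altered].sum() / lengths.sum())


def math_pre_post_wgd(annotated: pd.DataFrame, min_mutations: int = 10,
                      ) -> tuple[float | None, float | None]:
    """MATH decomposed into pre- and post-whole-genome-event mutation sets.

    The pre set comprises clonal mutations with multiplicity > 1 on doubled
    regions (these predate the doubling); the post set is the remaining
    clonal mutations.  Either score is None when its set has fewer than
    ``min_mutations`` mutations above the MATH depth floor.
    """
    clonal = annotated[annotated["clonal"]]
    pre_mask = (clonal["map_multiplicity"] >= 2) & (clonal["major_cn"] >= 2)
    out = []
    for subset in (clonal[pre_mask], clonal[~pre_mask]):
        depths = (subset["alt_count"] + subset["ref_count"]).to_numpy()
        ok = depths >= MATH_DEPTH_FLOOR
        if ok.sum() < min_mutations:
            out.append(None)
        else:
            out.append(math_score(subset["maf"].to_numpy()[ok]))
    return out[0], out[1]


@dataclass
class HeterogeneityProfile:
    """Per-tumor heterogeneity summary."""

    tumor_id: str
    math: float
    fga: float
    ploidy: PloidyFractions
    wge_call: str       # none | WGD | WGT
    math_pre_wgd: float | None = None
    math_post_wgd: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    @property
    def aneuploidy_class(self) -> str:
        return self.ploidy.aneuploidy_class


def heterogeneity_profile(annotated: pd.DataFrame, segments: pd.DataFrame,
                          tumor_id: str = "tumor") -> HeterogeneityProfile:
    """Compute the full heterogeneity profile for one tumor sample."""
    depths = (annotated["alt_count"] + annotated["ref_count"]).to_numpy()
    math = math_score(annotated["maf"].to_numpy(), depths)
    wge = call_whole_genome_event(segments)
    fga = compute_fga(segments, wge.event and wge.label != "none")
    ploidy = ploidy_fractions(segments)
    pre = post = None
    if wge.label in ("WGD", "WGT"):
        pre, post = math_pre_post_wgd(annotated)
    flags = ["wge_call_in_diploid_class"] if wge.qc_flag else []
    return HeterogeneityProfile(tumor_id, math, fga, ploidy, wge.label,
                                pre, post, flags)


def merge_paired_samples(profiles: list[HeterogeneityProfile],
                         ) -> HeterogeneityProfile:
    """Merge profiles of two (or more) samples from one tumor.

    MATH values are averaged (as are FGA values, a documented extension);
    discordant aneuploidy classes or whole-genome calls are QC-flagged and
    the first sample's call is kept.
    """
    if len(profiles) < 2:
        raise DomainError("merging requires at least 2 sample profiles")
    math = float(np.mean([p.math for p in profiles]))
    fga = float(np.mean([p.fga for p in profiles]))
    flags = sorted({f for p in profiles for f in p.qc_flags})
    if len({p.aneuploidy_class for p in profiles}) > 1:
        flags.append("discordant_aneuploidy_class")
    if len({p.wge_call for p in profiles}) > 1:
        flags.append("discordant_wge_call")
    first = profiles[0]
    return HeterogeneityProfile(first.tumor_id, math, fga, first.ploidy,
                                first.wge_call, first.math_pre_wgd,
                                first.math_post_wgd, flags)
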
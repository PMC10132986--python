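"""Per-tumor molecular timing of somatic events on the pi scale.

Every clonal event in a tumor receives a posterior distribution over a
molecular-time coordinate pi in [0, 1], anchored at the first (0) and last
(1) clonal events.  Copy gains are timed from the multiplicity structure of
the clonal mutations they carry: a mutation present on every copy of a
duplicated allele predates the duplication, one present on a single copy
postdates it.  With d pre-gain copies duplicated, u pre-gain copies left
single and C total copies after the gain, the expected fraction of
high-multiplicity mutations among informative clonal mutations at gain time
t is

    phi(t) = d * t / ((d + u) * t + C * (1 - t))

so a Beta(n_hi + 1, n_1 + 1) posterior on phi maps through the inverse of
this curve to a posterior on t.  Driver SNVs and losses are constrained
relative to the gains of their segments; untimeable clonal events get a
uniform pi distribution and subclonal events a point mass at pi = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import heterogeneity as het
from .errors import DomainError

#: Number of histogram bins of a PiDistribution.
N_PI_BINS = 100

#: Number of deterministic quantile samples behind a gain posterior.
N_QUANTILE_SAMPLES = 2048

#: Joint posterior samples drawn per tumor.
N_JOINT_SAMPLES = 1000

#: Power weights are capped at 1/MIN_DETECTION_POWER.
MIN_DETECTION_POWER = 0.05


class PiDistribution:
    """Posterior over molecular time pi in [0, 1], histogram-backed.

    Internally carries a sample array; the histogram view (``probs``) uses
    ``N_PI_BINS`` uniform bins and sums to 1.
    """

    def __init__(self, samples: np.ndarray):
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ValueError("PiDistribution needs at least one sample")
        if samples.min() < -1e-9 or samples.max() > 1 + 1e-9:
            raise ValueError("pi samples must lie in [0, 1]")
        self.samples = np.clip(samples, 0.0, 1.0)

    # -- constructors -----------------------------------------------------
    @classmethod
    def delta_one(cls) -> "PiDistribution":
        """Point mass at pi = 1 (last clonal / subclonal events)."""
        return cls(np.ones(2))

    @classmethod
    def uniform(cls, n: int = N_QUANTILE_SAMPLES) -> "PiDistribution":
        """Uniform distribution on [0, 1] (untimeable clonal events)."""
        return cls((np.arange(n) + 0.5) / n)

    @classmethod
    def from_probs(cls, probs: np.ndarray,
                   n: int = N_QUANTILE_SAMPLES) -> "PiDistribution":
        """Reconstitute quantile samples from a histogram (I/O round trip)."""
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        edges = np.linspace(0.0, 1.0, probs.size + 1)
        cdf = np.concatenate([[0.0], np.cumsum(probs)])
        q = (np.arange(n) + 0.5) / n
        return cls(np.interp(q, cdf, edges))

    # -- summaries --------------------------------------------------------
    @property
    def probs(self) -> np.ndarray:
        hist, _ = np.histogram(self.samples, bins=N_PI_BINS, range=(0.0, 1.0))
        return hist / hist.sum()

    def mean(self) -> float:
        return float(self.samples.mean())

    def median(self) -> float:
        return float(np.median(self.samples))

    def credible_interval(self, mass: float = 0.75) -> tuple[float, float]:
        lo = (1.0 - mass) / 2.0
        return (float(np.quantile(self.samples, lo)),
                float(np.quantile(self.samples, 1.0 - lo)))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.samples, size=size, replace=True)

    @property
    def is_delta_one(self) -> bool:
        return bool(np.all(self.samples == 1.0))


# ---------------------------------------------------------------------------
# Gain timing
# ---------------------------------------------------------------------------

def phi_of_t(t, d: float, u: float, c: float):
    """Expected high-multiplicity fraction at gain time t."""
    t = np.asarray(t, dtype=float)
    return d * t / ((d + u) * t + c * (1.0 - t))


def t_of_phi(phi, d: float, u: float, c: float):
    """Inverse of :func:`phi_of_t`; values mapping above t=1 are clipped."""
    phi = np.asarray(phi, dtype=float)
    denom = d - phi * (d + u - c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = phi * c / denom
    return np.clip(t, 0.0, 1.0)


def gain_profile_from_cn(major_cn: int, minor_cn: int):
    """(d, u, C) of the implied single duplication for a copy state.

    Returns None for states without a duplicated allele (major < 2).
    Covers the states produced by single-gain histories: (2,1) one allele
    duplicated, (2,2) whole-genome doubling, (2,0) copy-neutral LOH; higher
    states are approximated as a single d-copy duplication.
    """
    maj, mnr = int(major_cn), int(minor_cn)
    if maj < 2:
        return None
    if maj == mnr:               # balanced doubling of both alleles
        return (maj, 0, maj + mnr)
    if mnr <= 1:
        return (maj - 1, mnr, maj + mnr)
    return (maj - mnr, mnr, maj + mnr)


def time_segment_gain(n_hi: float, n_1: float, d: int, u: int, c: int,
                      n_points: int = N_QUANTILE_SAMPLES) -> PiDistribution:
    """Posterior over the molecular time of one segmental duplication.

    ``n_hi`` and ``n_1`` are (possibly power-weighted, hence fractional)
    counts of high-multiplicity and multiplicity-1 clonal mutations on the
    segment.  The posterior is Beta(n_hi+1, n_1+1) on phi, truncated to the
    attainable range [0, d/(d+u)] (phi cannot exceed its value at t = 1),
    transformed to t; it is represented by a deterministic mid-quantile
    sample grid.  With no informative mutations the posterior is uniform
    on t (unpowered).
    """
    if d < 1:
        raise DomainError(f"d must be >= 1, got {d}")
    if c <= d + u:
        raise DomainError(f"C must exceed d + u, got C={c}, d={d}, u={u}")
    if n_hi < 0 or n_1 < 0:
        raise DomainError("counts must be non-negative")
    if n_hi == 0 and n_1 == 0:
        return PiDistribution.uniform(n_points)
    q = (np.arange(n_points) + 0.5) / n_points
    a, b = n_hi + 1.0, n_1 + 1.0
    phi_max = d / (d + u)
    cdf_max = stats.beta.cdf(phi_max, a, b)
    phi = stats.beta.ppf(q * cdf_max, a, b)
    return PiDistribution(t_of_phi(phi, d, u, c))


@dataclass
class ArmGainCounts:
    """Weighted mutation counts on one duplicated arm."""

    arm: str
    n_hi: float
    n_1: float
    d: int
    u: int
    c: int


def time_wgd(arm_counts: list[ArmGainCounts],
             qc_spread_threshold: float = 0.5,
             ) -> tuple[PiDistribution, bool]:
    """Aggregate per-arm gain timings into one whole-genome-event posterior.

    Counts are pooled across the co-timed arms sharing the modal (d, u, C)
    duplication profile; pooling shrinks the posterior exactly as a Beta
    with summed counts.  Returns the posterior and a QC flag raised when
    individual arm posteriors disagree (spread of per-arm posterior means
    above ``qc_spread_threshold``), e.g. one all-pre and one all-post arm.
    """
    if not arm_counts:
        raise DomainError("no doubled arms: whole-genome event not timeable")
    groups: dict[tuple, list[ArmGainCounts]] = {}
    for a in arm_counts:
        groups.setdefault((a.d, a.u, a.c), []).append(a)
    profile, members = max(groups.items(),
                           key=lambda kv: sum(a.n_hi + a.n_1 for a in kv[1]))
    n_hi = sum(a.n_hi for a in members)
    n_1 = sum(a.n_1 for a in members)
    pooled = time_segment_gain(n_hi, n_1, *profile)

    means = [time_segment_gain(a.n_hi, a.n_1, a.d, a.u, a.c).mean()
             for a in arm_counts if a.n_hi + a.n_1 > 0]
    qc_flag = bool(means and (max(means) - min(means) > qc_spread_threshold))
    return pooled, qc_flag


# ---------------------------------------------------------------------------
# Constrained events
# ---------------------------------------------------------------------------

def time_snv_driver(clonal: bool, map_multiplicity: int,
                    gain_samples: np.ndarray | None,
                    rng: np.random.Generator,
                    n_samples: int = N_JOINT_SAMPLES) -> PiDistribution:
    """Pi posterior of a driver SNV given its segment's gain timing.

    A subclonal driver is a point mass at 1.  On a gained segment a
    multiplicity>1 driver predates the gain (pi uniform on [0, t_gain],
    sampled jointly with the gain), a multiplicity-1 driver postdates it.
    Without an informative copy context the distribution is uniform.
    When ``gain_samples`` is given it must already be a joint sample array;
    the returned samples are elementwise constrained against it.
    """
    if not clonal:
        return PiDistribution.delta_one()
    if gain_samples is None:
        return PiDistribution(rng.random(n_samples))
    g = np.asarray(gain_samples, dtype=float)
    un = rng.random(g.size)
    if map_multiplicity > 1:
        return PiDistribution(un * g)
    return PiDistribution(g + un * (1.0 - g))


# ---------------------------------------------------------------------------
# Whole-tumor assembly
# ---------------------------------------------------------------------------

@dataclass
class TimedEvent:
    """One timed somatic event in one tumor."""

    name: str
    event_class: str  # driver_snv | arm_gain | arm_loss | homozygous_deletion
    #                 # | wgd | wgt | hpv_integration
    pi: PiDistribution
    qc_flag: bool = False

    def to_dict(self) -> dict:
        lo, hi = self.pi.credible_interval(0.75)
        return {
            "name": self.name,
            "class": self.event_class,
            "mean": round(self.pi.mean(), 6),
            "ci75": [round(lo, 6), round(hi, 6)],
            "qc_flag": self.qc_flag,
            "probs": [round(p, 6) for p in self.pi.probs],
        }


@dataclass
class PatientTiming:
    """Ordered per-tumor event list with pi posteriors."""

    tumor_id: str
    events: list[TimedEvent] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, name: str) -> TimedEvent:
        for e in self.events:
            if e.name == name:
                return e
        raise KeyError(name)

    def names(self) -> list[str]:
        return [e.name for e in self.events]

    def ordered(self) -> list[TimedEvent]:
        return sorted(self.events, key=lambda e: e.pi.mean())

    def to_dict(self) -> dict:
        return {"tumor_id": self.tumor_id,
                "events": [e.to_dict() for e in self.ordered()],
                "diagnostics": self.diagnostics}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "PatientTiming":
        events = [TimedEvent(e["name"], e["class"],
                             PiDistribution.from_probs(np.asarray(e["probs"])),
                             e.get("qc_flag", False))
                  for e in d["events"]]
        return cls(d["tumor_id"], events, d.get("diagnostics", []))


def _arm_states(segments: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Modal (major, minor) state per arm, length-weighted."""
    states = {}
    for arm, sub in segments.groupby("chrom_arm"):
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        keys = list(zip(sub["major_cn"].astype(int),
                        sub["minor_cn"].astype(int)))
        weight: dict[tuple[int, int], float] = {}
        for k, w in zip(keys, lengths):
            weight[k] = weight.get(k, 0.0) + w
        total = lengths.sum()
        best, w = max(weight.items(), key=lambda kv: kv[1])
        # The modal state must cover at least half the arm to call an event.
        states[arm] = best if w >= 0.5 * total else (1, 1)
    return states


def _weighted_counts(muts: pd.DataFrame) -> tuple[float, float]:
    """Power-weighted (n_hi, n_1) from annotated clonal mutations."""
    w = 1.0 / np.maximum(muts["p_detect"].to_numpy(dtype=float),
                         MIN_DETECTION_POWER)
    hi = muts["map_multiplicity"].to_numpy() >= 2
    return float(w[hi].sum()), float(w[~hi].sum())


def assemble_patient_timing(annotated: pd.DataFrame, segments: pd.DataFrame,
                            tumor_id: str = "tumor",
                            seed: int = 0,
                            n_samples: int = N_JOINT_SAMPLES,
                            ) -> PatientTiming:
    """Time all events of one tumor, respecting pairwise constraints.

    Joint posterior samples are aligned across events: every event's sample
    array has length ``n_samples`` and index j of each array belongs to one
    joint draw, so constraints (a pre-gain SNV precedes its gain in every
    joint sample) hold sample-by-sample.

    ``annotated`` must carry the columns produced by
    :func:`tumortime.ccf.annotate_mutations`; driver SNVs are marked by a
    non-empty ``driver`` column.
    """
    rng = np.random.default_rng(seed)
    result = PatientTiming(tumor_id)

    clonal = annotated[(annotated["clonal"]) & (annotated["powered"])]
    if clonal.empty:
        result.diagnostics.append("no clonal powered mutations; no events timed")
        return result

    states = _arm_states(segments)
    wge = het.call_whole_genome_event(segments)
    target = {"WGD": (2, 2), "WGT": (2, 1)}.get(wge.label)

    def joint(dist: PiDistribution) -> np.ndarray:
        return dist.sample(rng, n_samples)

    gain_joint: dict[str, np.ndarray] = {}   # per-arm gain joint samples
    wgd_pool: list[ArmGainCounts] = []

    for arm, (maj, mnr) in sorted(states.items()):
        if (maj, mnr) == (1, 1):
            continue
        arm_muts = clonal[clonal["chrom_arm"] == arm]
        if maj >= 2:
            profile = gain_profile_from_cn(maj, mnr)
            n_hi, n_1 = _weighted_counts(arm_muts)
            if target is not None and (maj, mnr) == target:
                # Arm belongs to the genome-wide event; pooled below.
                wgd_pool.append(ArmGainCounts(arm, n_hi, n_1, *profile))
                continue
            pi = time_segment_gain(n_hi, n_1, *profile)
            js = joint(pi)
            gain_joint[arm] = js
            if mnr == 0:
                # Copy-neutral LOH: the loss is timed by its duplication,
                # a tight upper bound on the loss time.
                result.events.append(
                    TimedEvent(f"-{arm}", "arm_loss", PiDistribution(js)))
            else:
                result.events.append(
                    TimedEvent(f"+{arm}", "arm_gain", PiDistribution(js)))
        elif maj == 1 and mnr == 0:
            result.events.append(
                TimedEvent(f"-{arm}", "arm_loss",
                           PiDistribution(rng.random(n_samples))))
        elif maj == 0:
            result.events.append(
                TimedEvent(f"-/-{arm}", "homozygous_deletion",
                           PiDistribution(rng.random(n_samples))))

    if wgd_pool:
        pooled, qc = time_wgd(wgd_pool)
        js = joint(pooled)
        for a in wgd_pool:
            gain_joint[a.arm] = js
        result.events.append(
            TimedEvent(wge.label, "wgd" if wge.label == "WGD" else "wgt",
                       PiDistribution(js), qc_flag=qc))
    elif wge.qc_flag:
        result.diagnostics.append("whole-genome event criteria met in a "
                                  "diploid-class tumor; no WGD/WGT emitted")

    if "driver" in annotated.columns:
        drivers = annotated[annotated["driver"].astype(str).str.len() > 0]
        drivers = drivers[drivers["driver"].astype(str) != "nan"]
        for _, row in drivers.iterrows():
            arm = row["chrom_arm"]
            g = gain_joint.get(arm)
            pi = time_snv_driver(bool(row["clonal"]),
                                 int(row["map_multiplicity"]), g, rng,
                                 n_samples)
            result.events.append(
                TimedEvent(str(row["driver"]), "driver_snv", pi))

    if not result.events:
        result.diagnostics.append("no timeable events")
    return result


# ---------------------------------------------------------------------------
# HPV integration
# ---------------------------------------------------------------------------

def time_hpv_integration(alt_count: int, ref_count: int, purity: float,
                         major_cn: int, minor_cn: int,
                         local_mutations: pd.DataFrame,
                         seed: int = 0,
                         n_samples: int = N_JOINT_SAMPLES) -> PiDistribution:
    """Time one HPV integration breakpoint like a mutation-borne event.

    The breakpoint read support is annotated exactly as an SNV; the local
    copy gain is timed from the surrounding clonal mutations with
    APOBEC-context mutations excluded (they cluster at integration sites
    and would distort the local clock).
    """
    from .ccf import annotate_mutation
    from .realtime import classify_context

    rng = np.random.default_rng(seed)
    ann = annotate_mutation(alt_count, ref_count, purity, major_cn, minor_cn)
    profile = gain_profile_from_cn(major_cn, minor_cn)
    gain_samples = None
    if profile is not None:
        muts = local_mutations[(local_mutations["clonal"])
                               & (local_mutations["powered"])]
        ctx = [classify_context(r, a, c) for r, a, c in
               zip(muts["ref"], muts["alt"], muts["context"])]
        muts = muts[[c != "APOBEC" for c in ctx]]
        n_hi, n_1 = _weighted_counts(muts)
        gain_samples = time_segment_gain(n_hi, n_1, *profile).sample(
            rng, n_samples)
    return time_snv_driver(ann.clonal, ann.map_multiplicity, gain_samples,
                           rng, n_samples)


def representative_integration(sites: list[tuple[str, float]]) -> str:
    """Pick the representative site per participant: earliest real-time
    estimate (smallest pi mean maps to the largest years before diagnosis,
    so callers pass (site_name, years_before_diagnosis) pairs)."""
    if not sites:
        raise DomainError("no covered integration sites")
    return max(sites, key=lambda s: s[1])[0]
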
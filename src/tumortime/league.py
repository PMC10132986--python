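"""Cohort-level consensus ordering of somatic events (league model).

Per-tumor pi posteriors of shared events are combined by repeated
resampling: in each of 200 iterations a random ~63% of tumors is included
(binomial inclusion without replacement), one pi value is drawn per event
per included carrier, per-event scores are averaged over carriers and
rescaled so the earliest event of the iteration sits at 0 and the latest at
1.  The union of per-iteration scores forms each event's relative-timing
trace; its median is the mRT point estimate.  Cohort comparisons difference
the per-iteration scores of two cohorts, yielding one-way p values (the
fraction of the difference trace above zero), two-way p values
P_2way = 1 - 2|0.5 - P_1way| and Benjamini-Hochberg q values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DomainError
from .timing import PatientTiming, PiDistribution

N_ITERATIONS = 200
RESAMPLE_FRACTION = 0.63

#: Cohort container: tumor id -> {event name -> PiDistribution}.
Cohort = dict[str, dict[str, PiDistribution]]


def cohort_from_patient_timings(timings: list[PatientTiming],
                                merge_wge: bool = False) -> Cohort:
    """Index per-tumor timings by tumor and event name.

    With ``merge_wge`` the WGT label is folded into WGD: both mark the same
    originating whole-genome amplification, and a caller ordering event
    origins may want them pooled.
    """
    cohort: Cohort = {}
    for t in timings:
        events = {}
        for e in t.events:
            name = e.name
            if merge_wge and name == "WGT":
                name = "WGD"
            events[name] = e.pi
        cohort[t.tumor_id] = events
    return cohort


@dataclass
class CohortTimingResult:
    """Relative-timing traces, mRT point estimates and prevalence."""

    traces: dict[str, np.ndarray]
    prevalence: dict[str, float]
    n_tumors: int
    n_iterations: int

    @property
    def mrt(self) -> dict[str, float]:
        return {e: float(np.median(t)) for e, t in self.traces.items()
                if t.size > 0}

    def order(self) -> list[str]:
        """Events sorted from earliest to latest mRT."""
        m = self.mrt
        return sorted(m, key=m.get)

    def p_before(self, a: str, b: str) -> float:
        """Probability that event ``a`` precedes ``b``, from paired
        per-iteration scores."""
        sa, sb = self._paired[a], self._paired[b]
        ok = ~np.isnan(sa) & ~np.isnan(sb)
        if ok.sum() == 0:
            return float("nan")
        return float(np.mean(sa[ok] < sb[ok]))

    _paired: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.order():
            t = self.traces[e]
            rows.append({"event": e, "mRT": float(np.median(t)),
                         "ci75_lo": float(np.quantile(t, 0.125)),
                         "ci75_hi": float(np.quantile(t, 0.875)),
                         "prevalence": self.prevalence[e]})
        return pd.DataFrame(rows)


def _iteration_scores(cohort: Cohort, events: list[str], n_iterations: int,
                      resample_fraction: float, seed_key: list[int],
                      ) -> np.ndarray:
    """Matrix of rescaled per-iteration scores, shape (n_iterations,
    n_events); NaN where an event was absent from the subsample or the
    iteration was discarded (fewer than 2 events present).

    Randomness is streamed per entity (one stream for tumor inclusion, one
    per event name), so results are invariant to event and tumor input
    order at a fixed seed.
    """
    tumors = sorted(cohort)
    n_t = len(tumors)
    carriers = {e: [i for i, t in enumerate(tumors) if e in cohort[t]]
                for e in events}

    def event_rng(e):
        return np.random.default_rng(
            np.random.SeedSequence(seed_key + [zlib.crc32(e.encode())]))

    # Pre-draw one pi per (event, carrier, iteration).
    draws = {}
    for e in events:
        rng_e = event_rng(e)
        draws[e] = np.stack(
            [cohort[tumors[i]][e].sample(rng_e, n_iterations)
             for i in carriers[e]], axis=1) \
            if carriers[e] else np.zeros((n_iterations, 0))
    inc_rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    include = inc_rng.random((n_iterations, n_t)) < resample_fraction

    scores = np.full((n_iterations, len(events)), np.nan)
    for j, e in enumerate(events):
        idx = np.asarray(carriers[e], dtype=int)
        if idx.size == 0:
            continue
        mask = include[:, idx]
        cnt = mask.sum(axis=1)
        with np.errstate(invalid="ignore"):
            s = np.where(cnt > 0,
                         (draws[e] * mask).sum(axis=1) / np.maximum(cnt, 1),
                         np.nan)
        scores[:, j] = s
    # Rescale within each iteration: earliest present event -> 0, last -> 1.
    lo = np.nanmin(scores, axis=1, keepdims=True)
    hi = np.nanmax(scores, axis=1, keepdims=True)
    n_present = (~np.isnan(scores)).sum(axis=1)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        rescaled = (scores - lo) / np.where(span > 0, span, np.nan)
    rescaled[n_present < 2, :] = np.nan
    return rescaled


def league_aggregate(cohort: Cohort, events: list[str] | None = None,
                     n_iterations: int = N_ITERATIONS,
                     resample_fraction: float = RESAMPLE_FRACTION,
                     seed: int = 0) -> CohortTimingResult:
    """Consensus relative ordering of shared events across a cohort."""
    if not cohort:
        raise DomainError("empty cohort")
    if events is None:
        events = sorted({e for t in cohort.values() for e in t})
    missing = [e for e in events if not any(e in t for t in cohort.values())]
    if missing:
        raise DomainError(f"events absent from every tumor: {missing}")
    scores = _iteration_scores(cohort, events, n_iterations,
                               resample_fraction, [seed, 0])
    n_t = len(cohort)
    traces = {e: scores[~np.isnan(scores[:, j]), j]
              for j, e in enumerate(events)}
    prevalence = {e: sum(e in t for t in cohort.values()) / n_t
                  for e in events}
    paired = {e: scores[:, j] for j, e in enumerate(events)}
    return CohortTimingResult(traces, prevalence, n_t, n_iterations,
                              _paired=paired)


@dataclass
class TimingComparison:
    """Per-event timing differences between two cohorts."""

    events: list[str]
    delta_median: dict[str, float]
    p_one_way: dict[str, float]
    p_two_way: dict[str, float]
    q_value: dict[str, float]
    delta_traces: dict[str, np.ndarray]
    diagnostics: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"event": e, "delta_mrt": self.delta_median[e],
              "p_one_way": self.p_one_way[e], "p_two_way": self.p_two_way[e],
              "q": self.q_value[e]} for e in self.events])


def two_way_p(p_one_way: float) -> float:
    """P_2way = 1 - 2|0.5 - P_1way|."""
    return 1.0 - 2.0 * abs(0.5 - p_one_way)


def compare_cohorts(cohort_a: Cohort, cohort_b: Cohort,
                    events: list[str] | None = None,
                    min_cases_per_cohort: int = 3,
                    n_iterations: int = N_ITERATIONS,
                    resample_fraction: float = RESAMPLE_FRACTION,
                    seed: int = 0) -> TimingComparison:
    """Difference of relative timing between two cohorts, per shared event.

    Events carried by fewer than ``min_cases_per_cohort`` tumors in either
    cohort are excluded.  One-way p is the fraction of the per-iteration
    difference trace (cohort A minus cohort B) above zero.
    """
    def carriers(cohort, e):
        return sum(e in t for t in cohort.values())

    if events is None:
        shared = ({e for t in cohort_a.values() for e in t}
                  & {e for t in cohort_b.values() for e in t})
        events = sorted(shared)
    events = [e for e in events
              if carriers(cohort_a, e) >= min_cases_per_cohort
              and carriers(cohort_b, e) >= min_cases_per_cohort]
    if not events:
        return TimingComparison([], {}, {}, {}, {}, {},
                                ["no shared events above the prevalence "
                                 "floor"])
    sa = _iteration_scores(cohort_a, events, n_iterations, resample_fraction,
                           [seed, 101])
    sb = _iteration_scores(cohort_b, events, n_iterations, resample_fraction,
                           [seed, 102])
    delta = sa - sb
    delta_median, p1, p2 = {}, {}, {}
    for j, e in enumerate(events):
        tr = delta[~np.isnan(delta[:, j]), j]
        delta_median[e] = float(np.median(tr)) if tr.size else float("nan")
        # Ties (exact zeros, e.g. for events anchoring the rescaling in
        # both cohorts) count half, as in a mid-p value.
        p1[e] = float(np.mean(tr > 0) + 0.5 * np.mean(tr == 0)) \
            if tr.size else float("nan")
        p2[e] = two_way_p(p1[e])
    q = bh_fdr([p2[e] for e in events])
    traces = {e: delta[~np.isnan(delta[:, j]), j]
              for j, e in enumerate(events)}
    return TimingComparison(events, delta_median, p1, p2,
                            dict(zip(events, q)), traces)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
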
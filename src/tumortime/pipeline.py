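"""End-to-end orchestration and cohort prevalence statistics.

``run_pipeline`` chains simulate -> annotate -> per-tumor timing -> league
-> real-time -> heterogeneity (-> cohort comparison when two cohorts are
defined), writing every stage's outputs plus a manifest (seed, parameters,
per-stage wall times) that suffices to reproduce the run bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sp_stats

from . import __version__
from .ccf import annotate_mutations
from .errors import ConfigError, DomainError
from .heterogeneity import heterogeneity_profile
from .io import (read_metadata, read_mutations, read_segments, write_table,
                 write_timing_json)
from .league import (cohort_from_patient_timings, compare_cohorts,
                     league_aggregate, bh_fdr)
from .realtime import (count_clock_mutations, fit_aging_rate,
                       fit_wgd_wgt_conversion, pi_to_years)
from .synthetic import SimConfig, simulate_cohort
from .timing import assemble_patient_timing


def percent(k: int, n: int, decimals: int = 1) -> float:
    """Percentage k/n rounded (round-half-even) to ``decimals`` places.

    One decimal is the reporting precision for prevalence tables; prose
    summaries round the same value to the nearest integer
    (``decimals=0``)."""
    return round(100.0 * k / n, decimals) if decimals else \
        int(round(100.0 * k / n))


def cohort_stats(event_matrix: pd.DataFrame,
                 groups: pd.Series) -> pd.DataFrame:
    """Prevalence table with pairwise Fisher exact p and BH q values.

    ``event_matrix`` is a binary tumors x events table; ``groups`` maps
    each tumor (index-aligned) to one of exactly two group labels.
    """
    labels = sorted(pd.unique(groups.dropna()))
    if len(labels) != 2:
        raise DomainError(f"cohort_stats needs exactly 2 groups, "
                          f"got {labels}")
    ga, gb = labels
    idx_a = groups[groups == ga].index
    idx_b = groups[groups == gb].index
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise DomainError("empty group")
    rows = []
    for event in event_matrix.columns:
        ka = int(event_matrix.loc[idx_a, event].sum())
        kb = int(event_matrix.loc[idx_b, event].sum())
        na, nb = len(idx_a), len(idx_b)
        table = [[ka, na - ka], [kb, nb - kb]]
        p = float(sp_stats.fisher_exact(table, alternative="two-sided")[1])
        rows.append({"event": event,
                     f"count_{ga}": ka, f"n_{ga}": na,
                     f"pct_{ga}": percent(ka, na),
                     f"pct_int_{ga}": percent(ka, na, decimals=0),
                     f"count_{gb}": kb, f"n_{gb}": nb,
                     f"pct_{gb}": percent(kb, nb),
                     f"pct_int_{gb}": percent(kb, nb, decimals=0),
                     "p_fisher": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p_fisher"].to_numpy())
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    n_tumors: int = 30
    simulate: bool = True
    mutations_path: str | None = None
    segments_path: str | None = None
    metadata_path: str | None = None
    cohort_column: str | None = None        # metadata column defining two
    #                                       # cohorts to compare (optional)
    league_iterations: int = 200
    resample_fraction: float = 0.63
    min_cases_per_cohort: int = 3
    sim: dict = field(default_factory=dict)  # extra SimConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            for name in ("mutations_path", "segments_path", "metadata_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"{name} missing or does not exist")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "tumortime", "version": __version__,
                      "seed": config.seed, "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **extra}
        return done

    # -- inputs -----------------------------------------------------------
    done = stage("inputs")
    if config.simulate:
        sim = SimConfig(n_tumors=config.n_tumors, seed=config.seed,
                        **config.sim)
        bundle = simulate_cohort(sim)
        bundle.write(outdir / "cohort")
        mutations, segments, metadata = (bundle.mutations, bundle.segments,
                                         bundle.metadata)
        done(simulated=True, n_tumors=config.n_tumors)
    else:
        mutations = read_mutations(config.mutations_path)
        segments = read_segments(config.segments_path)
        metadata = read_metadata(config.metadata_path)
        done(simulated=False, n_tumors=int(metadata.shape[0]))

    meta_by_id = metadata.set_index("tumor_id")

    # -- annotate ---------------------------------------------------------
    done = stage("annotate")
    annotated = {}
    for tumor_id, muts in mutations.groupby("tumor_id"):
        purity = float(meta_by_id.loc[tumor_id, "purity"])
        segs = segments[segments["tumor_id"] == tumor_id]
        annotated[tumor_id] = annotate_mutations(muts, segs, purity)
    write_table(pd.concat(annotated.values(), ignore_index=True)
                .drop(columns=["multiplicity_posterior"], errors="ignore"),
                outdir / "annotated_mutations.tsv")
    done()

    # -- per-tumor timing -------------------------------------------------
    done = stage("timing")
    seed_seq = np.random.SeedSequence([config.seed, 7])
    tumor_ids = sorted(annotated)
    timings = []
    for tumor_id, child in zip(tumor_ids, seed_seq.spawn(len(tumor_ids))):
        segs = segments[segments["tumor_id"] == tumor_id]
        timings.append(assemble_patient_timing(
            annotated[tumor_id], segs, tumor_id,
            seed=int(child.generate_state(1)[0] % (2 ** 31))))
    write_timing_json(timings, outdir / "patient_timing.json")
    done()

    # -- league -----------------------------------------------------------
    done = stage("league")
    cohort = cohort_from_patient_timings(timings)
    result = league_aggregate(cohort,
                              n_iterations=config.league_iterations,
                              resample_fraction=config.resample_fraction,
                              seed=config.seed)
    write_table(result.to_frame(), outdir / "league_mrt.tsv")
    done()

    # -- real time --------------------------------------------------------
    done = stage("realtime")
    burdens, ages = {}, {}
    for tumor_id in tumor_ids:
        burdens[tumor_id] = count_clock_mutations(
            annotated[tumor_id], covered_cpg_mb=30.0)
        ages[tumor_id] = float(meta_by_id.loc[tumor_id, "age"])
    fit = fit_aging_rate(np.array([burdens[t] for t in tumor_ids]),
                         np.array([ages[t] for t in tumor_ids]))
    rt_rows, wge_times, wge_classes = [], [], []
    for t in timings:
        tid = t.tumor_id
        if burdens[tid] <= 0 or fit.rate <= 0:
            continue
        for e in t.events:
            est = pi_to_years(e.pi, burdens[tid], fit.rate, ages[tid])
            lo, hi = est.credible_interval(0.75)
            rt_rows.append({"tumor_id": tid, "event": e.name,
                            "years_mean": round(est.mean(), 3),
                            "years_ci75_lo": round(lo, 3),
                            "years_ci75_hi": round(hi, 3)})
            if e.event_class in ("wgd", "wgt"):
                wge_times.append(est.mean())
                wge_classes.append(e.name)
    write_table(pd.DataFrame(rt_rows), outdir / "real_time.tsv")
    realtime_summary = {"clock_rate": fit.rate,
                        "clock_rate_iqr": list(fit.iqr)}
    if len(wge_times) >= 10:
        conv = fit_wgd_wgt_conversion(wge_times, wge_classes)
        realtime_summary["conversion"] = {
            "rate": conv.rate, "immune_fraction": conv.immune_fraction,
            "rate_ci": list(conv.rate_ci),
            "immune_ci": list(conv.immune_ci)}
    (outdir / "realtime_model.json").write_text(
        json.dumps(realtime_summary, indent=1))
    done(clock_rate=round(fit.rate, 4))

    # -- heterogeneity ----------------------------------------------------
    done = stage("heterogeneity")
    het_rows = []
    for tumor_id in tumor_ids:
        segs = segments[segments["tumor_id"] == tumor_id]
        prof = heterogeneity_profile(annotated[tumor_id], segs, tumor_id)
        het_rows.append({
            "tumor_id": tumor_id, "MATH": round(prof.math, 3),
            "FGA": round(prof.fga, 4),
            "aneuploidy_class": prof.aneuploidy_class,
            "wge_call": prof.wge_call,
            "math_pre_wgd": prof.math_pre_wgd,
            "math_post_wgd": prof.math_post_wgd})
    write_table(pd.DataFrame(het_rows), outdir / "heterogeneity.tsv")
    done()

    # -- cohort comparison ------------------------------------------------
    if config.cohort_column:
        done = stage("compare")
        col = meta_by_id[config.cohort_column]
        labels = sorted(col.unique())
        if len(labels) == 2:
            split = {lab: {t.tumor_id: cohort[t.tumor_id] for t in timings
                           if col[t.tumor_id] == lab} for lab in labels}
            comp = compare_cohorts(split[labels[0]], split[labels[1]],
                                   min_cases_per_cohort=
                                   config.min_cases_per_cohort,
                                   n_iterations=config.league_iterations,
                                   resample_fraction=
                                   config.resample_fraction,
                                   seed=config.seed)
            write_table(comp.to_frame(), outdir / "cohort_comparison.tsv")
        done(groups=list(map(str, labels)))

    manifest["parameters"] = {
        "n_tumors": config.n_tumors,
        "league_iterations": config.league_iterations,
        "resample_fraction": config.resample_fraction}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
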
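"""Synthetic tumor cohorts with fully known ground truth.

The generator emulates clonal evolution on the 39-arm genome abstraction:
somatic mutations accrue on lineage copies, so a mutation that predates a
duplication of its allele of origin ends at multiplicity equal to that
allele's post-gain copy number, while later mutations stay at multiplicity
one.  Clonal CpG>T mutations accrue linearly with age at the configured
clock rate; arm-level gains, losses (optionally as copy-neutral LOH, a
loss closely followed by duplication of the remaining allele) and a
whole-genome doubling occur at configured prevalences inside configured
molecular-time windows.  A whole-genome doubling may later erode to a
predominantly triploid profile (WGT) via a Poisson conversion process with
an immune (never-converting) fraction.  Read counts are binomial around
the purity-diluted expected VAF.  Every tumor's true event order, true
molecular times and true calendar times are recorded in a truth ledger.

Molecular time t in [0, 1] maps to calendar time as
years_before_diagnosis = (1 - t) * age, consistent with the zero-intercept
CpG>T clock.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ccf import expected_vaf
from .errors import ConfigError
from .genome import ARMS, ARM_LENGTHS_MB, GENOME_MB, arm_length_bp
from .timing import PiDistribution, phi_of_t, time_segment_gain

SITES = ("oral_cavity", "larynx", "oropharynx")

# Trinucleotide context templates per mutation class (ref is the middle
# base): the analysis-side classifier maps these back to the class labels.
_CONTEXTS = {
    "CpG>T": ("ACG", "C", "T"),
    "APOBEC": ("TCA", "C", "G"),
    "other": ("ACA", "C", "A"),
}


@dataclass(frozen=True)
class EventSpec:
    """One menu event: name, prevalence, and true molecular-time window.

    Names follow the field convention: "+3q" arm gain, "-9p" arm loss,
    "WGD" whole-genome doubling; any other name is a driver SNV and needs
    an explicit ``arm``.
    """

    name: str
    prevalence: float
    window: tuple[float, float]
    arm: str | None = None

    @property
    def kind(self) -> str:
        if self.name == "WGD":
            return "wgd"
        if self.name.startswith("+"):
            return "arm_gain"
        if self.name.startswith("-"):
            return "arm_loss"
        return "driver_snv"

    @property
    def target_arm(self) -> str | None:
        if self.kind in ("arm_gain", "arm_loss"):
            return self.name[1:]
        return self.arm


def default_event_menu() -> list[EventSpec]:
    """Ten staggered events mirroring a classic HPV-negative progression:
    early arm losses, intermediate gains, late whole-genome doubling."""
    return [
        EventSpec("-9p", 0.85, (0.00, 0.10)),
        EventSpec("-3p", 0.80, (0.06, 0.18)),
        EventSpec("-17p", 0.55, (0.12, 0.26)),
        EventSpec("-8p", 0.60, (0.20, 0.34)),
        EventSpec("-13q", 0.45, (0.28, 0.42)),
        EventSpec("+3q", 0.55, (0.42, 0.58)),
        EventSpec("+8q", 0.50, (0.50, 0.66)),
        EventSpec("-14q", 0.40, (0.60, 0.74)),
        EventSpec("-4q", 0.40, (0.68, 0.82)),
        EventSpec("WGD", 0.45, (0.72, 0.92)),
    ]


@dataclass
class WgdParams:
    """Whole-genome-doubling conversion process.

    ``origination_years`` is the window of event ages (years before
    diagnosis) used by the standalone conversion-event simulator;
    ``conversion_rate`` is the annual WGD-to-WGT conversion probability
    rate and ``immune_fraction`` the fraction of doubled tumors that never
    convert.
    """

    origination_years: tuple[float, float] = (0.0, 40.0)
    conversion_rate: float = 0.11
    immune_fraction: float = 0.35


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort."""

    n_tumors: int = 100
    seed: int = 0
    coverage_mean: float = 120.0
    purity_range: tuple[float, float] = (0.3, 0.9)
    clock_rate: float = 0.37            # CpG>T per Mb at risk per year
    age_range: tuple[float, float] = (40.0, 80.0)
    covered_cpg_mb: float = 30.0
    background_snv_per_mb: float = 0.2  # lifetime clonal non-clock SNVs
    apobec_fraction: float = 0.25
    event_menu: list[EventSpec] = field(default_factory=default_event_menu)
    wgd_params: WgdParams = field(default_factory=WgdParams)
    loh_duplication_prob: float = 0.8   # losses presenting as cn-LOH (2:0)
    loh_duplication_lag: float = 0.05   # molecular-time lag of that dup
    subclone_ccf: float | None = 0.35
    subclone_mut_fraction: float = 0.3
    hpv_positive_fraction: float = 0.0

    def validate(self) -> None:
        if self.n_tumors < 1:
            raise ConfigError("n_tumors must be >= 1")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be positive")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("purity_range must lie in (0, 1]")
        if self.clock_rate < 0:
            raise ConfigError("clock_rate must be non-negative")
        if self.covered_cpg_mb <= 0:
            raise ConfigError("covered_cpg_mb must be positive")
        for spec in self.event_menu:
            if not 0.0 <= spec.prevalence <= 1.0:
                raise ConfigError(
                    f"event_menu prevalence for {spec.name} not in [0,1]")
            a, b = spec.window
            if not 0.0 <= a <= b <= 1.0:
                raise ConfigError(
                    f"event_menu window for {spec.name} not in [0,1]")
            if spec.kind == "driver_snv" and spec.target_arm is None:
                raise ConfigError(
                    f"event_menu driver {spec.name} needs an arm")
        if self.wgd_params.conversion_rate < 0:
            raise ConfigError("wgd_params conversion_rate must be >= 0")
        if not 0.0 <= self.wgd_params.immune_fraction <= 1.0:
            raise ConfigError("wgd_params immune_fraction not in [0,1]")
        if self.subclone_ccf is not None and not 0 < self.subclone_ccf < 1:
            raise ConfigError("subclone_ccf must lie in (0,1)")


@dataclass
class TrueEvent:
    name: str
    kind: str
    arm: str | None
    t: float                    # true molecular time
    years_before: float
    cn_after: tuple[int, int] | None


@dataclass
class TrueHistory:
    """Ground truth for one simulated tumor."""

    tumor_id: str
    age: float
    purity: float
    hpv_status: str
    site: str
    wge_label: str              # none | WGD | WGT
    events: list[TrueEvent]

    def event_times(self) -> dict[str, float]:
        return {e.name: e.t for e in self.events}

    def to_dict(self) -> dict:
        d = asdict(self)
        for e in d["events"]:
            e["t"] = round(e["t"], 6)
            e["years_before"] = round(e["years_before"], 4)
        d["age"] = round(self.age, 4)
        d["purity"] = round(self.purity, 6)
        return d


# Per-arm mutational phases: (t_lo, t_hi, copies at risk, final mult).
_Phase = tuple[float, float, float, int]


def _arm_phases(state: tuple[int, int], history: str,
                t_event: float) -> list[_Phase]:
    if history == "neutral":
        return [(0.0, 1.0, 2.0, 1)]
    if history == "gain":          # 1:1 -> 2:1
        return [(0.0, t_event, 1.0, 2), (0.0, t_event, 1.0, 1),
                (t_event, 1.0, 3.0, 1)]
    if history == "cnloh":         # 1:1 -> 1:0 -> 2:0 at t_event (the dup)
        return [(0.0, t_event, 1.0, 2), (t_event, 1.0, 2.0, 1)]
    if history == "loss":          # 1:1 -> 1:0
        return [(0.0, t_event, 1.0, 1), (t_event, 1.0, 1.0, 1)]
    if history == "wgd":           # 1:1 -> 2:2
        return [(0.0, t_event, 2.0, 2), (t_event, 1.0, 4.0, 1)]
    if history == "wgt":           # 1:1 -> 2:2 -> 2:1 (erosion)
        return [(0.0, t_event, 1.0, 2), (0.0, t_event, 1.0, 1),
                (t_event, 1.0, 3.0, 1)]
    raise ValueError(history)


def _multiplicity_at(phases: list[_Phase], t: float,
                     rng: np.random.Generator) -> int:
    """Multiplicity of a mutation arising at time t on a random at-risk
    copy of an arm with the given phase structure."""
    hits = [(c, m) for lo, hi, c, m in phases if lo <= t < hi or
            (t == 1.0 and hi == 1.0)]
    if not hits:
        return 1
    weights = np.array([c for c, _ in hits], dtype=float)
    return hits[rng.choice(len(hits), p=weights / weights.sum())][1]


def simulate_tumor(config: SimConfig, rng: np.random.Generator,
                   tumor_id: str = "T0001",
                   ) -> tuple[TrueHistory, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one tumor: truth, mutation table, segment table, metadata."""
    config.validate()
    age = float(rng.uniform(*config.age_range))
    purity = float(rng.uniform(*config.purity_range))
    hpv = "positive" if rng.random() < config.hpv_positive_fraction \
        else "negative"
    site = str(rng.choice(SITES))

    # -- sample events -----------------------------------------------------
    chosen: list[tuple[EventSpec, float]] = []
    for spec in config.event_menu:
        if rng.random() < spec.prevalence:
            chosen.append((spec, float(rng.uniform(*spec.window))))

    wge_label = "none"
    t_wgd = None
    for spec, t in chosen:
        if spec.kind == "wgd":
            t_wgd = t
            tau = (1.0 - t) * age
            lam = config.wgd_params.conversion_rate
            immune = rng.random() < config.wgd_params.immune_fraction
            converted = (not immune and lam > 0
                         and rng.exponential(1.0 / lam) < tau)
            wge_label = "WGT" if converted else "WGD"

    # -- arm plans ---------------------------------------------------------
    plan: dict[str, tuple[str, float, tuple[int, int]]] = {}
    truth_events: list[TrueEvent] = []
    menu_arms = set()
    for spec, t in chosen:
        arm = spec.target_arm
        if spec.kind == "arm_gain":
            plan[arm] = ("gain", t, (2, 1))
            menu_arms.add(arm)
            truth_events.append(TrueEvent(spec.name, spec.kind, arm, t,
                                          (1 - t) * age, (2, 1)))
        elif spec.kind == "arm_loss":
            if rng.random() < config.loh_duplication_prob:
                t_dup = min(t + rng.uniform(0, config.loh_duplication_lag),
                            1.0)
                plan[arm] = ("cnloh", t_dup, (2, 0))
                cn = (2, 0)
            else:
                plan[arm] = ("loss", t, (1, 0))
                cn = (1, 0)
            menu_arms.add(arm)
            truth_events.append(TrueEvent(spec.name, spec.kind, arm, t,
                                          (1 - t) * age, cn))
    if t_wgd is not None:
        history = "wgt" if wge_label == "WGT" else "wgd"
        cn = (2, 1) if wge_label == "WGT" else (2, 2)
        for arm in ARMS:
            if arm not in menu_arms:
                plan[arm] = (history, t_wgd, cn)
        truth_events.append(TrueEvent("WGD", "wgd", None, t_wgd,
                                      (1 - t_wgd) * age, cn))
    truth_events.sort(key=lambda e: e.t)

    # -- mutations ---------------------------------------------------------
    rows: list[dict] = []

    def emit(arm, t, mult, ccf, ctx_class, state, driver=""):
        n_total = state[0] + state[1]
        trinuc, ref, alt = _CONTEXTS[ctx_class]
        vaf = expected_vaf(mult, ccf, purity, n_total) if n_total else 0.0
        depth = int(rng.poisson(config.coverage_mean))
        alt_count = int(rng.binomial(depth, vaf)) if depth > 0 else 0
        rows.append({
            "tumor_id": tumor_id, "chrom_arm": arm,
            "pos": int(rng.integers(0, arm_length_bp(arm))),
            "ref": ref, "alt": alt, "alt_count": alt_count,
            "ref_count": depth - alt_count, "context": trinuc,
            "driver": driver,
            "true_multiplicity": mult, "true_ccf": ccf,
            "true_t": round(float(t), 6),
        })

    clock_lifetime = config.clock_rate * age   # per CpG-Mb over lifetime
    for arm in ARMS:
        history, t_event, state = plan.get(arm, ("neutral", 0.0, (1, 1)))
        phases = _arm_phases(state, history, t_event)
        len_mb = ARM_LENGTHS_MB[arm]
        cpg_mb = config.covered_cpg_mb * len_mb / GENOME_MB
        for lo, hi, copies, mult in phases:
            dur = hi - lo
            if dur <= 0:
                continue
            for mean, ctx in ((clock_lifetime * cpg_mb * copies / 2 * dur,
                               "CpG>T"),
                              (config.background_snv_per_mb * len_mb
                               * copies / 2 * dur, None)):
                for _ in range(int(rng.poisson(mean))):
                    t = float(rng.uniform(lo, hi))
                    c = ctx or ("APOBEC" if rng.random()
                                < config.apobec_fraction else "other")
                    emit(arm, t, mult, 1.0, c, state)

    if config.subclone_ccf is not None:
        n_sub = int(rng.poisson(config.subclone_mut_fraction
                                * config.background_snv_per_mb * GENOME_MB))
        lengths = np.array([ARM_LENGTHS_MB[a] for a in ARMS])
        arms_idx = rng.choice(len(ARMS), size=n_sub,
                              p=lengths / lengths.sum())
        for i in arms_idx:
            arm = ARMS[i]
            _, _, state = plan.get(arm, ("neutral", 0.0, (1, 1)))
            ctx = "APOBEC" if rng.random() < config.apobec_fraction \
                else "other"
            emit(arm, 1.0, 1, config.subclone_ccf, ctx, state)

    for spec, t in chosen:
        if spec.kind == "driver_snv":
            arm = spec.target_arm
            history, t_event, state = plan.get(arm, ("neutral", 0.0, (1, 1)))
            phases = _arm_phases(state, history, t_event)
            mult = _multiplicity_at(phases, t, rng)
            emit(arm, t, mult, 1.0, "other", state, driver=spec.name)
            truth_events.append(TrueEvent(spec.name, "driver_snv", arm, t,
                                          (1 - t) * age, None))

    mutations = pd.DataFrame(rows).sort_values(
        ["chrom_arm", "pos"], kind="stable").reset_index(drop=True)

    segments = pd.DataFrame(
        [{"tumor_id": tumor_id, "chrom_arm": arm, "start": 0,
          "end": arm_length_bp(arm),
          "major_cn": plan.get(arm, ("", 0, (1, 1)))[2][0],
          "minor_cn": plan.get(arm, ("", 0, (1, 1)))[2][1]}
         for arm in ARMS])

    meta = {"tumor_id": tumor_id, "purity": round(purity, 6),
            "age": round(age, 4), "hpv_status": hpv, "site": site}
    history = TrueHistory(tumor_id, age, purity, hpv, site, wge_label,
                          truth_events)
    return history, mutations, segments, meta


@dataclass
class CohortBundle:
    """All files of one simulated cohort, plus the truth ledger."""

    config: SimConfig
    mutations: pd.DataFrame
    segments: pd.DataFrame
    metadata: pd.DataFrame
    histories: list[TrueHistory]

    def truth_ledger(self) -> dict:
        return {"n_tumors": self.config.n_tumors,
                "seed": self.config.seed,
                "tumors": [h.to_dict() for h in self.histories]}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.mutations.to_csv(outdir / "mutations.tsv", sep="\t",
                              index=False)
        self.segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(self.truth_ledger(), indent=1, sort_keys=True))


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Simulate a cohort; deterministic given ``config.seed``."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_tumors)
    histories, muts, segs, metas = [], [], [], []
    for i, ss in enumerate(streams):
        tumor_id = f"T{i + 1:04d}"
        h, m, s, meta = simulate_tumor(config, np.random.default_rng(ss),
                                       tumor_id)
        histories.append(h)
        muts.append(m)
        segs.append(s)
        metas.append(meta)
    return CohortBundle(config,
                        pd.concat(muts, ignore_index=True),
                        pd.concat(segs, ignore_index=True),
                        pd.DataFrame(metas), histories)


# ---------------------------------------------------------------------------
# Focused simulators for calibration experiments
# ---------------------------------------------------------------------------

def simulate_clock_cohort(n_tumors: int, clock_rate: float,
                          age_range: tuple[float, float],
                          covered_cpg_mb: float,
                          rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-tumor clonal CpG>T burdens (per Mb) and ages: counts are Poisson
    with mean clock_rate * age * covered_cpg_mb (diploid genomes)."""
    ages = rng.uniform(*age_range, size=n_tumors)
    counts = rng.poisson(clock_rate * ages * covered_cpg_mb)
    return counts / covered_cpg_mb, ages


def simulate_conversion_events(n_events: int, rate: float,
                               immune_fraction: float,
                               tau_range: tuple[float, float],
                               rng: np.random.Generator,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Whole-genome events with ages tau ~ Uniform(tau_range); each is
    immune with probability ``immune_fraction``, otherwise converts to WGT
    after an exponential waiting time at ``rate`` per year.  Returns
    (tau, is_wgt)."""
    tau = rng.uniform(*tau_range, size=n_events)
    immune = rng.random(n_events) < immune_fraction
    if rate > 0:
        wait = rng.exponential(1.0 / rate, size=n_events)
    else:
        wait = np.full(n_events, np.inf)
    return tau, (~immune) & (wait < tau)


def simulate_pi_cohort(n_tumors: int, menu: list[EventSpec],
                       rng: np.random.Generator,
                       informative_mutations: float = 30.0,
                       ) -> dict[str, dict[str, PiDistribution]]:
    """Per-tumor pi posteriors drawn directly from menu ground truth,
    bypassing read-level simulation (league-model test harness).

    For each carried event the true time t is drawn from its window and a
    gain-timing posterior is formed from Binomial(n, phi(t)) informative
    mutation counts on a 1:1 -> 2:1 profile.
    """
    cohort: dict[str, dict[str, PiDistribution]] = {}
    for i in range(n_tumors):
        events: dict[str, PiDistribution] = {}
        for spec in menu:
            if rng.random() >= spec.prevalence:
                continue
            t = rng.uniform(*spec.window)
            n = int(rng.poisson(informative_mutations))
            n_hi = int(rng.binomial(n, phi_of_t(t, 1, 1, 3))) if n else 0
            events[spec.name] = time_segment_gain(n_hi, n - n_hi, 1, 1, 3)
        cohort[f"T{i + 1:04d}"] = events
    return cohort
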
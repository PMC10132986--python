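"""Real-time conversion of molecular timings via the CpG>T clock, and the
WGD-to-WGT conversion-rate model.

CpG>T transitions at CpG dinucleotides (the SBS1 "aging" signature) accrue
approximately linearly with age, so the per-tumor clonal CpG>T burden per
megabase at risk, divided by the cohort clock rate r (mutations per Mb per
year), converts a molecular time pi into years before diagnosis:

    years(pi) = (1 - pi) * burden / r,  truncated to [0, age].

The cohort rate is fitted by a trimmed zero-intercept regression of burden
on age: per-tumor slopes burden/age are computed, the top and bottom 5% are
dropped, and a least-squares zero-intercept line is fitted to the retained
tumors.

Whole-genome amplifications originate as doublings (WGD) and may later
erode to a predominantly triploid profile (WGT).  With a fixed annual
conversion rate lam and a fraction f of tumors that never convert, an
event of age tau (years before diagnosis) presents as WGT with probability

    P(WGT | tau) = (1 - f) * (1 - exp(-lam * tau)),

fitted by maximum likelihood with profile-likelihood confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError
from .timing import PiDistribution

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def classify_context(ref: str, alt: str, context: str) -> str:
    """Classify a substitution as CpG>T, APOBEC or other.

    ``context`` is either a categorical label (passed through) or the
    trinucleotide around the site with the reference base in the middle.
    Purine-reference contexts are complemented to the pyrimidine strand.
    CpG>T: C>T at a CpG (NCG); APOBEC: C>T or C>G in TCW (W in {A, T}).
    A TCG C>T site matches both motifs and is classified CpG>T (the clock
    takes precedence).  Anything unrecognized is "other".
    """
    if context in ("CpG>T", "APOBEC", "other"):
        return context
    ctx = str(context).upper()
    ref = str(ref).upper()
    alt = str(alt).upper()
    if len(ctx) != 3 or any(b not in "ACGT" for b in ctx) or ctx[1] != ref:
        return "other"
    if ref in "AG":
        ctx, ref, alt = _revcomp(ctx), _revcomp(ref), _revcomp(alt)
    if ref == "C" and alt == "T" and ctx[2] == "G":
        return "CpG>T"
    if ref == "C" and alt in "TG" and ctx[0] == "T" and ctx[2] in "AT":
        return "APOBEC"
    return "other"


def count_clock_mutations(annotated: pd.DataFrame,
                          covered_cpg_mb: float) -> float:
    """Clonal CpG>T burden per megabase at risk, copy-number corrected.

    Each clonal powered CpG>T mutation contributes weight 2m/N, where m is
    its multiplicity and N the local total copy number: this normalizes the
    burden to diploid-equivalent Mb-years (a multiplicity-2 mutation on a
    doubled 2:2 region counts once; a post-doubling multiplicity-1 mutation
    on 4 copies counts one half, since twice the copies were at risk).
    """
    if covered_cpg_mb <= 0:
        raise DomainError("covered_cpg_mb must be positive")
    sub = annotated[(annotated["clonal"]) & (annotated["powered"])]
    ctx = [classify_context(r, a, c) for r, a, c in
           zip(sub["ref"], sub["alt"], sub["context"])]
    sub = sub[[c == "CpG>T" for c in ctx]]
    if sub.empty:
        return 0.0
    m = sub["map_multiplicity"].to_numpy(dtype=float)
    n = sub["total_cn"].to_numpy(dtype=float)
    return float(np.sum(2.0 * m / np.maximum(n, 1.0)) / covered_cpg_mb)


@dataclass
class AgingRateFit:
    """Fitted cohort CpG>T clock."""

    rate: float                 # mutations per Mb at risk per year
    slopes: np.ndarray          # all per-tumor burden/age slopes
    retained: np.ndarray        # boolean mask of tumors kept after trimming
    trim_bounds: tuple[float, float]
    iqr: tuple[float, float]    # IQR of the retained slopes
    trimmed: bool


def fit_aging_rate(burdens, ages, trim: float = 0.05,
                   min_tumors: int = 20) -> AgingRateFit:
    """Trimmed zero-intercept regression of CpG>T burden on age.

    Per-tumor slopes burden/age are ranked, the top and bottom ``trim``
    fractions are dropped, and the rate is the zero-intercept least-squares
    slope on the retained tumors.  Below ``min_tumors`` tumors a warning is
    issued and no trimming is applied.
    """
    burdens = np.asarray(burdens, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if burdens.shape != ages.shape or burdens.ndim != 1:
        raise DomainError("burdens and ages must be 1-D and equal length")
    if np.any(ages <= 0):
        raise DomainError("ages must be positive")
    n = burdens.size
    slopes = burdens / ages
    if n < min_tumors:
        warnings.warn(f"only {n} tumors (<{min_tumors}); fitting without "
                      "slope trimming", stacklevel=2)
        retained = np.ones(n, dtype=bool)
        trimmed = False
    else:
        k = int(np.floor(trim * n))
        order = np.argsort(slopes, kind="stable")
        retained = np.ones(n, dtype=bool)
        if k > 0:
            retained[order[:k]] = False
            retained[order[-k:]] = False
        trimmed = k > 0
    a, b = ages[retained], burdens[retained]
    rate = float(a @ b / (a @ a))
    kept = slopes[retained]
    return AgingRateFit(rate=rate, slopes=slopes, retained=retained,
                        trim_bounds=(float(kept.min()), float(kept.max())),
                        iqr=(float(np.quantile(kept, 0.25)),
                             float(np.quantile(kept, 0.75))),
                        trimmed=trimmed)


@dataclass
class RealTimeEstimate:
    """Posterior over years before diagnosis for one event."""

    samples: np.ndarray

    def mean(self) -> float:
        return float(self.samples.mean())

    def credible_interval(self, mass: float = 0.75) -> tuple[float, float]:
        lo = (1.0 - mass) / 2.0
        return (float(np.quantile(self.samples, lo)),
                float(np.quantile(self.samples, 1.0 - lo)))


def pi_to_years(pi: PiDistribution, burden: float, rate: float,
                age: float) -> RealTimeEstimate:
    """Convert a pi posterior into years before diagnosis.

    years = (1 - pi) * burden / rate, truncated to [0, age].  ``burden``
    should be the tumor's clonal CpG>T burden per Mb at diagnosis and
    ``pi`` a posterior computed from CpG>T mutations only.
    """
    if rate <= 0:
        raise DomainError("rate must be positive")
    if burden <= 0:
        raise DomainError("zero CpG>T burden: event cannot be real-timed")
    years = (1.0 - pi.samples) * burden / rate
    return RealTimeEstimate(np.clip(years, 0.0, age))


@dataclass
class ConversionModelFit:
    """Maximum-likelihood WGD-to-WGT conversion model."""

    rate: float               # annual conversion rate lambda
    immune_fraction: float    # fraction of tumors that never convert
    log_likelihood: float
    rate_ci: tuple[float, float]
    immune_ci: tuple[float, float]


def p_wgt(tau, rate: float, immune_fraction: float):
    """P(WGT | event age tau years) = (1-f)(1 - exp(-lam*tau))."""
    tau = np.asarray(tau, dtype=float)
    return (1.0 - immune_fraction) * (-np.expm1(-rate * tau))


def _nll(params, tau, is_wgt):
    lam, f = params
    p = np.clip(p_wgt(tau, lam, f), 1e-12, 1.0 - 1e-12)
    return -float(np.sum(np.where(is_wgt, np.log(p), np.log1p(-p))))


def fit_wgd_wgt_conversion(times_years, classes,
                           max_rate: float = 2.0) -> ConversionModelFit:
    """Fit (lambda, f) by maximum likelihood from real-timed events.

    ``classes`` holds "WGT"/"WGD" labels (or booleans, True = WGT) and
    ``times_years`` the events' years before diagnosis.  Profile-likelihood
    95% confidence intervals are reported for both parameters.
    """
    tau = np.asarray(times_years, dtype=float)
    if tau.size < 10:
        raise DomainError("need at least 10 classified events")
    classes = np.asarray(classes)
    is_wgt = (classes == "WGT") if classes.dtype.kind in "OU" \
        else classes.astype(bool)
    if is_wgt.all() or (~is_wgt).all():
        warnings.warn("all events in one class; boundary fit", stacklevel=2)

    lam_grid = np.linspace(1e-4, max_rate, 241)
    f_grid = np.linspace(0.0, 0.999, 201)
    nll = np.array([[_nll((l, f), tau, is_wgt) for f in f_grid]
                    for l in lam_grid])
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    res = optimize.minimize(_nll, x0=[lam_grid[i], f_grid[j]],
                            args=(tau, is_wgt), method="L-BFGS-B",
                            bounds=[(1e-6, max_rate), (0.0, 0.999)])
    lam_hat, f_hat = res.x
    best = res.fun

    cut = best + stats.chi2.ppf(0.95, df=1) / 2.0
    prof_lam = nll.min(axis=1)
    ok = lam_grid[prof_lam <= cut]
    rate_ci = (float(ok.min()), float(ok.max())) if ok.size else (lam_hat,) * 2
    prof_f = nll.min(axis=0)
    ok = f_grid[prof_f <= cut]
    immune_ci = (float(ok.min()), float(ok.max())) if ok.size else (f_hat,) * 2

    return ConversionModelFit(rate=float(lam_hat),
                              immune_fraction=float(f_hat),
                              log_likelihood=-float(best),
                              rate_ci=rate_ci, immune_ci=immune_ci)
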
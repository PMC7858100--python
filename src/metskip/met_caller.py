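"""Exon-14 skipping calls, expression tiers, distribution diagnostics.

The two call families share one statistical idea: a cohort-adaptive outlier
threshold of the form mean + k.SD, estimated on the analyzed cohort itself
(sample SD, n-1 denominator).

* Skipping: per evaluable sample the log-ratio log(dex14 / wt) of the
  normalized junction-probe and wild-type-probe values. Samples whose raw
  junction count is zero ("no counts") are directly negative and do not enter
  the cutoff estimate. Positive means log-ratio strictly above mean + 2.SD of
  the cohort's defined log-ratios.
* Expression: per evaluable sample the log of the normalized wild-type MET
  value (log-MET). Tier boundaries are mean + 1.SD (moderately elevated) and
  mean + 2.SD (very high), with ">=" at each boundary.

Because both probes share the sample's normalization factors, the log-ratio
(and hence every skipping call) is identical whether computed on raw or
normalized counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_counts import Codeset
from .qc_normalize import NormalizedMatrix, log_transform

__all__ = [
    "CutoffStats",
    "CutoffSet",
    "DetectabilityRule",
    "estimate_cutoff",
    "dex14_log_ratio",
    "call_skipping",
    "categorize_expression",
    "distribution_diagnostics",
    "compare_groups",
    "MixtureFit",
    "DistributionReport",
]


@dataclass(frozen=True)
class CutoffStats:
    """mean + k.SD threshold estimated from a cohort of values."""

    mean: float
    sd: float
    k: float
    cutoff: float
    n: int
    degenerate: bool = False


@dataclass
class CutoffSet:
    """All cutoffs used for one cohort analysis (auditable provenance)."""

    lr: CutoffStats | None = None          # skipping log-ratio, mean + 2 SD
    lm_mod: CutoffStats | None = None      # log-MET, mean + 1 SD
    lm_high: CutoffStats | None = None     # log-MET, mean + 2 SD

    def as_dict(self) -> dict:
        out = {}
        for name, cs in [("lr", self.lr), ("lm_mod", self.lm_mod), ("lm_high", self.lm_high)]:
            if cs is not None:
                out[name] = {
                    "mean": cs.mean, "sd": cs.sd, "k": cs.k,
                    "cutoff": cs.cutoff, "n": cs.n, "degenerate": cs.degenerate,
                }
        return out


@dataclass(frozen=True)
class DetectabilityRule:
    """When does the junction probe count as detected?

    ``raw_zero`` (default): detected iff the raw count is > 0 — the literal
    "no counts" rule. ``background``: detected iff the raw count exceeds the
    per-sample mean + 2.SD of the negative-control counts.
    """

    mode: str = "raw_zero"

    def __post_init__(self) -> None:
        if self.mode not in {"raw_zero", "background"}:
            raise ValueError(f"unknown detectability mode {self.mode!r}")

    def detected(self, raw_dex14: pd.Series, raw: pd.DataFrame, codeset: Codeset) -> pd.Series:
        if self.mode == "raw_zero":
            return raw_dex14 > 0
        neg = raw[codeset.negative_controls].to_numpy(dtype=float)
        if neg.shape[1] == 0:
            raise ValueError("background mode requires negative-control probes")
        bg = neg.mean(axis=1) + 2 * neg.std(axis=1, ddof=1 if neg.shape[1] > 1 else 0)
        return pd.Series(raw_dex14.to_numpy() > bg, index=raw_dex14.index)


def estimate_cutoff(values, k: float) -> CutoffStats:
    """Arithmetic mean, sample SD (n-1) and mean + k.SD of a value cohort."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if len(arr) < 2:
        raise ValueError(f"cutoff estimation requires >=2 values, got {len(arr)}")
    if k < 0:
        raise ValueError("k must be >= 0")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    degenerate = sd == 0.0
    return CutoffStats(mean=mean, sd=sd, k=float(k), cutoff=mean + k * sd, n=len(arr), degenerate=degenerate)


def dex14_log_ratio(
    norm: NormalizedMatrix,
    rule: DetectabilityRule = DetectabilityRule(),
    base: float | str = 2,
) -> pd.Series:
    """Per-sample log(dex14 / wt) on normalized values; NaN where undetected.

    A QC-passing sample with a zero wild-type count is treated as data
    corruption (it passed the housekeeping gate yet has no signal on an
    abundantly expressed probe) and raises, naming the sample.
    """
    cs = norm.codeset
    wt = norm.values[cs.met_wt]
    if (wt <= 0).any():
        bad = list(wt.index[wt <= 0])
        raise ValueError(f"QC-passing sample(s) with zero MET wild-type count: {bad}")
    detected = rule.detected(norm.raw[cs.met_dex14], norm.raw, cs)
    lr = pd.Series(np.nan, index=norm.values.index)
    d = norm.values.loc[detected, cs.met_dex14]
    lr.loc[detected] = log_transform(d / wt[detected], base=base)
    return lr


def call_skipping(
    norm: NormalizedMatrix,
    rule: DetectabilityRule = DetectabilityRule(),
    k: float = 2.0,
    base: float | str = 2,
    frozen: CutoffStats | None = None,
    strict_gt: bool = True,
) -> tuple[pd.Series, CutoffStats | None, pd.Series]:
    """Skipping calls for all QC-passing samples.

    Returns (calls, cutoff, log_ratios). Positive iff the log-ratio exceeds
    mean + k.SD of the cohort's defined log-ratios (strictly, by default);
    undetected samples are negative. With fewer than two defined log-ratios
    every sample is negative and no cutoff is estimated. ``frozen`` supplies
    an externally fixed cutoff for prospective use.
    """
    lr = dex14_log_ratio(norm, rule=rule, base=base)
    calls = pd.Series("negative", index=lr.index)
    defined = lr.dropna()
    if frozen is not None:
        cut = frozen
    elif len(defined) < 2:
        return calls, None, lr
    else:
        cut = estimate_cutoff(defined, k)
    above = defined > cut.cutoff if strict_gt else defined >= cut.cutoff
    calls.loc[above[above].index] = "positive"
    return calls, cut, lr


def categorize_expression(
    norm: NormalizedMatrix,
    k_mod: float = 1.0,
    k_high: float = 2.0,
    base: float | str = 2,
    frozen: tuple[CutoffStats, CutoffStats] | None = None,
) -> tuple[pd.Series, CutoffStats, CutoffStats, pd.Series]:
    """Expression tiers for all QC-passing samples.

    Returns (tiers, cut_mod, cut_high, log_met). ``very_high`` iff
    log-MET >= mean + k_high.SD; ``mod_elevated`` iff mean + k_mod.SD <=
    log-MET < the very-high boundary; otherwise ``normal``. With zero cohort
    SD every sample is normal (degenerate flag set on the cutoffs).
    """
    cs = norm.codeset
    wt = norm.values[cs.met_wt]
    if (wt <= 0).any():
        bad = list(wt.index[wt <= 0])
        raise ValueError(f"QC-passing sample(s) with zero MET wild-type count: {bad}")
    log_met = log_transform(wt, base=base)
    if frozen is not None:
        cut_mod, cut_high = frozen
    else:
        if len(log_met) < 2:
            raise ValueError("cohort cutoffs require >=2 evaluable samples")
        cut_mod = estimate_cutoff(log_met, k_mod)
        cut_high = estimate_cutoff(log_met, k_high)
    tiers = pd.Series("normal", index=log_met.index)
    if not cut_high.degenerate:
        tiers[log_met >= cut_mod.cutoff] = "mod_elevated"
        tiers[log_met >= cut_high.cutoff] = "very_high"
    return tiers, cut_mod, cut_high, log_met


# ---------------------------------------------------------------------------
# distribution diagnostics


@dataclass
class MixtureFit:
    """Two-component equal-variance 1-D Gaussian mixture (EM fit)."""

    means: tuple[float, float]
    sigma: float
    weights: tuple[float, float]
    loglik: float
    loglik_single: float
    boundary: float
    n_iter: int
    converged: bool

    @property
    def delta_loglik(self) -> float:
        return self.loglik - self.loglik_single

    @property
    def separation(self) -> float:
        return abs(self.means[1] - self.means[0])


@dataclass
class DistributionReport:
    n: int
    mean: float
    sd: float
    ks_stat: float | None
    ks_p: float | None
    ks_lilliefors: bool
    mixture: MixtureFit | None
    valley_ratio: float | None
    verdict: str  # "unimodal" | "bimodal" | "degenerate"


def _fit_gmm2(x: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> MixtureFit:
    """Deterministic EM for a two-component equal-variance Gaussian mixture.

    Initialized by a Lloyd 2-means pass seeded at the data extremes, which
    reliably lands one centre in each mode when two exist; no randomness, so
    repeated fits are bit-identical.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    centers = np.array([x[0], x[-1]])
    for _ in range(100):  # Lloyd iterations; deterministic split point
        split = centers.mean()
        lo, hi = x[x <= split], x[x > split]
        if len(lo) == 0 or len(hi) == 0:
            lo, hi = x[: n // 2], x[n // 2:]
            break
        new = np.array([lo.mean(), hi.mean()])
        if np.array_equal(new, centers):
            break
        centers = new
    mu = np.array([lo.mean(), hi.mean()])
    sigma = max(x.std(), 1e-12)
    w = np.array([len(lo) / n, len(hi) / n])

    def loglik_of(mu, sigma, w):
        comp = np.stack([w[j] * stats.norm.pdf(x, mu[j], sigma) for j in range(2)])
        dens = comp.sum(axis=0)
        return float(np.log(np.clip(dens, 1e-300, None)).sum()), comp, dens

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, comp, dens = loglik_of(mu, sigma, w)
        resp = comp / np.clip(dens, 1e-300, None)
        nk = resp.sum(axis=1)
        nk = np.clip(nk, 1e-12, None)
        mu = (resp * x).sum(axis=1) / nk
        var = (resp * (x[None, :] - mu[:, None]) ** 2).sum() / n  # tied variance
        sigma = max(math.sqrt(var), 1e-12)
        w = nk / n
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    ll, _, _ = loglik_of(mu, sigma, w)

    order = np.argsort(mu)
    mu, w = mu[order], w[order]
    # single-Gaussian reference (MLE: mean, population SD)
    s1 = max(x.std(), 1e-12)
    ll1 = float(stats.norm.logpdf(x, x.mean(), s1).sum())
    # equal-variance posterior boundary (closed form); midpoint if weights vanish
    if mu[1] > mu[0] and 0 < w[0] < 1:
        boundary = (mu[0] + mu[1]) / 2 + sigma**2 * math.log(w[0] / w[1]) / (mu[1] - mu[0])
    else:
        boundary = float(mu.mean())
    return MixtureFit(
        means=(float(mu[0]), float(mu[1])), sigma=float(sigma),
        weights=(float(w[0]), float(w[1])), loglik=ll, loglik_single=ll1,
        boundary=float(boundary), n_iter=it, converged=converged,
    )


def _valley_ratio(fit: MixtureFit, x: np.ndarray) -> float:
    """Valley depth of the fitted mixture density between its two modes.

    Returns valley / (lower peak); 1.0 when the fitted density has a single
    mode (no interior valley at all).
    """
    grid = np.linspace(x.min() - fit.sigma, x.max() + fit.sigma, 2001)
    dens = (fit.weights[0] * stats.norm.pdf(grid, fit.means[0], fit.sigma)
            + fit.weights[1] * stats.norm.pdf(grid, fit.means[1], fit.sigma))
    d = np.diff(dens)
    maxima = np.where((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))[0]
    if len(maxima) < 2:
        return 1.0
    top2 = maxima[np.argsort(dens[maxima])][-2:]
    i, j = sorted(top2)
    valley = dens[i:j + 1].min()
    lower_peak = min(dens[i], dens[j])
    return float(valley / lower_peak)


def distribution_diagnostics(
    values,
    loglik_margin: float = 5.0,
    valley_max: float = 0.5,
) -> DistributionReport:
    """Normality test plus a two-component mixture bimodality diagnostic.

    The normality check is a Kolmogorov-Smirnov test with parameters
    estimated from the data (Lilliefors correction; table p-values are
    clipped at 0.001 below / 0.2 above). The verdict is ``bimodal`` iff the
    equal-variance two-component mixture (i) improves the log-likelihood
    over a single Gaussian by more than ``loglik_margin``, (ii) has
    components separated by more than 2 pooled SDs and (iii) its fitted
    density shows an actual valley between two modes (valley / lower peak
    < ``valley_max``); otherwise ``unimodal``. Condition (iii) distinguishes
    a heavy upper tail from a genuinely separated second mode.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        raise ValueError(f"distribution diagnostics require >=8 values, got {len(x)}")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0.0:
        return DistributionReport(len(x), mean, sd, None, None, True, None, None, "degenerate")
    from statsmodels.stats.diagnostic import lilliefors

    ks_stat, ks_p = lilliefors(x, dist="norm", pvalmethod="table")
    fit = _fit_gmm2(x)
    vr = _valley_ratio(fit, x)
    bimodal = (
        fit.delta_loglik > loglik_margin
        and fit.separation > 2 * fit.sigma
        and vr < valley_max
    )
    return DistributionReport(
        n=len(x), mean=mean, sd=sd, ks_stat=float(ks_stat), ks_p=float(ks_p),
        ks_lilliefors=True, mixture=fit, valley_ratio=vr,
        verdict="bimodal" if bimodal else "unimodal",
    )


def compare_groups(
    log_met: pd.Series,
    labels: pd.Series,
    reference: str = "none",
    min_n: int = 3,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Rank-sum comparison of log-MET between each driver group and a reference.

    Two-sided Mann-Whitney U per group vs the reference group; groups with
    fewer than ``min_n`` samples are skipped with a warning. No multiplicity
    adjustment by default; pass e.g. ``adjust="holm"`` or ``"fdr_bh"`` for
    statsmodels-adjusted p-values in an extra column.
    """
    labels = labels.reindex(log_met.index)
    ref_vals = log_met[labels == reference].dropna()
    if len(ref_vals) < min_n:
        raise ValueError(f"reference group {reference!r} has {len(ref_vals)} samples (< {min_n})")
    rows = []
    for group in sorted(set(labels.dropna()) - {reference}):
        vals = log_met[labels == group].dropna()
        if len(vals) < min_n:
            warnings.warn(f"group {group!r} has {len(vals)} samples (< {min_n}); skipped")
            continue
        u, p = stats.mannwhitneyu(vals, ref_vals, alternative="two-sided")
        rows.append({"group": group, "n": len(vals), "n_ref": len(ref_vals),
                     "statistic": float(u), "p_value": float(p),
                     "median_shift": float(vals.median() - ref_vals.median())})
    out = pd.DataFrame(rows, columns=["group", "n", "n_ref", "statistic", "p_value", "median_shift"])
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = multipletests(out["p_value"], method=adjust)[1]
    return out
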
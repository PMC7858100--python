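"""Cross-method agreement statistics for paired binary calls.

All statistics derive from a 2x2 table of a test assay against a reference
assay: percent agreement with a Wilson score interval (Clopper-Pearson
available), Cohen's kappa, and sensitivity/specificity treating the
reference assay's calls as truth. Samples with an unknown call on either
side are excluded pairwise, which is why each comparison has its own N.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable2x2",
    "build_table",
    "percent_agreement",
    "cohens_kappa",
    "sens_spec",
    "kappa_band",
    "agreement_report",
]

POSITIVE, NEGATIVE, UNKNOWN = "positive", "negative", "unknown"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Paired binary calls: a = both positive, b = test-only positive,
    c = reference-only positive, d = both negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n < 1:
            raise ValueError("table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        """The same pairs with test and reference roles exchanged."""
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


def _as_binary(calls: pd.Series) -> pd.Series:
    s = calls.astype(str).str.strip().str.lower()
    ok = s.isin([POSITIVE, NEGATIVE, UNKNOWN, "nan", ""])
    if not ok.all():
        bad = sorted(set(s[~ok]))
        raise ValueError(f"calls must be positive/negative/unknown; got {bad}")
    return s.replace({"nan": UNKNOWN, "": UNKNOWN})


def build_table(test_calls: pd.Series, ref_calls: pd.Series) -> tuple[ContingencyTable2x2, int]:
    """Tally paired calls aligned by sample id.

    Returns (table, n_dropped) where n_dropped counts samples excluded
    because either call was unknown or missing on one side.
    """
    t = _as_binary(test_calls)
    r = _as_binary(ref_calls)
    common = t.index.intersection(r.index)
    t, r = t.loc[common], r.loc[common]
    known = (t != UNKNOWN) & (r != UNKNOWN)
    n_dropped = int(len(test_calls.index.union(ref_calls.index)) - known.sum())
    t, r = t[known], r[known]
    if len(t) == 0:
        raise ValueError("no overlapping samples with both calls known")
    return (
        ContingencyTable2x2(
            a=int(((t == POSITIVE) & (r == POSITIVE)).sum()),
            b=int(((t == POSITIVE) & (r == NEGATIVE)).sum()),
            c=int(((t == NEGATIVE) & (r == POSITIVE)).sum()),
            d=int(((t == NEGATIVE) & (r == NEGATIVE)).sum()),
        ),
        n_dropped,
    )


def _proportion_ci(k: int, n: int, conf: float, method: str) -> tuple[float, float]:
    meth = {"wilson": "wilson", "clopper-pearson": "beta", "exact": "beta"}[method]
    lo, hi = proportion_confint(k, n, alpha=1 - conf, method=meth)
    # the score interval is exactly [.., 1] at p-hat = 1 (and [0, ..] at 0);
    # clamp float round-off so the bounds honour that
    lo = 0.0 if k == 0 else max(float(lo), 0.0)
    hi = 1.0 if k == n else min(float(hi), 1.0)
    return lo, hi


def percent_agreement(
    t: ContingencyTable2x2, conf: float = 0.95, method: str = "wilson"
) -> tuple[float, float, float]:
    """Observed agreement (a+d)/n with a binomial score interval.

    Returned as proportions in [0, 1]; the Wilson upper bound is exactly 1
    when every pair agrees.
    """
    p = (t.a + t.d) / t.n
    lo, hi = _proportion_ci(t.a + t.d, t.n, conf, method)
    return p, lo, hi


def cohens_kappa(t: ContingencyTable2x2) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    When expected agreement p_e is 1 (both raters constant), kappa is 1 for
    perfect observed agreement and NaN otherwise.
    """
    n = t.n
    p_o = (t.a + t.d) / n
    p_e = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1 - p_e)


def sens_spec(
    t: ContingencyTable2x2, conf: float = 0.95, method: str = "wilson"
) -> dict:
    """Sensitivity a/(a+c) and specificity d/(b+d) of the test assay,
    treating the reference assay's calls as truth; each with a score CI.

    A component with an empty denominator is returned as None.
    """
    out = {"orientation": "reference-as-truth"}
    if t.a + t.c >= 1:
        out["sensitivity"] = t.a / (t.a + t.c)
        out["sensitivity_ci"] = _proportion_ci(t.a, t.a + t.c, conf, method)
    else:
        out["sensitivity"] = None
        out["sensitivity_ci"] = None
    if t.b + t.d >= 1:
        out["specificity"] = t.d / (t.b + t.d)
        out["specificity_ci"] = _proportion_ci(t.d, t.b + t.d, conf, method)
    else:
        out["specificity"] = None
        out["specificity_ci"] = None
    return out


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value (Landis-Koch style)."""
    if kappa != kappa:  # NaN
        return "undefined"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def agreement_report(
    pairs: list[tuple[str, pd.Series, pd.Series]],
    conf: float = 0.95,
    method: str = "wilson",
) -> pd.DataFrame:
    """One row per comparison: n, percent agreement + CI, kappa (+band),
    sensitivity and specificity. Proportions are reported in percent."""
    if not pairs:
        raise ValueError("agreement_report requires at least one comparison")
    rows = []
    for name, test, ref in pairs:
        tab, n_dropped = build_table(test, ref)
        p, lo, hi = percent_agreement(tab, conf, method)
        kap = cohens_kappa(tab)
        ss = sens_spec(tab, conf, method)
        rows.append({
            "comparison": name, "n": tab.n, "n_dropped": n_dropped,
            "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
            "agreement_pct": 100 * p,
            "agreement_ci_low": 100 * lo, "agreement_ci_high": 100 * hi,
            "kappa": kap, "kappa_band": kappa_band(kap),
            "sensitivity_pct": None if ss["sensitivity"] is None else 100 * ss["sensitivity"],
            "specificity_pct": None if ss["specificity"] is None else 100 * ss["specificity"],
        })
    return pd.DataFrame(rows).set_index("comparison")
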
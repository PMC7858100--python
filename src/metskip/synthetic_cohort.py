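"""Synthetic probe-count cohorts with known ground truth.

The generator emulates the statistical structure of an FFPE NSCLC cohort
profiled on a targeted MET panel: ~11% of samples fail the housekeeping
QC gate, log-MET expression is unimodal with a high tail (a small very-high
stratum and a larger moderately-elevated stratum), and the exon-14-skipped /
wild-type log-ratio is bimodal with ~3% positives.

Generative model (per sample i):

* lane scalar s_i = exp(N(0, lane_factor_sd)), applied to every probe mean;
* latent MET level z_i: truncated N(0, 1) (upper truncation at
  ``bulk_truncate_sd``) for normal-tier samples, N(shift_mod, within_group_sd)
  for moderately elevated, N(shift_very_high, within_group_sd) for very high.
  The bulk is truncated so that true tier labels remain identifiable: an
  unbounded Gaussian bulk would place ~1 sample per cohort above any
  cohort-adaptive mean + 2.SD cutoff by construction;
* total MET mean mu_i = met_wt_mean * 2**(sigma_log2 * z_i), with sigma_log2
  chosen in closed form so the latent cohort log2-SD is ~1;
* skipping-positive samples reallocate mu_i between isoforms: wild-type probe
  mean (1 - skipped_fraction) * mu_i, junction probe mean
  skipped_fraction * mu_i (total MET output is conserved, matching the
  observed moderate-but-not-high expression of skipping cases);
* skipping-negative samples see junction-probe background
  negctrl_mean + crosshyb_frac * mu_i — a floor of nonspecific binding plus
  cross-hybridization that tracks the abundant wild-type transcript;
* QC-failing samples have housekeeping and endogenous means multiplied by
  ``qc_fail_depletion`` (degraded RNA), driving the housekeeping geomean
  far below 100; positive-control spike-ins are unaffected by RNA quality;
* every count is negative-binomial via the gamma-Poisson mixture with size
  ``nb_dispersion`` (variance mu * (1 + mu/size); size -> inf is Poisson).

All randomness flows from the single config seed through one Generator with
a fixed draw order (statuses, lane factors, z, then counts probe-block by
probe-block), so identical configs reproduce bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_counts import Codeset, MetRole, ProbeClass, ProbeDefinition, RawCountMatrix

__all__ = ["CohortSimConfig", "default_codeset", "simulate_cohort", "simulate_spikein", "CELL_MODELS"]

# positive-control ladder (relative input-concentration steps)
_POS_LADDER = {"POS_A": 8.0, "POS_B": 4.0, "POS_C": 2.0, "POS_D": 1.0, "POS_E": 0.5, "POS_F": 0.25}
# modest expression differences between the three housekeeping genes
_HK_LEVELS = {"ACTB": 1.5, "PSMC4": 1.0, "MRPL19": 0.7}
_NEG_PROBES = ["NEG_A", "NEG_B", "NEG_C", "NEG_D"]


def default_codeset() -> Codeset:
    """The simulated panel: MET wt + junction probes, ACTB/PSMC4/MRPL19
    housekeepers, six positive and four negative control probes."""
    probes = [
        ProbeDefinition("MET_wt", ProbeClass.ENDOGENOUS, MetRole.MET_WT),
        ProbeDefinition("MET_dex14", ProbeClass.ENDOGENOUS, MetRole.MET_DEX14),
    ]
    probes += [ProbeDefinition(n, ProbeClass.HOUSEKEEPING) for n in _HK_LEVELS]
    probes += [ProbeDefinition(n, ProbeClass.POSITIVE_CONTROL) for n in _POS_LADDER]
    probes += [ProbeDefinition(n, ProbeClass.NEGATIVE_CONTROL) for n in _NEG_PROBES]
    return Codeset(tuple(probes))


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort composition and noise model; defaults mirror the study cohort
    (474 samples: 52 QC-fail; among the 422 evaluable, 13 skipping-positive,
    15 very-high and 36 moderately-elevated MET mRNA)."""

    n_samples: int = 474
    frac_qc_fail: float = 52 / 474
    n_skipping: int = 13
    n_very_high: int = 15
    n_mod_elevated: int = 36
    skipped_fraction: float = 0.5      # isoform fraction lacking exon 14 in positives
    shift_very_high: float = 4.0       # latent log-SD units
    shift_mod: float = 1.5
    within_group_sd: float = 0.25
    bulk_truncate_sd: float = 2.3      # upper truncation of the normal-tier stratum
    nb_dispersion: float = 100.0       # NB size; var = mu(1 + mu/size); inf -> Poisson
    lane_factor_sd: float = 0.3        # natural-log SD of the per-sample lane scalar
    crosshyb_frac: float = 0.003       # junction-probe cross-hybridization to wt MET
    qc_fail_depletion: float = 0.03    # RNA-content factor for QC-failing samples
    hk_mean: float = 600.0
    posctrl_mean: float = 1000.0
    negctrl_mean: float = 4.0
    met_wt_mean: float = 2000.0
    seed: int = 0

    @property
    def n_qc_fail(self) -> int:
        return int(round(self.frac_qc_fail * self.n_samples))

    def validate(self) -> None:
        if not (0 <= self.frac_qc_fail < 1):
            raise ValueError("frac_qc_fail must be in [0, 1)")
        if not (0 < self.skipped_fraction <= 1):
            raise ValueError("skipped_fraction must be in (0, 1]")
        if self.shift_very_high <= self.shift_mod or self.shift_mod < 0:
            raise ValueError("group shifts must satisfy shift_very_high > shift_mod >= 0")
        n_eval = self.n_samples - self.n_qc_fail
        n_special = self.n_skipping + self.n_very_high + self.n_mod_elevated
        if n_special > n_eval:
            raise ValueError(
                f"infeasible config: {n_special} labelled samples exceed {n_eval} evaluable"
            )
        for name in ("nb_dispersion", "hk_mean", "posctrl_mean", "negctrl_mean", "met_wt_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lane_factor_sd < 0:
            raise ValueError("lane_factor_sd must be >= 0")


def _sigma_log2(cfg: CohortSimConfig) -> float:
    """Closed-form calibration of the latent-to-log2 scale so the evaluable
    cohort's log2-MET SD is ~1 (untruncated moments; calls are invariant to
    this constant, it only sets the relative weight of count noise)."""
    n_eval = cfg.n_samples - cfg.n_qc_fail
    n_norm = n_eval - cfg.n_very_high - cfg.n_mod_elevated
    w = np.array([n_norm, cfg.n_mod_elevated, cfg.n_very_high], dtype=float)
    if w.sum() == 0:
        return 1.0
    w /= w.sum()
    mu = np.array([0.0, cfg.shift_mod, cfg.shift_very_high])
    var = np.array([1.0, cfg.within_group_sd**2, cfg.within_group_sd**2])
    m = (w * mu).sum()
    v = (w * (var + mu**2)).sum() - m**2
    return 1.0 / math.sqrt(v) if v > 0 else 1.0


def _nbinom(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    """Gamma-Poisson negative binomial draw; Poisson in the size -> inf limit."""
    mean = np.asarray(mean, dtype=float)
    if math.isinf(size):
        return rng.poisson(mean)
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def _truncated_normal(rng: np.random.Generator, n: int, upper: float) -> np.ndarray:
    """Standard normal truncated above at ``upper`` (rejection sampling)."""
    out = rng.normal(size=n)
    while True:
        bad = out > upper
        if not bad.any():
            return out
        out[bad] = rng.normal(size=int(bad.sum()))


def simulate_cohort(config: CohortSimConfig | None = None) -> tuple[RawCountMatrix, pd.DataFrame]:
    """Draw a raw count cohort and its ground truth.

    Returns (RawCountMatrix, GroundTruth) where the truth frame has per-sample
    columns ``qc_fail`` (bool), ``skipping`` (bool) and ``tier``
    (normal / mod_elevated / very_high). The count matrix also carries
    ``sample_meta`` with a driver label and truth-derived orthogonal assay
    calls (useful for concordance exercises).
    """
    cfg = config or CohortSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    codeset = default_codeset()
    n = cfg.n_samples
    ids = [f"S{i + 1:04d}" for i in range(n)]

    # 1) status assignment on a seeded permutation
    order = rng.permutation(n)
    qc_fail = np.zeros(n, dtype=bool)
    qc_fail[order[: cfg.n_qc_fail]] = True
    evaluable = order[cfg.n_qc_fail:]
    tier = np.array(["normal"] * n, dtype=object)
    skipping = np.zeros(n, dtype=bool)
    skipping[evaluable[: cfg.n_skipping]] = True
    pos = cfg.n_skipping
    tier[evaluable[pos: pos + cfg.n_very_high]] = "very_high"
    pos += cfg.n_very_high
    tier[evaluable[pos: pos + cfg.n_mod_elevated]] = "mod_elevated"
    tier[qc_fail] = "normal"  # latent level of failing samples is uninformative

    # 2) lane factors, 3) latent MET levels
    lane = np.exp(rng.normal(0.0, cfg.lane_factor_sd, size=n))
    z = np.empty(n)
    is_norm = tier == "normal"
    z[is_norm] = _truncated_normal(rng, int(is_norm.sum()), cfg.bulk_truncate_sd)
    z[tier == "very_high"] = rng.normal(cfg.shift_very_high, cfg.within_group_sd, int((tier == "very_high").sum()))
    z[tier == "mod_elevated"] = rng.normal(cfg.shift_mod, cfg.within_group_sd, int((tier == "mod_elevated").sum()))

    sigma = _sigma_log2(cfg)
    mu_met = cfg.met_wt_mean * np.power(2.0, sigma * z)
    f = np.where(skipping, cfg.skipped_fraction, 0.0)
    mu_wt = (1.0 - f) * mu_met
    mu_dex = np.where(skipping, f * mu_met, cfg.negctrl_mean + cfg.crosshyb_frac * mu_met)

    rna_quality = np.where(qc_fail, cfg.qc_fail_depletion, 1.0)

    # 4) counts, probe block by probe block in codeset order
    counts = {}
    counts["MET_wt"] = _nbinom(rng, lane * rna_quality * mu_wt, cfg.nb_dispersion)
    counts["MET_dex14"] = _nbinom(rng, lane * rna_quality * mu_dex, cfg.nb_dispersion)
    for probe, lvl in _HK_LEVELS.items():
        counts[probe] = _nbinom(rng, lane * rna_quality * cfg.hk_mean * lvl, cfg.nb_dispersion)
    for probe, lvl in _POS_LADDER.items():
        counts[probe] = _nbinom(rng, lane * cfg.posctrl_mean * lvl, cfg.nb_dispersion)
    for probe in _NEG_PROBES:
        counts[probe] = _nbinom(rng, np.full(n, cfg.negctrl_mean) * lane, cfg.nb_dispersion)

    count_df = pd.DataFrame(counts, index=ids)[codeset.names]
    count_df.index.name = "sample_id"

    truth = pd.DataFrame(
        {"qc_fail": qc_fail, "skipping": skipping, "tier": tier}, index=ids
    )
    truth.index.name = "sample_id"

    driver = np.where(skipping, "METdex14", np.where(tier == "very_high", "MET_amp", "none"))
    meta = pd.DataFrame(
        {
            "timepoint": "unknown",
            "driver": driver,
            "ngs_dex14": np.where(skipping, "positive", "negative"),
            "fish_amp": np.where(tier == "very_high", "positive", "negative"),
        },
        index=ids,
    )
    meta.loc[qc_fail, ["ngs_dex14", "fish_amp"]] = "unknown"
    return RawCountMatrix(counts=count_df, sample_meta=meta), truth


# ---------------------------------------------------------------------------
# spike-in mixtures

# probe-mean models of the three cell backgrounds, as multiples of the
# wild-type cell's total MET output: the skipping cell is MET-amplified with
# 90% of its transcripts lacking exon 14; the amplified cell over-expresses
# intact MET. Synthetic stand-ins for cultured-cell profiles; not measured data.
CELL_MODELS = {
    "wt_cell": {"met_total": 1.0, "skipped_fraction": 0.0},
    "skipping_cell": {"met_total": 16.0, "skipped_fraction": 0.9},
    "amplified_cell": {"met_total": 16.0, "skipped_fraction": 0.0},
}


def simulate_spikein(
    mix_fraction: float,
    background: str = "skipping_cell",
    n_replicates: int = 3,
    seed: int = 0,
    config: CohortSimConfig | None = None,
) -> RawCountMatrix:
    """Pseudo-samples whose MET probe means are convex mixtures of a spiked
    cell model and the wild-type cell model.

    ``mix_fraction`` is the fraction of spiked cells; at 0 the sample is
    indistinguishable from the wild-type background. Housekeeping and control
    probes follow the cohort defaults.
    """
    if not (0 <= mix_fraction <= 1):
        raise ValueError("mix_fraction must be in [0, 1]")
    if background not in CELL_MODELS:
        raise ValueError(f"unknown cell model {background!r}; choose from {sorted(CELL_MODELS)}")
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(seed)
    codeset = default_codeset()
    spike, base = CELL_MODELS[background], CELL_MODELS["wt_cell"]

    def met_means(model):
        total = cfg.met_wt_mean * model["met_total"]
        fskip = model["skipped_fraction"]
        wt = (1 - fskip) * total
        dex = fskip * total + cfg.negctrl_mean + cfg.crosshyb_frac * total
        return wt, dex

    wt_s, dex_s = met_means(spike)
    wt_b, dex_b = met_means(base)
    mu_wt = mix_fraction * wt_s + (1 - mix_fraction) * wt_b
    mu_dex = mix_fraction * dex_s + (1 - mix_fraction) * dex_b

    ids = [f"MIX{int(round(mix_fraction * 100)):03d}_R{r + 1}" for r in range(n_replicates)]
    nrep = n_replicates
    counts = {
        "MET_wt": _nbinom(rng, np.full(nrep, mu_wt), cfg.nb_dispersion),
        "MET_dex14": _nbinom(rng, np.full(nrep, mu_dex), cfg.nb_dispersion),
    }
    for probe, lvl in _HK_LEVELS.items():
        counts[probe] = _nbinom(rng, np.full(nrep, cfg.hk_mean * lvl), cfg.nb_dispersion)
    for probe, lvl in _POS_LADDER.items():
        counts[probe] = _nbinom(rng, np.full(nrep, cfg.posctrl_mean * lvl), cfg.nb_dispersion)
    for probe in _NEG_PROBES:
        counts[probe] = _nbinom(rng, np.full(nrep, cfg.negctrl_mean), cfg.nb_dispersion)
    df = pd.DataFrame(counts, index=ids)[codeset.names]
    df.index.name = "sample_id"
    return RawCountMatrix(counts=df)
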
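"""Sample evaluability filtering and two-step count normalization.

A sample is evaluable only if the geometric mean of its *raw* housekeeping
counts reaches a threshold (default 100; the comparison is "lower than" on
the fail side, so a geomean of exactly 100 passes). Evaluable samples are
then normalized in two multiplicative steps, following the standard nCounter
convention: first to the positive-control content (correcting lane/hybridisation
efficiency), then to the housekeeping content (correcting RNA input). Each
step scales a sample by (cohort mean of per-sample geomeans) / (sample geomean),
with the cohort reference taken over QC-passing samples only.

Because both steps are per-sample scalar multiplications, within-sample probe
ratios — in particular the exon-14-skipped / wild-type ratio — are exactly
invariant under normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_counts import Codeset, RawCountMatrix

__all__ = ["NormalizedMatrix", "hk_geomean", "qc_filter", "normalize_two_step", "log_transform"]

_LOG_BASES = {"2": 2.0, "10": 10.0, "e": math.e, 2: 2.0, 10: 10.0, 2.0: 2.0, 10.0: 10.0}


@dataclass
class NormalizedMatrix:
    """Normalized values for QC-passing samples plus per-sample provenance.

    ``values`` rows cover only QC-passing samples; ``raw`` retains the raw
    counts of those samples (the zero-count detectability rule for the
    skipped-exon probe is defined on raw counts). For every passing sample
    ``values = counts * pos_factor * hk_factor``.
    """

    values: pd.DataFrame
    raw: pd.DataFrame
    pos_factor: pd.Series
    hk_factor: pd.Series
    qc_pass: pd.Series
    hk_geomean: pd.Series
    codeset: Codeset

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def _geomean_rows(df: pd.DataFrame) -> pd.Series:
    """Row-wise geometric mean with the zero-annihilation convention."""
    arr = df.to_numpy(dtype=float)
    out = np.zeros(len(df))
    pos = (arr > 0).all(axis=1)
    if pos.any():
        out[pos] = np.exp(np.log(arr[pos]).mean(axis=1))
    return pd.Series(out, index=df.index)


def hk_geomean(counts: pd.Series | np.ndarray, codeset: Codeset | None = None) -> float:
    """Geometric mean of one sample's raw housekeeping counts.

    With a codeset, ``counts`` is the sample's full probe row and the
    housekeeping subset is selected; without one, ``counts`` is taken to be
    the housekeeping counts themselves. Returns 0.0 if any count is zero
    (such a sample can never pass QC — the intended outcome for a dead lane).
    """
    if isinstance(counts, pd.Series) and codeset is not None:
        vals = counts[codeset.housekeeping].to_numpy(dtype=float)
    else:
        vals = np.asarray(counts, dtype=float)
    if (vals <= 0).any():
        return 0.0
    return float(np.exp(np.log(vals).mean()))


def qc_filter(matrix: RawCountMatrix, codeset: Codeset, threshold: float = 100.0) -> pd.Series:
    """Evaluability flags: pass iff the raw housekeeping geomean is >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gm = _geomean_rows(matrix.counts[codeset.housekeeping])
    return gm >= threshold


def normalize_two_step(
    matrix: RawCountMatrix,
    codeset: Codeset,
    qc_pass: pd.Series | None = None,
    qc_threshold: float = 100.0,
) -> NormalizedMatrix:
    """Positive-control scaling followed by housekeeping scaling.

    Each factor is (arithmetic mean over QC-passing samples of the per-sample
    geomean) / (this sample's geomean), computed on the relevant probe class;
    the housekeeping step uses the step-1-scaled values. A QC-passing sample
    with a zero positive-control geomean indicates a corrupt lane and raises.
    """
    if not codeset.positive_controls:
        raise ValueError("codeset has no positive-control probes")
    if qc_pass is None:
        qc_pass = qc_filter(matrix, codeset, qc_threshold)
    hk_gm_all = _geomean_rows(matrix.counts[codeset.housekeeping])
    passing = matrix.counts.loc[qc_pass.reindex(matrix.counts.index, fill_value=False)]
    if len(passing) == 0:
        raise ValueError("no QC-passing samples to normalize")

    pos_gm = _geomean_rows(passing[codeset.positive_controls])
    if (pos_gm == 0).any():
        bad = list(pos_gm.index[pos_gm == 0])
        raise ValueError(f"QC-passing sample(s) with zero positive-control geomean (corrupt lane): {bad}")
    pos_factor = pos_gm.mean() / pos_gm
    step1 = passing.astype(float).mul(pos_factor, axis=0)

    hk_gm = _geomean_rows(step1[codeset.housekeeping])
    if (hk_gm == 0).any():
        bad = list(hk_gm.index[hk_gm == 0])
        raise ValueError(f"QC-passing sample(s) with zero housekeeping geomean: {bad}")
    hk_factor = hk_gm.mean() / hk_gm
    values = step1.mul(hk_factor, axis=0)

    return NormalizedMatrix(
        values=values,
        raw=passing,
        pos_factor=pos_factor,
        hk_factor=hk_factor,
        qc_pass=qc_pass.reindex(matrix.counts.index, fill_value=False),
        hk_geomean=hk_gm_all,
        codeset=codeset,
    )


def log_transform(values, base: float | str = 2):
    """Elementwise logarithm in the requested base (2, 10 or 'e').

    Downstream mean+k.SD classification is invariant to the base, since a
    base change is a positive linear rescaling of the log values.
    """
    if base not in _LOG_BASES:
        raise ValueError(f"unsupported log base {base!r}; use 2, 10 or 'e'")
    b = _LOG_BASES[base]
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("log_transform received negative values")
    if (arr == 0).any():
        raise ValueError("log_transform received zero values; zeros must be handled upstream")
    out = np.log(arr) / math.log(b)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out
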
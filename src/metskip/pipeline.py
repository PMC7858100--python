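"""End-to-end orchestration: QC -> normalize -> log -> calls -> concordance.

Every run produces a per-sample call table, a cohort summary and a manifest
recording the inputs, the configuration snapshot and the data-dependent
cutoffs actually used, so each reported number is traceable. The pipeline is
a pure function of (inputs, config): identical inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import agreement_report
from .config import AnalysisConfig
from .io_counts import CALL_COLUMNS, Codeset, RawCountMatrix, validate_calls
from .met_caller import (
    CutoffSet,
    DetectabilityRule,
    call_skipping,
    categorize_expression,
    distribution_diagnostics,
)
from .qc_normalize import normalize_two_step, qc_filter

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_concordance"]

# annotation-column suffix -> which pipeline call it is compared against
_ASSAY_KIND = {"dex14": "dex14", "amp": "very_high"}


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    summary: dict
    manifest: dict
    cutoffs: CutoffSet
    diagnostics: dict
    concordance: pd.DataFrame | None = None


def _codeset_hash(codeset: Codeset) -> str:
    canon = ";".join(f"{p.name}:{p.probe_class.value}:{p.met_role.value}" for p in codeset.probes)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(
    matrix: RawCountMatrix,
    codeset: Codeset,
    annotations: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    frozen_cutoffs: CutoffSet | None = None,
    diagnostics: bool = True,
) -> PipelineResult:
    """Run the full calling pipeline on a raw count cohort.

    Stages: QC filter, two-step normalization, log transform, skipping call,
    expression tiering, optional distribution diagnostics and concordance
    against annotation columns (``*_dex14`` vs the skipping call, ``*_amp``
    vs the very-high tier). Errors are re-raised with the failing stage name.
    """
    cfg = config or AnalysisConfig()
    stage = "qc"
    try:
        qc_pass = qc_filter(matrix, codeset, cfg.qc_hk_geomean_min)
        n_eval = int(qc_pass.sum())
        if n_eval < 2 and frozen_cutoffs is None:
            raise ValueError("cohort cutoffs require >=2 evaluable samples (supply frozen cutoffs)")
        stage = "normalize"
        norm = normalize_two_step(matrix, codeset, qc_pass=qc_pass)
        stage = "call_skipping"
        rule = DetectabilityRule(cfg.detect_mode)
        dex_calls, lr_cut, lr = call_skipping(
            norm, rule=rule, k=cfg.lr_k, base=cfg.log_base,
            frozen=frozen_cutoffs.lr if frozen_cutoffs else None,
            strict_gt=cfg.strict_gt,
        )
        stage = "categorize_expression"
        frozen_lm = (frozen_cutoffs.lm_mod, frozen_cutoffs.lm_high) if frozen_cutoffs else None
        tiers, lm_mod, lm_high, log_met = categorize_expression(
            norm, k_mod=cfg.lm_k_mod, k_high=cfg.lm_k_high, base=cfg.log_base, frozen=frozen_lm
        )
    except Exception as err:
        raise type(err)(f"[stage {stage}] {err}") from err

    cutoffs = CutoffSet(lr=lr_cut, lm_mod=lm_mod, lm_high=lm_high)

    calls = pd.DataFrame(index=matrix.counts.index, columns=CALL_COLUMNS)
    calls.index.name = "sample_id"
    calls["qc_pass"] = qc_pass
    calls["hk_geomean"] = norm.hk_geomean
    calls["log_met"] = log_met.reindex(calls.index)
    calls["dex14_log_ratio"] = lr.reindex(calls.index)
    calls["expression_tier"] = tiers.reindex(calls.index).fillna("not_evaluable")
    calls["dex14_call"] = dex_calls.reindex(calls.index).fillna("not_evaluable")
    validate_calls(calls)

    tier_counts = calls["expression_tier"].value_counts()
    summary = {
        "n_total": matrix.n_samples,
        "n_not_evaluable": matrix.n_samples - n_eval,
        "n_evaluable": n_eval,
        "n_dex14_positive": int((calls["dex14_call"] == "positive").sum()),
        "n_very_high": int(tier_counts.get("very_high", 0)),
        "n_mod_elevated": int(tier_counts.get("mod_elevated", 0)),
        "n_normal": int(tier_counts.get("normal", 0)),
        "n_log_ratio_defined": 0 if lr_cut is None else lr_cut.n,
        "cutoffs": cutoffs.as_dict(),
    }
    assert summary["n_total"] == summary["n_not_evaluable"] + summary["n_evaluable"]

    diag = {}
    if diagnostics:
        if lr.notna().sum() >= 8:
            diag["log_ratio"] = distribution_diagnostics(lr.dropna())
        if len(log_met) >= 8:
            diag["log_met"] = distribution_diagnostics(log_met)

    conc = None
    if annotations is not None:
        conc = run_concordance(calls, annotations, config=cfg)

    manifest = {
        "software": "metskip",
        "version": __version__,
        "config": {k: (v if not isinstance(v, float) or np.isfinite(v) else str(v))
                   for k, v in cfg.as_dict().items()},
        "codeset_hash": _codeset_hash(codeset),
        "stage_counts": {k: summary[k] for k in
                         ("n_total", "n_not_evaluable", "n_evaluable",
                          "n_dex14_positive", "n_very_high", "n_mod_elevated")},
        "cutoffs": cutoffs.as_dict(),
        "frozen_cutoffs": frozen_cutoffs is not None,
    }
    for name, cs in cutoffs.as_dict().items():
        log.info("cutoff %s: mean=%.6g sd=%.6g k=%g -> %.6g (n=%d)",
                 name, cs["mean"], cs["sd"], cs["k"], cs["cutoff"], cs["n"])

    return PipelineResult(calls=calls, summary=summary, manifest=manifest,
                          cutoffs=cutoffs, diagnostics=diag, concordance=conc)


def run_concordance(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Compare pipeline calls with orthogonal assay annotations.

    Annotation columns ending ``_dex14`` are compared against the skipping
    call and columns ending ``_amp`` against the very-high expression tier;
    evaluable samples only, unknowns excluded pairwise.
    """
    cfg = config or AnalysisConfig()
    validate_calls(calls)
    evaluable = calls[calls["qc_pass"].astype(bool)]
    dex_bin = evaluable["dex14_call"]
    vh_bin = pd.Series(np.where(evaluable["expression_tier"] == "very_high", "positive", "negative"),
                       index=evaluable.index)
    pairs = []
    for col in annotations.columns:
        kind = next((v for k, v in _ASSAY_KIND.items() if col.lower().endswith(k)), None)
        if kind is None:
            continue
        test = dex_bin if kind == "dex14" else vh_bin
        ref = annotations[col]
        overlap = test.index.intersection(ref.index)
        if len(overlap) == 0:
            continue
        pairs.append((col, test.loc[overlap], ref.loc[overlap]))
    if not pairs:
        raise ValueError("no annotation assay overlaps the calls")
    return agreement_report(pairs, conf=cfg.ci_conf, method=cfg.ci_method)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write calls.tsv, summary.json, manifest.json (and concordance.tsv)."""
    from .io_counts import write_calls

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"calls": out / "calls.tsv", "summary": out / "summary.json",
             "manifest": out / "manifest.json"}
    write_calls(result.calls, paths["calls"],
                cutoffs={k: v["cutoff"] for k, v in result.cutoffs.as_dict().items()},
                summary_path=paths["summary"])
    paths["summary"].write_text(json.dumps(result.summary, indent=2, default=float) + "\n")
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2, default=float) + "\n")
    if result.concordance is not None:
        paths["concordance"] = out / "concordance.tsv"
        result.concordance.to_csv(paths["concordance"], sep="\t", float_format="%.6g")
    return paths
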
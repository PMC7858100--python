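"""Reading and writing probe count data, codesets, annotations and call tables.

Two count dialects are supported: NanoString-style RCC files (one per sample,
only the ``Code_Summary`` section and the sample identity are consumed) and a
plain delimited table (first column sample id, remaining columns probe names).
Probe names are matched exactly and case-sensitively against the codeset.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ProbeClass",
    "MetRole",
    "ProbeDefinition",
    "Codeset",
    "RawCountMatrix",
    "read_codeset",
    "read_counts",
    "read_annotations",
    "write_calls",
    "read_calls",
    "write_rcc",
    "write_count_table",
    "CALL_COLUMNS",
]


class ProbeClass(str, enum.Enum):
    ENDOGENOUS = "endogenous"
    HOUSEKEEPING = "housekeeping"
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"


class MetRole(str, enum.Enum):
    MET_WT = "met_wt"
    MET_DEX14 = "met_dex14"
    NONE = "none"


@dataclass(frozen=True)
class ProbeDefinition:
    name: str
    probe_class: ProbeClass
    met_role: MetRole = MetRole.NONE


@dataclass(frozen=True)
class Codeset:
    """A validated probe panel definition.

    Exactly one probe must carry the MET wild-type role and exactly one the
    MET exon-14-skipped (junction) role; at least one housekeeping probe is
    required because the housekeeping geomean gates sample evaluability.
    """

    probes: tuple[ProbeDefinition, ...]

    def __post_init__(self) -> None:
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate probe name(s): {dupes}")
        n_wt = len(self.met_wt_probes)
        if n_wt != 1:
            raise ValueError(
                "missing MET wild-type probe" if n_wt == 0
                else f"expected exactly one MET wild-type probe, found {n_wt}"
            )
        n_d14 = len(self.met_dex14_probes)
        if n_d14 != 1:
            raise ValueError(
                "missing METdex14 probe" if n_d14 == 0
                else f"expected exactly one METdex14 probe, found {n_d14}"
            )
        if not self.housekeeping:
            raise ValueError("codeset must contain at least one housekeeping probe")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    def _by_class(self, cls: ProbeClass) -> list[str]:
        return [p.name for p in self.probes if p.probe_class is cls]

    @property
    def housekeeping(self) -> list[str]:
        return self._by_class(ProbeClass.HOUSEKEEPING)

    @property
    def positive_controls(self) -> list[str]:
        return self._by_class(ProbeClass.POSITIVE_CONTROL)

    @property
    def negative_controls(self) -> list[str]:
        return self._by_class(ProbeClass.NEGATIVE_CONTROL)

    @property
    def met_wt_probes(self) -> list[str]:
        return [p.name for p in self.probes if p.met_role is MetRole.MET_WT]

    @property
    def met_dex14_probes(self) -> list[str]:
        return [p.name for p in self.probes if p.met_role is MetRole.MET_DEX14]

    @property
    def met_wt(self) -> str:
        return self.met_wt_probes[0]

    @property
    def met_dex14(self) -> str:
        return self.met_dex14_probes[0]


@dataclass
class RawCountMatrix:
    """Non-negative integer counts, samples x probes, plus optional metadata.

    ``counts`` columns are aligned to the codeset probe order; ``sample_meta``
    (if given) is indexed by sample id and may carry a ``timepoint`` column,
    a ``driver`` column and orthogonal assay calls (positive/negative/unknown).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    f"non-integer count for sample {self.counts.index[bad[0]]!r}, "
                    f"probe {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count for sample {self.counts.index[bad[0]]!r}, "
                f"probe {self.counts.columns[bad[1]]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return len(self.counts)


def _read_delimited(path: str | Path, **kw) -> pd.DataFrame:
    """Read a CSV/TSV, sniffing the delimiter from the extension/content."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, **kw)


def read_codeset(path: str | Path) -> Codeset:
    """Read a codeset definition with columns ``probe``, ``class``, ``met_role``.

    ``met_role`` may be blank/absent for probes without a MET role.
    """
    df = _read_delimited(path, dtype=str)
    required = {"probe", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"codeset file must have columns {sorted(required)}; got {list(df.columns)}")
    probes = []
    for i, row in df.iterrows():
        try:
            cls = ProbeClass(row["class"].strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown probe class {row['class']!r} in codeset row {i} (probe {row['probe']!r})"
            ) from None
        role_raw = row.get("met_role")
        if role_raw is None or (isinstance(role_raw, float) and math.isnan(role_raw)) or str(role_raw).strip() in {"", "none"}:
            role = MetRole.NONE
        else:
            try:
                role = MetRole(str(role_raw).strip().lower())
            except ValueError:
                raise ValueError(
                    f"unknown met_role {role_raw!r} in codeset row {i} (probe {row['probe']!r})"
                ) from None
        probes.append(ProbeDefinition(row["probe"].strip(), cls, role))
    return Codeset(tuple(probes))


# mapping from RCC CodeClass tokens to probe classes, for cross-checking only
_RCC_CLASS = {
    "endogenous": ProbeClass.ENDOGENOUS,
    "housekeeping": ProbeClass.HOUSEKEEPING,
    "positive": ProbeClass.POSITIVE_CONTROL,
    "negative": ProbeClass.NEGATIVE_CONTROL,
}


def _parse_rcc(path: Path) -> tuple[str, dict[str, int]]:
    """Extract (sample id, probe->count) from one RCC file.

    Only the ``Sample_Attributes`` ID and the ``Code_Summary`` section are
    read; all instrument fields are ignored. Any RCC version exposing a
    ``Code_Summary`` section is accepted.
    """
    sample_id = path.stem
    counts: dict[str, int] = {}
    section = None
    header: list[str] | None = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("<") and line.endswith(">"):
            tag = line.strip("<>/").strip()
            section = None if line.startswith("</") else tag
            header = None
            continue
        fields = line.split(",")
        if section == "Sample_Attributes" and fields[0] == "ID" and len(fields) > 1 and fields[1]:
            sample_id = fields[1]
        elif section == "Code_Summary":
            if header is None:
                header = [f.strip() for f in fields]
                continue
            rec = dict(zip(header, fields))
            name = rec.get("Name", "").strip()
            if not name:
                continue
            try:
                count = int(rec["Count"])
            except (KeyError, ValueError):
                raise ValueError(
                    f"non-integer count {rec.get('Count')!r} for probe {name!r} in {path}"
                ) from None
            counts[name] = count
    if not counts:
        raise ValueError(f"no Code_Summary section with counts found in {path}")
    return sample_id, counts


def _align_to_codeset(rows: Mapping[str, Mapping[str, int]], codeset: Codeset) -> pd.DataFrame:
    """Align per-sample probe->count maps to the codeset probe order.

    Extra probes are dropped with a warning; a codeset probe missing from any
    sample is an error (a missing probe is not a zero).
    """
    wanted = set(codeset.names)
    out = {}
    for sid, cmap in rows.items():
        extra = sorted(set(cmap) - wanted)
        if extra:
            log.warning("sample %s: dropping %d probe(s) absent from codeset: %s", sid, len(extra), extra)
        missing = sorted(wanted - set(cmap))
        if missing:
            raise ValueError(f"sample {sid!r} is missing codeset probe(s): {missing}")
        out[sid] = [cmap[p] for p in codeset.names]
    df = pd.DataFrame.from_dict(out, orient="index", columns=codeset.names)
    df.index.name = "sample_id"
    return df


def read_counts(
    paths: str | Path | Sequence[str | Path],
    codeset: Codeset,
    dialect: str = "table",
    sample_meta: pd.DataFrame | None = None,
) -> RawCountMatrix:
    """Read raw probe counts in either the ``rcc`` or the ``table`` dialect.

    For ``rcc``, ``paths`` is one file per sample (or a directory of ``.RCC``
    files); for ``table``, a single delimited file whose first column is the
    sample id.
    """
    if dialect == "rcc":
        if isinstance(paths, (str, Path)) and Path(paths).is_dir():
            paths = sorted(Path(paths).glob("*.[Rr][Cc][Cc]"))
        elif isinstance(paths, (str, Path)):
            paths = [paths]
        rows: dict[str, dict[str, int]] = {}
        for p in paths:
            sid, cmap = _parse_rcc(Path(p))
            if sid in rows:
                raise ValueError(f"duplicate sample id {sid!r} (file {p})")
            rows[sid] = cmap
        counts = _align_to_codeset(rows, codeset)
    elif dialect == "table":
        if not isinstance(paths, (str, Path)):
            if len(paths) != 1:
                raise ValueError("table dialect expects a single file")
            paths = paths[0]
        df = _read_delimited(paths, index_col=0)
        df.index = df.index.astype(str)
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                sid = df.index[vals.isna().argmax()]
                raise ValueError(f"non-numeric count for sample {sid!r}, probe {col!r}")
        rows = {sid: row.to_dict() for sid, row in df.iterrows()}
        counts = _align_to_codeset(rows, codeset)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'rcc' or 'table'")
    return RawCountMatrix(counts=counts, sample_meta=sample_meta)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-sample categorical annotations keyed by sample id.

    Missing values become ``"unknown"``; unknown entries are excluded from
    concordance denominators downstream.
    """
    df = _read_delimited(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df.fillna("unknown").apply(lambda s: s.str.strip().str.lower())


CALL_COLUMNS = [
    "qc_pass",
    "hk_geomean",
    "log_met",
    "expression_tier",
    "dex14_log_ratio",
    "dex14_call",
]

TIERS = ["not_evaluable", "normal", "mod_elevated", "very_high"]
DEX14_CALLS = ["not_evaluable", "negative", "positive"]


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Check SampleCallTable invariants; returns the table unchanged."""
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table is missing column(s): {missing}")
    ne_tier = calls["expression_tier"] == "not_evaluable"
    ne_call = calls["dex14_call"] == "not_evaluable"
    fails = ~calls["qc_pass"].astype(bool)
    if not (ne_tier == fails).all() or not (ne_call == fails).all():
        raise ValueError("not_evaluable labels must coincide exactly with QC failure")
    bad_tier = set(calls["expression_tier"]) - set(TIERS)
    bad_call = set(calls["dex14_call"]) - set(DEX14_CALLS)
    if bad_tier or bad_call:
        raise ValueError(f"unknown labels: {bad_tier | bad_call}")
    undef_lr = calls["dex14_log_ratio"].isna()
    if (undef_lr & (calls["dex14_call"] == "positive")).any():
        raise ValueError("a sample without a defined log-ratio cannot be called positive")
    return calls


def write_calls(
    calls: pd.DataFrame,
    path: str | Path,
    cutoffs: Mapping[str, float] | None = None,
    summary_path: str | Path | None = None,
) -> Path:
    """Write the per-sample call table (TSV) plus a JSON cohort summary.

    Floats are written with full precision so that ``read_calls`` reproduces
    the table exactly. The summary records cohort composition and the cutoff
    values actually used.
    """
    if len(calls) == 0:
        raise ValueError("refusing to write an empty call table")
    validate_calls(calls)
    path = Path(path)
    out = calls[CALL_COLUMNS].copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")

    n = len(calls)
    n_fail = int((~calls["qc_pass"].astype(bool)).sum())
    tier_counts = calls["expression_tier"].value_counts().to_dict()
    summary = {
        "n_total": n,
        "n_not_evaluable": n_fail,
        "n_evaluable": n - n_fail,
        "tiers": {t: int(tier_counts.get(t, 0)) for t in TIERS},
        "n_dex14_positive": int((calls["dex14_call"] == "positive").sum()),
        "cutoffs": dict(cutoffs) if cutoffs else {},
    }
    spath = Path(summary_path) if summary_path else path.with_suffix(".summary.json")
    spath.write_text(json.dumps(summary, indent=2) + "\n")
    return path


def read_calls(path: str | Path) -> pd.DataFrame:
    """Re-read a call table written by :func:`write_calls`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return validate_calls(df)


def write_count_table(matrix: RawCountMatrix, path: str | Path) -> Path:
    """Write counts in the ``table`` dialect (TSV)."""
    path = Path(path)
    out = matrix.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    return path


def write_rcc(matrix: RawCountMatrix, codeset: Codeset, out_dir: str | Path) -> list[Path]:
    """Write one minimal RCC file per sample (Code_Summary + identity only)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_token = {
        ProbeClass.ENDOGENOUS: "Endogenous",
        ProbeClass.HOUSEKEEPING: "Housekeeping",
        ProbeClass.POSITIVE_CONTROL: "Positive",
        ProbeClass.NEGATIVE_CONTROL: "Negative",
    }
    written = []
    for sid in matrix.sample_ids:
        lines = [
            "<Header>", "FileVersion,1.7", "SoftwareVersion,metskip", "</Header>",
            "<Sample_Attributes>", f"ID,{sid}", "</Sample_Attributes>",
            "<Lane_Attributes>", "ID,1", "</Lane_Attributes>",
            "<Code_Summary>", "CodeClass,Name,Accession,Count",
        ]
        for probe in codeset.probes:
            c = int(matrix.counts.at[sid, probe.name])
            lines.append(f"{class_token[probe.probe_class]},{probe.name},NA,{c}")
        lines += ["</Code_Summary>", ""]
        p = out_dir / f"{sid}.RCC"
        p.write_text("\n".join(lines))
        written.append(p)
    return written
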
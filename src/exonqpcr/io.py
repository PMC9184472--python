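"""Reading and writing the pipeline's delimited-text formats.

Ct tables and manifests are plain CSV/TSV (dialect auto-detected from the
file extension, decimal point only). Censoring is canonicalized at read
time: the literal token ``ND`` and any numeric Ct above the configured
detection limit both become censored records, so downstream code never sees
a supra-limit number. On write, censored values are emitted as ``ND``.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .model import (
    CENSORED_TOKEN,
    CT_COLUMNS,
    KEY_COLUMNS,
    MANIFEST_COLUMNS,
    Config,
    validate_manifest,
)

_EVAL_FLOAT_COLUMNS = ("baseline_ct", "variability_score")


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_ct_table(path: str | Path, config: Config | None = None) -> pd.DataFrame:
    """Parse a long-format Ct table into the canonical record frame.

    The file must carry a header with the columns ``sample_id, donor_id,
    dose_gy, time_h, gene, assay_id, replicate, ct``. The ``ct`` field is a
    positive number or the non-detect token ``ND``; numeric values above
    ``config.censor_ct`` are censored on ingestion.
    """
    config = config or Config()
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    required = [c for c in CT_COLUMNS if c != "censored"]
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"Ct table {path} is missing column {col!r}")

    def _num(col: str, cast, check, what: str) -> list:
        out = []
        for i, text in enumerate(raw[col]):
            try:
                value = cast(text)
            except (TypeError, ValueError):
                raise ParseError(f"{col} value {text!r} is not {what}", line=i + 2)
            if not check(value):
                raise ParseError(f"{col} value {text!r} is not {what}", line=i + 2)
            out.append(value)
        return out

    dose = _num("dose_gy", float, lambda v: math.isfinite(v) and v >= 0,
                "a non-negative number")
    time = _num("time_h", float, lambda v: math.isfinite(v) and v > 0,
                "a positive number")
    replicate = _num("replicate", int, lambda v: v >= 1, "a positive integer")

    ct_vals, censored = [], []
    for i, text in enumerate(raw["ct"]):
        token = text.strip()
        if token.upper() == CENSORED_TOKEN:
            ct_vals.append(math.nan)
            censored.append(True)
            continue
        try:
            value = float(token)
        except ValueError:
            raise ParseError(
                f"ct value {text!r} is neither a number nor {CENSORED_TOKEN!r}",
                line=i + 2,
            )
        if not math.isfinite(value) or value <= 0:
            raise ParseError(f"ct value {text!r} must be finite and > 0", line=i + 2)
        if value > config.censor_ct:
            ct_vals.append(math.nan)
            censored.append(True)
        else:
            ct_vals.append(value)
            censored.append(False)

    records = pd.DataFrame(
        {
            "sample_id": raw["sample_id"].astype(str),
            "donor_id": raw["donor_id"].astype(str),
            "dose_gy": dose,
            "time_h": time,
            "gene": raw["gene"].astype(str),
            "assay_id": raw["assay_id"].astype(str),
            "replicate": replicate,
            "ct": ct_vals,
            "censored": censored,
        }
    )[list(CT_COLUMNS)]

    dup = records.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        key = records.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
        raise ValidationError(f"duplicate measurement key {key} in {path}")
    return records


def write_ct_table(records: pd.DataFrame, path: str | Path) -> None:
    """Serialize a record frame; censored Cts become the ``ND`` token."""
    out = records[[c for c in CT_COLUMNS if c != "censored"]].copy()
    out["ct"] = [
        CENSORED_TOKEN if (isinstance(v, float) and math.isnan(v)) else repr(float(v))
        for v in records["ct"]
    ]
    out.to_csv(path, sep=_sep_for(path), index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate an assay manifest (CSV/TSV). An empty file yields
    an empty manifest."""
    try:
        raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    raw.columns = [c.strip() for c in raw.columns]
    if raw.empty and not set(MANIFEST_COLUMNS) - set(raw.columns):
        return pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    missing = set(MANIFEST_COLUMNS) - set(raw.columns)
    if missing:
        raise FormatError(f"manifest {path} is missing columns {sorted(missing)}")
    try:
        exon_idx = raw["exon_region_index"].astype(int)
    except ValueError as exc:
        raise ParseError(f"exon_region_index in {path}: {exc}")
    best = raw["best_coverage"].str.strip().str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if best.isna().any():
        bad = raw.loc[best.isna().idxmax(), "best_coverage"]
        raise ParseError(f"best_coverage value {bad!r} is not boolean")
    manifest = pd.DataFrame(
        {
            "assay_id": raw["assay_id"].astype(str),
            "gene": raw["gene"].astype(str),
            "exon_region_index": exon_idx,
            "design_suffix": raw["design_suffix"].str.strip(),
            "best_coverage": best.astype(bool),
        }
    )
    return validate_manifest(manifest)


def default_manifest() -> pd.DataFrame:
    """The packaged 41-assay panel (16 FDXR, 11 DDB2, 5 WNT3, 9 POU2AF1).

    Assay ids not disclosed by the vendor catalogue are synthetic
    placeholders (``PLACEHOLDER_<gene>_<k>``) occupying otherwise uncovered
    exon-region positions, so per-gene panel sizes are preserved.
    """
    with resources.as_file(
        resources.files("exonqpcr.data").joinpath("manifest.csv")
    ) as p:
        return load_manifest(p)


# -- evaluation output ------------------------------------------------


def write_evaluation_table(evaluations: pd.DataFrame, path: str | Path) -> None:
    """Write per-assay evaluation rows as delimited text.

    Rows are ordered by gene (alphabetical) then exon-region index
    ascending, mirroring the 5'->3' panel layout. Numeric values are
    written at full precision so that a read-back reproduces them
    bit-identically.
    """
    out = evaluations.sort_values(["gene", "exon_region_index"]).reset_index(drop=True)
    out.to_csv(
        path, sep=_sep_for(path), index=False, float_format=lambda v: repr(float(v))
    )


def read_evaluation_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_evaluation_table`."""
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    for col in ("rank",):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return df


def write_summary_json(evaluations: pd.DataFrame, path: str | Path) -> None:
    """Per-gene JSON summary: selected assays (best first) and the panel."""
    summary = {}
    for gene, sub in evaluations.groupby("gene"):
        sel = sub[sub["selected"]].sort_values("rank")
        summary[gene] = {
            "n_assays": int(len(sub)),
            "n_detectable": int(sub["detectable"].sum()),
            "direction": sub["direction"].iloc[0],
            "selected": sel["assay_id"].tolist(),
            "best_assay": sel["assay_id"].iloc[0] if len(sel) else None,
        }
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
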
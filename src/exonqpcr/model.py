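"""Domain model: Ct records, assay annotations, analysis configuration.

In-memory containers are plain :class:`pandas.DataFrame` objects with fixed
column schemas (declared below); the dataclasses in this module describe and
validate single rows or whole-run settings. A censored measurement (raw Ct
above the detection limit) is stored as ``ct = NaN`` with ``censored = True``
— supra-limit Ct values are never kept as numbers, so downstream arithmetic
can simply skip NaNs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ValidationError

#: columns of a Ct record table, in canonical order
CT_COLUMNS = (
    "sample_id",
    "donor_id",
    "dose_gy",
    "time_h",
    "gene",
    "assay_id",
    "replicate",
    "ct",
    "censored",
)

#: columns identifying one well measurement
KEY_COLUMNS = ("donor_id", "dose_gy", "time_h", "gene", "assay_id", "replicate")

#: columns of an assay manifest
MANIFEST_COLUMNS = (
    "assay_id",
    "gene",
    "exon_region_index",
    "design_suffix",
    "best_coverage",
)

DESIGN_SUFFIXES = ("m1", "g1", "custom")

#: file token for a censored (non-detect) Ct value
CENSORED_TOKEN = "ND"

UP = "up"
DOWN = "down"

#: dose-dependency verdicts
FULL = "full"
HIGH_DOSE_ONLY = "high_dose_only"
NONE = "none"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class CtRecord:
    """One raw well measurement. ``ct is None`` means censored (beyond the
    detection limit)."""

    sample_id: str
    donor_id: str
    dose_gy: float
    time_h: float
    gene: str
    assay_id: str
    replicate: int
    ct: float | None

    def __post_init__(self):
        if self.dose_gy < 0:
            raise ValidationError(f"dose must be non-negative, got {self.dose_gy}")
        if self.time_h <= 0:
            raise ValidationError(f"time must be positive, got {self.time_h}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.ct is not None and (not math.isfinite(self.ct) or self.ct <= 0):
            raise ValidationError(f"ct must be finite and > 0, got {self.ct}")

    @property
    def censored(self) -> bool:
        return self.ct is None


@dataclass(frozen=True)
class AssayAnnotation:
    """A TaqMan assay's gene, 5'->3' exon-region position and design info."""

    assay_id: str
    gene: str
    exon_region_index: int
    design_suffix: str
    best_coverage: bool = False

    def __post_init__(self):
        if self.exon_region_index < 1:
            raise ValidationError(
                f"exon_region_index must be >= 1, got {self.exon_region_index}"
            )
        if self.design_suffix not in DESIGN_SUFFIXES:
            raise ValidationError(
                f"design_suffix must be one of {DESIGN_SUFFIXES}, "
                f"got {self.design_suffix!r}"
            )


@dataclass(frozen=True)
class Config:
    """All analysis thresholds and conventions in one place.

    Parameters
    ----------
    housekeeper_assay_id
        Assay id of the normalization reference (diluted 18S rRNA).
    censor_ct
        Detection limit; raw Ct above this carries no quantitative
        information and is treated as a non-detect.
    baseline_max_up, baseline_max_down
        Strict upper bounds on the mean sham (0 Gy) raw Ct for an assay of an
        up- / down-regulated gene to have enough dynamic range.
    dose_margin
        Minimum fold-change increase (absolute FC units) required between
        consecutive dose categories of an up-regulated gene.
    persistency_margin
        Maximum allowed FC difference (absolute units) between the two
        post-exposure time points.
    down_ratio
        Minimum multiplicative FC *decrease* between consecutive dose
        categories of a down-regulated gene (the additive margin has no
        meaning on the (0, 1] scale).
    reference_scope
        ``"cohort"``: the reference ΔCt is the mean sham ΔCt across donors at
        the same time point, so per-donor sham fold changes carry
        inter-individual scatter. ``"donor"``: each donor is referenced to
        their own sham sample (sham FCs are then produced per replicate).
    direction_override
        gene -> ``"up"``/``"down"``; takes precedence over direction
        inference from the data.
    variability_include_sham, variability_per_time
        Which (dose, time) cells enter the summed-SD variability score.
    cv_pool_times
        ``"average"``: average each donor's FC over time points before
        computing the per-dose CV; ``"observations"``: treat (donor, time)
        pairs as separate observations.
    gg_correction
        Apply the Greenhouse–Geisser sphericity correction in the
        repeated-measures ANOVA.
    """

    housekeeper_assay_id: str = "Hs03003631_g1"
    censor_ct: float = 40.0
    baseline_max_up: float = 33.0
    baseline_max_down: float = 30.0
    dose_margin: float = 2.0
    persistency_margin: float = 1.0
    down_ratio: float = 2.0
    doses: tuple[float, ...] = (0.0, 0.5, 4.0)
    reference_dose: float = 0.0
    tertile_labels: tuple[str, str, str] = ("upper", "middle", "lower")
    reference_scope: str = "cohort"
    direction_override: Mapping[str, str] = field(default_factory=dict)
    variability_include_sham: bool = True
    variability_per_time: bool = True
    cv_pool_times: str = "average"
    gg_correction: bool = False

    def __post_init__(self):
        if not (self.baseline_max_down <= self.baseline_max_up < self.censor_ct):
            raise ValidationError(
                "require baseline_max_down <= baseline_max_up < censor_ct, got "
                f"{self.baseline_max_down}, {self.baseline_max_up}, {self.censor_ct}"
            )
        if self.dose_margin <= 0:
            raise ValidationError("dose_margin must be > 0")
        if self.persistency_margin <= 0:
            raise ValidationError("persistency_margin must be > 0")
        if self.down_ratio <= 1:
            raise ValidationError("down_ratio must be > 1")
        if self.reference_dose not in self.doses:
            raise ValidationError(
                f"reference_dose {self.reference_dose} not in doses {self.doses}"
            )
        if len(self.doses) != len(set(self.doses)):
            raise ValidationError("doses must be distinct")
        if self.reference_scope not in ("cohort", "donor"):
            raise ValidationError("reference_scope must be 'cohort' or 'donor'")
        if self.cv_pool_times not in ("average", "observations"):
            raise ValidationError("cv_pool_times must be 'average' or 'observations'")
        for gene, direction in self.direction_override.items():
            if direction not in (UP, DOWN):
                raise ValidationError(
                    f"direction override for {gene} must be 'up' or 'down'"
                )
        if len(self.tertile_labels) != 3:
            raise ValidationError("tertile_labels must have three entries")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["doses"] = list(self.doses)
        d["tertile_labels"] = list(self.tertile_labels)
        d["direction_override"] = dict(self.direction_override)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Config":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("doses", "tertile_labels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load a YAML or JSON config file (YAML is a superset of JSON)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable content hash; changes iff the configuration changes."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class Dataset:
    """A validated bundle of Ct records, assay manifest and configuration."""

    records: pd.DataFrame
    manifest: pd.DataFrame
    config: Config = field(default_factory=Config)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        rec, man, cfg = self.records, self.manifest, self.config
        missing = set(CT_COLUMNS) - set(rec.columns)
        if missing:
            raise ValidationError(f"record table lacks columns {sorted(missing)}")
        missing = set(MANIFEST_COLUMNS) - set(man.columns)
        if missing:
            raise ValidationError(f"manifest lacks columns {sorted(missing)}")

        dup = rec.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            key = rec.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
            raise ValidationError(f"duplicate measurement key {key}")

        targets = rec[rec["assay_id"] != cfg.housekeeper_assay_id]
        unknown = set(targets["assay_id"]) - set(man["assay_id"])
        if unknown:
            raise ValidationError(
                f"assays missing from manifest: {sorted(unknown)}"
            )

        # every target group must include the reference dose
        doses_per_group = targets.groupby(
            ["donor_id", "time_h", "gene", "assay_id"], sort=False
        )["dose_gy"].agg(lambda s: cfg.reference_dose in set(s))
        if not doses_per_group.all():
            bad = doses_per_group[~doses_per_group].index[0]
            raise ValidationError(
                f"group {bad} has no reference-dose ({cfg.reference_dose} Gy) sample"
            )

        # housekeeper must be measured in every (donor, dose, time)
        hk = rec[rec["assay_id"] == cfg.housekeeper_assay_id]
        sample_groups = set(map(tuple, targets[["donor_id", "dose_gy", "time_h"]].values))
        hk_groups = set(map(tuple, hk[["donor_id", "dose_gy", "time_h"]].values))
        missing_hk = sample_groups - hk_groups
        if missing_hk:
            raise ValidationError(
                f"housekeeper records missing for groups {sorted(missing_hk)[:3]}"
            )

    @property
    def target_records(self) -> pd.DataFrame:
        return self.records[
            self.records["assay_id"] != self.config.housekeeper_assay_id
        ]

    @property
    def housekeeper_records(self) -> pd.DataFrame:
        return self.records[
            self.records["assay_id"] == self.config.housekeeper_assay_id
        ]


def records_frame(records: Sequence[CtRecord]) -> pd.DataFrame:
    """Build a canonical record table from :class:`CtRecord` objects."""
    rows = [
        (
            r.sample_id,
            r.donor_id,
            float(r.dose_gy),
            float(r.time_h),
            r.gene,
            r.assay_id,
            int(r.replicate),
            math.nan if r.ct is None else float(r.ct),
            r.censored,
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(CT_COLUMNS))


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants; returns the frame sorted by gene and
    5'->3' exon-region position."""
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValidationError(f"manifest lacks columns {sorted(missing)}")
    dup = manifest["assay_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate assay id {manifest.loc[dup.idxmax(), 'assay_id']!r}"
        )
    for gene, sub in manifest.groupby("gene"):
        idx = sorted(sub["exon_region_index"])
        if idx != list(range(1, len(idx) + 1)):
            raise ValidationError(
                f"exon_region_index for {gene} must be contiguous from 1, got {idx}"
            )
        if int(sub["best_coverage"].sum()) > 1:
            raise ValidationError(f"gene {gene} has more than one best-coverage assay")
    bad = ~manifest["design_suffix"].isin(DESIGN_SUFFIXES)
    if bad.any():
        raise ValidationError(
            f"invalid design_suffix {manifest.loc[bad.idxmax(), 'design_suffix']!r}"
        )
    return manifest.sort_values(["gene", "exon_region_index"]).reset_index(drop=True)
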
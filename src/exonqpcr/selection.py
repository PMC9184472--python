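"""The four-criterion TaqMan assay evaluation and final selection.

An assay of a radiation-responsive gene is judged on:

1. **Baseline** — mean raw sham (0 Gy) Ct strictly below 33 for genes that
   respond by up-regulation, below 30 for down-regulated genes (a
   down-shift pushes Ct further up, so more headroom below the detection
   limit is needed).
2. **Dose dependency** — the donor- and time-averaged fold change must
   separate the dose categories. Up-regulated genes need at least
   ``dose_margin`` (2) additional FC units per consecutive category (e.g. a
   tenfold response at 0.5 Gy demands ≥ 12-fold at 4 Gy); down-regulated
   genes need a ≥ ``down_ratio`` (2)-fold FC *decrease* per category, since
   an additive margin cannot be met on the (0, 1] scale. Passing only the
   sham-to-top-dose comparison gives the intermediate ``high_dose_only``
   verdict.
3. **Time persistency** — the per-dose FC must agree within
   ``persistency_margin`` (±1) unit between 24 h and 48 h (10.5-fold at
   24 h admits 9.5–11.5 at 48 h), at every exposed dose.
4. **Inter-individual variability** — the sum over dose(-time) cells of the
   across-donor FC standard deviation; assays are ranked per gene (rank 1 =
   least variable) and binned into tertiles.

Assays whose every well is beyond the detection limit are flagged
non-detectable and excluded from ranking and selection. Selection is the
conjunction of criteria 1–3 with detectability; the variability rank breaks
ties among the survivors.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from . import foldchange
from .errors import DataError
from .model import (
    DOWN,
    FULL,
    HIGH_DOSE_ONLY,
    NONE,
    UNDETERMINED,
    UP,
    Config,
    Dataset,
)

log = logging.getLogger(__name__)

EVALUATION_COLUMNS = (
    "gene",
    "assay_id",
    "exon_region_index",
    "best_coverage",
    "direction",
    "detectable",
    "baseline_ct",
    "baseline_pass",
    "dose_dependency",
    "persistency_pass",
    "variability_score",
    "rank",
    "tertile",
    "selected",
    "reason",
)


def assess_detectability(records: pd.DataFrame) -> pd.Series:
    """Per-assay detectability: False iff every well is censored."""
    return records.groupby("assay_id")["censored"].agg(lambda s: not s.all())


def infer_direction(donor_fc: pd.DataFrame, gene: str, config: Config) -> str:
    """Direction of a gene's radiation response.

    A configured override wins; otherwise the median fold change at the
    highest dose across detectable assays, donors and times decides
    (median > 1 -> up). An exact median of 1 classifies down — the stricter
    baseline threshold then applies, the conservative choice.
    """
    override = config.direction_override.get(gene)
    if override is not None:
        return override
    top = max(config.doses)
    fcs = donor_fc[(donor_fc["gene"] == gene) & (donor_fc["dose_gy"] == top)]["fc"]
    if fcs.empty:
        raise DataError(f"no usable fold changes at {top} Gy for gene {gene}")
    return UP if float(fcs.median()) > 1.0 else DOWN


def baseline_criterion(
    baseline_ct: float, direction: str, config: Config | None = None
) -> bool:
    """Strict raw-Ct baseline threshold; a missing baseline fails."""
    config = config or Config()
    if baseline_ct is None or math.isnan(baseline_ct):
        return False
    limit = config.baseline_max_up if direction == UP else config.baseline_max_down
    return baseline_ct < limit


def dose_dependency_criterion(
    mean_fc: Mapping[float, float], direction: str, config: Config | None = None
) -> str:
    """Classify the dose response as ``full``, ``high_dose_only`` or ``none``.

    ``mean_fc`` maps each dose category to its donor- and time-averaged fold
    change (the reference dose is 1 by convention). Missing dose levels give
    ``undetermined``.
    """
    config = config or Config()
    doses = sorted(config.doses)
    if any(d not in mean_fc or math.isnan(mean_fc[d]) for d in doses):
        return UNDETERMINED
    fcs = [mean_fc[d] for d in doses]
    if direction == UP:
        step_ok = [b >= a + config.dose_margin for a, b in zip(fcs, fcs[1:])]
        top_ok = fcs[-1] >= fcs[0] + config.dose_margin
    else:
        step_ok = [a / b >= config.down_ratio for a, b in zip(fcs, fcs[1:])]
        top_ok = fcs[0] / fcs[-1] >= config.down_ratio
    if all(step_ok):
        return FULL
    if top_ok:
        return HIGH_DOSE_ONLY
    return NONE


def persistency_criterion(
    fc_24: float, fc_48: float, config: Config | None = None
) -> bool:
    """Fold-change stability between the two time points, inclusive bounds."""
    config = config or Config()
    if math.isnan(fc_24) or math.isnan(fc_48):
        return False
    return abs(fc_24 - fc_48) <= config.persistency_margin


def variability_score(
    fc_per_donor: pd.DataFrame, config: Config | None = None
) -> float:
    """Sum over dose(-time) cells of the across-donor sample SD of the FC.

    ``fc_per_donor`` needs columns ``donor_id, dose_gy, time_h, fc`` for one
    assay. Cells with fewer than two donors are skipped (and logged). The
    sham dose and the per-time split are configurable.
    """
    config = config or Config()
    df = fc_per_donor
    if not config.variability_include_sham:
        df = df[df["dose_gy"] != config.reference_dose]
    if config.variability_per_time:
        cells = df.groupby(["dose_gy", "time_h"])["fc"]
    else:
        per_donor = df.groupby(["dose_gy", "donor_id"], as_index=False)["fc"].mean()
        cells = per_donor.groupby("dose_gy")["fc"]
    total = 0.0
    for key, values in cells:
        if len(values) < 2:
            log.info("variability cell %s has < 2 donors; skipped", (key,))
            continue
        total += float(values.std(ddof=1))
    return total


def rank_and_tertile(
    scores: Mapping[str, float], labels: tuple[str, str, str] = ("upper", "middle", "lower")
) -> dict[str, tuple[int, str]]:
    """Rank assays by variability score (rank 1 = least variable) and bin
    into tertiles: the first ceil(n/3) ranks form the upper third, the last
    floor(n/3) the lower third, the remainder the middle. Ties are broken by
    assay id, lexicographically."""
    ordered = sorted(scores, key=lambda a: (scores[a], a))
    n = len(ordered)
    n_upper = math.ceil(n / 3)
    n_lower = n // 3
    out = {}
    for i, assay in enumerate(ordered):
        rank = i + 1
        if rank <= n_upper:
            tertile = labels[0]
        elif rank > n - n_lower:
            tertile = labels[2]
        else:
            tertile = labels[1]
        out[assay] = (rank, tertile)
    return out


def evaluate_assays(
    dataset: Dataset, fc_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Run the full evaluation over a dataset; one row per manifest assay.

    Returns a frame with the columns in :data:`EVALUATION_COLUMNS` plus one
    ``fc_<dose>gy_<time>h`` column per exposed (dose, time) cell and one
    ``fc_<dose>gy`` time-averaged column per dose.
    """
    cfg = dataset.config
    records = dataset.target_records
    if fc_table is None:
        fc_table = foldchange.compute_fc_table(dataset)
    donor_fc = foldchange.donor_fc_table(fc_table, cfg)
    mean_fc = foldchange.mean_fc_by_dose_time(donor_fc, cfg)

    detectable = assess_detectability(records)
    sham = records[(records["dose_gy"] == cfg.reference_dose) & ~records["censored"]]
    baselines = sham.groupby("assay_id")["ct"].mean()

    exposed_doses = sorted(d for d in cfg.doses if d != cfg.reference_dose)
    times = sorted(records["time_h"].unique())

    rows = []
    manifest = dataset.manifest.sort_values(["gene", "exon_region_index"])
    directions = {
        gene: infer_direction(donor_fc, gene, cfg)
        for gene in manifest["gene"].unique()
    }

    for _, assay in manifest.iterrows():
        aid, gene = assay["assay_id"], assay["gene"]
        direction = directions[gene]
        det = bool(detectable.get(aid, False))
        baseline = float(baselines.get(aid, math.nan))
        reasons = []

        row = {
            "gene": gene,
            "assay_id": aid,
            "exon_region_index": int(assay["exon_region_index"]),
            "best_coverage": bool(assay["best_coverage"]),
            "direction": direction,
            "detectable": det,
            "baseline_ct": baseline,
        }

        cell_fc = mean_fc[mean_fc["assay_id"] == aid]
        dose_means: dict[float, float] = {cfg.reference_dose: 1.0}
        for dose in exposed_doses:
            per_time = []
            for t in times:
                sub = cell_fc[(cell_fc["dose_gy"] == dose) & (cell_fc["time_h"] == t)]
                value = float(sub["fc"].iloc[0]) if len(sub) else math.nan
                row[f"fc_{dose:g}gy_{t:g}h"] = value
                per_time.append(value)
            dose_means[dose] = float(np.mean(per_time))  # NaN if any cell missing
            row[f"fc_{dose:g}gy"] = dose_means[dose]

        if not det:
            row.update(
                baseline_pass=False,
                dose_dependency=UNDETERMINED,
                persistency_pass=False,
                variability_score=math.nan,
                rank=pd.NA,
                tertile=pd.NA,
                selected=False,
                reason="not detectable",
            )
            rows.append(row)
            continue

        b_pass = baseline_criterion(baseline, direction, cfg)
        if not b_pass:
            reasons.append("baseline")

        dd = dose_dependency_criterion(dose_means, direction, cfg)
        if dd in (NONE, UNDETERMINED):
            reasons.append(f"dose dependency ({dd})")

        persistency = True
        for dose in exposed_doses:
            fcs = [row.get(f"fc_{dose:g}gy_{t:g}h", math.nan) for t in times]
            if len(fcs) < 2 or any(math.isnan(v) for v in fcs):
                persistency = False
                break
            if max(fcs) - min(fcs) > cfg.persistency_margin:
                persistency = False
        if not persistency:
            reasons.append("time persistency")

        per_donor = donor_fc[donor_fc["assay_id"] == aid][
            ["donor_id", "dose_gy", "time_h", "fc"]
        ]
        score = variability_score(per_donor, cfg)

        row.update(
            baseline_pass=b_pass,
            dose_dependency=dd,
            persistency_pass=persistency,
            variability_score=score,
            rank=pd.NA,  # filled per gene below
            tertile=pd.NA,
            selected=b_pass and dd in (FULL, HIGH_DOSE_ONLY) and persistency,
            reason="; ".join(reasons),
        )
        rows.append(row)

    evaluations = pd.DataFrame(rows)
    for gene, sub in evaluations.groupby("gene"):
        det_sub = sub[sub["detectable"]]
        ranks = rank_and_tertile(
            dict(zip(det_sub["assay_id"], det_sub["variability_score"])),
            cfg.tertile_labels,
        )
        for aid, (rank, tertile) in ranks.items():
            idx = evaluations.index[evaluations["assay_id"] == aid]
            evaluations.loc[idx, "rank"] = rank
            evaluations.loc[idx, "tertile"] = tertile
    evaluations["rank"] = evaluations["rank"].astype("Int64")

    for _, row in evaluations[~evaluations["selected"]].iterrows():
        log.info(
            "assay %s (%s) excluded: %s",
            row["assay_id"], row["gene"], row["reason"] or "criteria failed",
        )
    return evaluations


def select_assays(evaluations: pd.DataFrame) -> dict[str, list[str]]:
    """Per-gene list of selected assay ids, best (lowest variability rank)
    first."""
    out: dict[str, list[str]] = {}
    for gene, sub in evaluations.groupby("gene"):
        sel = sub[sub["selected"]].sort_values("rank")
        out[gene] = sel["assay_id"].tolist()
    return out
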
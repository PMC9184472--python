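"""Replicate collapsing, 18S normalization and ΔΔCt fold changes.

The quantification chain is the classic comparative-Ct method:

    ΔCt   = mean target Ct − mean housekeeper Ct          (per sample)
    ΔΔCt  = ΔCt(sample) − ΔCt(reference)                  (same time point)
    FC    = 2^(−ΔΔCt)

assuming amplification efficiency 2 for every assay. The reference ΔCt is
taken from the unexposed (sham) sample at the same time point. Two
conventions for "the unexposed sample" are supported (``Config.reference_scope``):

``cohort`` (default)
    One reference per (time, gene, assay): the mean sham ΔCt across donors.
    Every donor then gets a fold change at every dose, including sham, and
    the sham fold changes express each donor's deviation from the cohort
    baseline — the quantity the inter-individual variability analyses need.

``donor``
    Each donor is referenced to their own sham ΔCt (replicate mean). Sham
    fold changes would then be identically 1, so the sham scatter is instead
    produced per replicate against the replicate-mean ΔCt, and a mean-based
    sham row with FC exactly 1 is emitted alongside.

Groups whose target measurement is entirely censored have no ΔCt and are
dropped (and logged); a censored housekeeper well is a hard data error.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .model import Config, Dataset

log = logging.getLogger(__name__)

#: columns of the fold-change table
FC_COLUMNS = (
    "donor_id",
    "dose_gy",
    "time_h",
    "gene",
    "assay_id",
    "replicate",
    "ddct",
    "fc",
    "n_censored",
)


def collapse_replicates(cts: Iterable[float]) -> tuple[float, int]:
    """Mean of the non-censored replicate Cts.

    Returns ``(mean, n_censored)``; the mean is NaN when every replicate is
    censored. Raises :class:`UsageError` on an empty collection.
    """
    arr = np.asarray(list(cts), dtype=float)
    if arr.size == 0:
        raise UsageError("collapse_replicates needs at least one value")
    n_censored = int(np.isnan(arr).sum())
    if n_censored == arr.size:
        return math.nan, n_censored
    return float(np.nanmean(arr)), n_censored


def normalize(target_ct: float, housekeeper_ct: float) -> float:
    """ΔCt = target − housekeeper. A missing (NaN) target propagates; a
    missing housekeeper is a data error, the housekeeper is required
    everywhere."""
    if housekeeper_ct is None or math.isnan(housekeeper_ct):
        raise DataError("housekeeper Ct is missing; normalization impossible")
    if target_ct is None or math.isnan(target_ct):
        return math.nan
    return target_ct - housekeeper_ct


def delta_delta_ct(sample_dct: float, reference_dct: float) -> float:
    """ΔΔCt = sample ΔCt − reference ΔCt (same time point)."""
    if reference_dct is None or math.isnan(reference_dct):
        raise DataError("reference ΔCt is missing")
    return sample_dct - reference_dct


def fold_change(ddct: float) -> float:
    """FC = 2^(−ΔΔCt); strictly decreasing in ΔΔCt, FC(0) = 1."""
    return 2.0 ** (-ddct)


def _group_means(dataset: Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group replicate-collapsed target and housekeeper Ct means."""
    cfg = dataset.config
    hk = dataset.housekeeper_records
    if hk.empty:
        raise DataError(
            f"no records for housekeeper assay {cfg.housekeeper_assay_id!r}"
        )
    if hk["censored"].any():
        bad = hk.loc[hk["censored"].idxmax(), ["donor_id", "dose_gy", "time_h"]]
        raise DataError(
            f"censored housekeeper well in group {tuple(bad)}; "
            "the housekeeper must be detectable everywhere"
        )
    hk_means = (
        hk.groupby(["donor_id", "dose_gy", "time_h"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "hk_ct"})
    )
    tgt = dataset.target_records
    tgt_means = tgt.groupby(
        ["donor_id", "dose_gy", "time_h", "gene", "assay_id"], as_index=False
    ).agg(ct_mean=("ct", "mean"), n_censored=("censored", "sum"))
    tgt_means["n_censored"] = tgt_means["n_censored"].astype(int)
    return tgt_means, hk_means


def compute_fc_table(dataset: Dataset) -> pd.DataFrame:
    """Fold-change table for every (donor, dose, time, assay) group with a
    measurable ΔCt. See the module docstring for the two reference scopes.

    The ``replicate`` column is NaN for replicate-mean based rows; in
    ``donor`` scope the sham rows additionally appear once per detected
    replicate.
    """
    cfg = dataset.config
    tgt_means, hk_means = _group_means(dataset)

    dct = tgt_means.merge(hk_means, on=["donor_id", "dose_gy", "time_h"], how="left")
    if dct["hk_ct"].isna().any():
        bad = dct.loc[dct["hk_ct"].isna().idxmax(), ["donor_id", "dose_gy", "time_h"]]
        raise DataError(f"no housekeeper measurement for group {tuple(bad)}")
    dct["dct"] = dct["ct_mean"] - dct["hk_ct"]

    missing = dct["dct"].isna()
    for _, row in dct[missing].iterrows():
        log.info(
            "dropping fully censored group donor=%s dose=%.3g time=%.3g assay=%s",
            row["donor_id"], row["dose_gy"], row["time_h"], row["assay_id"],
        )
    dct = dct[~missing].copy()

    ref = dct[dct["dose_gy"] == cfg.reference_dose]
    if cfg.reference_scope == "cohort":
        ref_dct = (
            ref.groupby(["time_h", "gene", "assay_id"], as_index=False)["dct"]
            .mean()
            .rename(columns={"dct": "ref_dct"})
        )
        merged = dct.merge(ref_dct, on=["time_h", "gene", "assay_id"], how="left")
    else:
        ref_dct = ref.rename(columns={"dct": "ref_dct"})[
            ["donor_id", "time_h", "gene", "assay_id", "ref_dct"]
        ]
        merged = dct.merge(
            ref_dct, on=["donor_id", "time_h", "gene", "assay_id"], how="left"
        )

    no_ref = merged["ref_dct"].isna()
    for _, row in merged[no_ref].iterrows():
        log.info(
            "no usable reference for donor=%s dose=%.3g time=%.3g assay=%s; dropped",
            row["donor_id"], row["dose_gy"], row["time_h"], row["assay_id"],
        )
    merged = merged[~no_ref].copy()

    merged["ddct"] = merged["dct"] - merged["ref_dct"]
    merged["fc"] = 2.0 ** (-merged["ddct"])
    merged["replicate"] = math.nan

    if cfg.reference_scope == "donor":
        # per-replicate sham fold changes against the replicate-mean ΔCt,
        # so sham groups exhibit within-donor scatter
        sham_wells = dataset.target_records
        sham_wells = sham_wells[
            (sham_wells["dose_gy"] == cfg.reference_dose) & ~sham_wells["censored"]
        ].copy()
        sham_wells = sham_wells.merge(
            hk_means, on=["donor_id", "dose_gy", "time_h"], how="left"
        )
        sham_wells = sham_wells.merge(
            ref_dct, on=["donor_id", "time_h", "gene", "assay_id"], how="inner"
        )
        sham_wells["ddct"] = (sham_wells["ct"] - sham_wells["hk_ct"]) - sham_wells[
            "ref_dct"
        ]
        sham_wells["fc"] = 2.0 ** (-sham_wells["ddct"])
        sham_wells["n_censored"] = 0
        merged = pd.concat(
            [merged, sham_wells[list(FC_COLUMNS)]], ignore_index=True
        )

    out = merged[list(FC_COLUMNS)].sort_values(
        ["gene", "assay_id", "dose_gy", "time_h", "donor_id"]
    )
    return out.reset_index(drop=True)


def donor_fc_table(fc_table: pd.DataFrame, config: Config) -> pd.DataFrame:
    """One fold change per (donor, dose, time, gene, assay).

    In ``cohort`` scope the fold-change table already has that shape. In
    ``donor`` scope the sham per-replicate rows are averaged per donor
    (replicate-mean based sham rows, which are exactly 1, are excluded so
    the sham scatter survives).
    """
    if config.reference_scope == "cohort":
        df = fc_table
    else:
        sham = fc_table["dose_gy"] == config.reference_dose
        rep_rows = fc_table["replicate"].notna()
        keep = fc_table[~sham | rep_rows]
        df = (
            keep.groupby(
                ["donor_id", "dose_gy", "time_h", "gene", "assay_id"],
                as_index=False,
            )
            .agg(ddct=("ddct", "mean"), fc=("fc", "mean"),
                 n_censored=("n_censored", "max"))
        )
    return df[
        ["donor_id", "dose_gy", "time_h", "gene", "assay_id", "ddct", "fc",
         "n_censored"]
    ].reset_index(drop=True)


def mean_fc_by_dose_time(donor_fc: pd.DataFrame, config: Config) -> pd.DataFrame:
    """Donor-averaged fold change per (gene, assay, dose, time).

    The reference dose is reported as exactly 1 (fold changes are expressed
    relative to sham by definition), regardless of reference scope.
    """
    out = donor_fc.groupby(
        ["gene", "assay_id", "dose_gy", "time_h"], as_index=False
    )["fc"].mean()
    out.loc[out["dose_gy"] == config.reference_dose, "fc"] = 1.0
    return out


def write_fc_table(fc_table: pd.DataFrame, path) -> None:
    """Optional TSV export of the fold-change table."""
    fc_table.to_csv(path, sep="\t", index=False)
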
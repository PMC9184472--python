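"""Coefficient-of-variation analysis of fold changes across doses.

For each gene, the inter-individual spread of the fold change is summarised
per assay and dose category as the coefficient of variation across donors
(CV = SD × 100 / mean, percent). Whether irradiation inflates that spread
is tested with a one-way repeated-measures ANOVA — each assay is a subject
measured at every dose level — followed by Tukey's studentized-range test on
the dose means, using the within-subject residual mean square as the error
term. The effect size is reported as the ratio of the median CV at each
exposed dose to the median sham CV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import foldchange
from .errors import DataError
from .model import Config, Dataset

log = logging.getLogger(__name__)


def cv_of_fold_changes(fcs: Iterable[float]) -> float:
    """Percent coefficient of variation: sample SD (n−1) × 100 / mean.

    Needs at least two values; a zero mean leaves the CV undefined (NaN).
    """
    arr = np.asarray(list(fcs), dtype=float)
    if arr.size < 2:
        raise DataError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        log.info("CV undefined (zero mean); recorded as missing")
        return math.nan
    return float(arr.std(ddof=1) * 100.0 / mean)


def cv_table(donor_fc: pd.DataFrame, config: Config | None = None) -> pd.DataFrame:
    """Per (gene, assay, dose) CV of donor fold changes.

    By default each donor's FC is first averaged over the two time points
    (``cv_pool_times="average"``); with ``"observations"`` every
    (donor, time) pair counts as one observation.
    """
    config = config or Config()
    if config.cv_pool_times == "average":
        obs = donor_fc.groupby(
            ["gene", "assay_id", "dose_gy", "donor_id"], as_index=False
        )["fc"].mean()
    else:
        obs = donor_fc
    rows = []
    for (gene, aid, dose), sub in obs.groupby(["gene", "assay_id", "dose_gy"]):
        if len(sub) < 2:
            log.info("CV cell (%s, %s, %.3g Gy) has < 2 observations; skipped",
                     gene, aid, dose)
            continue
        rows.append(
            {
                "gene": gene,
                "assay_id": aid,
                "dose_gy": float(dose),
                "cv": cv_of_fold_changes(sub["fc"]),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "assay_id", "dose_gy", "cv"])


@dataclass
class RmAnovaResult:
    f: float
    df_num: float
    df_den: float
    p: float
    ms_effect: float
    ms_residual: float
    n_subjects: int
    epsilon: float = 1.0  # Greenhouse–Geisser epsilon (1 = no correction)


def _complete_matrix(cv_matrix: pd.DataFrame) -> pd.DataFrame:
    incomplete = cv_matrix.isna().any(axis=1)
    for assay in cv_matrix.index[incomplete]:
        log.info("assay %s has incomplete CVs; dropped from ANOVA", assay)
    return cv_matrix[~incomplete]


def rm_anova(cv_matrix: pd.DataFrame, gg_correction: bool = False) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on an assays × doses matrix.

    F = MS(dose) / MS(assay × dose residual) with (k−1) and (k−1)(n−1)
    degrees of freedom. Incomplete rows are dropped. With
    ``gg_correction`` both degrees of freedom are multiplied by the
    Greenhouse–Geisser epsilon before computing the p-value.
    """
    x = _complete_matrix(cv_matrix).to_numpy(dtype=float)
    n, k = x.shape
    if n < 2:
        raise DataError("repeated-measures ANOVA needs at least two complete assays")
    if k < 2:
        raise DataError("repeated-measures ANOVA needs at least two dose levels")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_dose = n * ((col_means - grand) ** 2).sum()
    ss_subj = k * ((row_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_resid = ss_total - ss_dose - ss_subj
    df_num = k - 1.0
    df_den = (k - 1.0) * (n - 1.0)
    ms_dose = ss_dose / df_num
    ms_resid = max(ss_resid, 0.0) / df_den

    eps = 1.0
    if gg_correction:
        cov = np.cov(x, rowvar=False, ddof=1)
        centered = (
            cov
            - cov.mean(axis=0, keepdims=True)
            - cov.mean(axis=1, keepdims=True)
            + cov.mean()
        )
        denom = (k - 1) * (centered ** 2).sum()
        eps = float(np.trace(centered) ** 2 / denom) if denom > 0 else 1.0
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)

    if ms_resid == 0.0:
        f = 0.0 if ms_dose == 0.0 else math.inf
        p = 1.0 if ms_dose == 0.0 else 0.0
    else:
        f = ms_dose / ms_resid
        p = float(stats.f.sf(f, df_num * eps, df_den * eps))
    return RmAnovaResult(
        f=float(f), df_num=df_num * eps, df_den=df_den * eps, p=p,
        ms_effect=float(ms_dose), ms_residual=float(ms_resid),
        n_subjects=n, epsilon=eps,
    )


def tukey_posthoc(cv_matrix: pd.DataFrame) -> dict[tuple[float, float], float]:
    """Tukey's test on the dose-level means, with the repeated-measures
    residual mean square as the error term.

    For doses i, j: q = |m_i − m_j| / sqrt(MS_resid / n), adjusted p from
    the studentized-range distribution with k groups and (k−1)(n−1) df.
    """
    complete = _complete_matrix(cv_matrix)
    res = rm_anova(complete)
    x = complete.to_numpy(dtype=float)
    n, k = x.shape
    col_means = dict(zip(complete.columns, x.mean(axis=0)))
    doses = list(complete.columns)
    out: dict[tuple[float, float], float] = {}
    for i, d1 in enumerate(doses):
        for d2 in doses[i + 1:]:
            diff = abs(col_means[d1] - col_means[d2])
            if res.ms_residual == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                q = diff / math.sqrt(res.ms_residual / n)
                p = float(stats.studentized_range.sf(q, k, res.df_den))
            out[(float(d1), float(d2))] = p
    return out


def variability_fold_increase(
    cvs: pd.DataFrame, config: Config | None = None
) -> dict[float, float]:
    """Median CV at each exposed dose divided by the median sham CV.

    ``cvs`` holds one gene's per-assay, per-dose CVs (columns ``assay_id,
    dose_gy, cv``). A zero sham median leaves the ratio undefined.
    """
    config = config or Config()
    medians = cvs.groupby("dose_gy")["cv"].median()
    sham = medians.get(config.reference_dose, math.nan)
    out = {}
    for dose in sorted(d for d in config.doses if d != config.reference_dose):
        if math.isnan(sham) or sham == 0:
            log.info("sham median CV is 0/undefined; fold increase undefined")
            out[dose] = math.nan
        else:
            out[dose] = float(medians.get(dose, math.nan) / sham)
    return out


@dataclass
class VarianceTestResult:
    """Per-gene dose-dependency test of the inter-individual variability."""

    gene: str
    anova_f: float
    anova_p: float
    df_num: float
    df_den: float
    n_assays: int
    pairwise: dict[tuple[float, float], float]
    fold_increase: dict[float, float]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pairwise"] = {f"{a:g}_vs_{b:g}": p for (a, b), p in self.pairwise.items()}
        d["fold_increase"] = {f"{k:g}": v for k, v in self.fold_increase.items()}
        return d


def analyze_gene(cvs: pd.DataFrame, gene: str, config: Config) -> VarianceTestResult:
    matrix = cvs.pivot_table(index="assay_id", columns="dose_gy", values="cv")
    matrix = matrix.reindex(columns=sorted(config.doses))
    res = rm_anova(matrix, gg_correction=config.gg_correction)
    return VarianceTestResult(
        gene=gene,
        anova_f=res.f,
        anova_p=res.p,
        df_num=res.df_num,
        df_den=res.df_den,
        n_assays=res.n_subjects,
        pairwise=tukey_posthoc(matrix),
        fold_increase=variability_fold_increase(cvs, config),
    )


def analyze(dataset: Dataset, fc_table: pd.DataFrame | None = None
            ) -> dict[str, VarianceTestResult]:
    """CV dose-dependency analysis for every gene in a dataset."""
    cfg = dataset.config
    if fc_table is None:
        fc_table = foldchange.compute_fc_table(dataset)
    donor_fc = foldchange.donor_fc_table(fc_table, cfg)
    cvs = cv_table(donor_fc, cfg)
    out = {}
    for gene, sub in cvs.groupby("gene"):
        try:
            out[gene] = analyze_gene(sub, gene, cfg)
        except DataError as exc:
            log.info("variance test not computable for %s: %s", gene, exc)
    return out


def write_varstats_json(results: dict[str, VarianceTestResult], path) -> None:
    payload = {gene: res.to_dict() for gene, res in sorted(results.items())}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_cv_table(cvs: pd.DataFrame, path) -> None:
    cvs.to_csv(path, sep="\t", index=False)
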
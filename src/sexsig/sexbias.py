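"""Identification of sex-biased genes.

Each gene is compared between male and female samples with a two-sample
t-test (Welch by default), p-values are adjusted by the Benjamini-Hochberg
step-up procedure, and genes at q <= threshold are classified as male-biased
(MG, higher in males) or female-biased (FG, higher in females).  Fold change
is reported both as log2(male) - log2(female) and as a signed linear ratio
(r for r >= 1, -1/r otherwise), matching the signed-fold-change idiom used
for drug signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression_io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

#: a gene is dropped when missing in more than this fraction of either sex
MAX_MISSING_FRACTION = 0.20


def signed_fold_change(log2_fc: float) -> float:
    """Signed linear ratio: 2**lfc for lfc >= 0, else -2**(-lfc)."""
    return float(2.0 ** log2_fc) if log2_fc >= 0 else float(-(2.0 ** -log2_fc))


@dataclass
class SexBiasRecord:
    """Per-gene two-group comparison result."""

    gene_id: str
    mean_male: float
    mean_female: float
    t_stat: float
    p_value: float
    log2_fc: float
    fold_change: float
    q_value: float | None = None
    bias_class: Literal["MG", "FG", "none"] = "none"


@dataclass(frozen=True)
class GeneClassSets:
    """The MG/FG sets together with the universe of genes actually tested."""

    mg: frozenset[str]
    fg: frozenset[str]
    tested_universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.mg & self.fg:
            raise ValidationError("MG and FG overlap")
        if not (self.mg | self.fg) <= self.tested_universe:
            raise ValidationError("MG/FG contain genes outside the tested universe")

    @property
    def sex_biased(self) -> frozenset[str]:
        return self.mg | self.fg


def _split_by_sex(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> tuple[np.ndarray, np.ndarray]:
    by_id = {a.sample_id: a for a in annotations}
    males = [s for s in matrix.sample_ids if by_id.get(s) and by_id[s].sex == "male"]
    females = [s for s in matrix.sample_ids if by_id.get(s) and by_id[s].sex == "female"]
    if len(males) < 2 or len(females) < 2:
        raise ValidationError(
            f"need >=2 usable samples per sex, got {len(males)} male / "
            f"{len(females)} female"
        )
    vals = matrix.to_log2().data
    return vals[males].to_numpy(float), vals[females].to_numpy(float)


def gene_wise_ttest(
    matrix: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    variant: Literal["welch", "pooled"] = "welch",
) -> list[SexBiasRecord]:
    """Two-sided two-sample t-test for every gene, male vs female.

    Genes missing in more than 20% of either sex's samples, genes leaving
    fewer than two usable values in a sex, and genes with zero variance in
    both groups are excluded (logged).  Zero variance in a single group is
    kept: the Welch (or pooled) statistic is still finite there.
    """
    if variant not in ("welch", "pooled"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    male, female = _split_by_sex(matrix, annotations)
    gene_ids = np.asarray(matrix.gene_ids)

    n_m = np.sum(~np.isnan(male), axis=1)
    n_f = np.sum(~np.isnan(female), axis=1)
    ok = (
        (np.isnan(male).mean(axis=1) <= MAX_MISSING_FRACTION)
        & (np.isnan(female).mean(axis=1) <= MAX_MISSING_FRACTION)
        & (n_m >= 2) & (n_f >= 2)
    )
    n_missing_dropped = int((~ok).sum())
    if n_missing_dropped:
        logger.info("excluding %d genes failing the missingness filter",
                    n_missing_dropped)

    with np.errstate(invalid="ignore"):
        var_m = np.nanvar(male, axis=1, ddof=1)
        var_f = np.nanvar(female, axis=1, ddof=1)
    flat = ok & (var_m == 0) & (var_f == 0)
    if flat.any():
        logger.info("excluding %d genes with zero variance in both groups",
                    int(flat.sum()))
    ok &= ~flat

    male, female = male[ok], female[ok]
    res = stats.ttest_ind(
        male, female, axis=1, equal_var=(variant == "pooled"), nan_policy="omit"
    )
    mean_m = np.nanmean(male, axis=1)
    mean_f = np.nanmean(female, axis=1)
    lfc = mean_m - mean_f

    records = []
    for gid, mm, mf, t, p, d in zip(
        gene_ids[ok], mean_m, mean_f, res.statistic, res.pvalue, lfc
    ):
        records.append(SexBiasRecord(
            gene_id=str(gid), mean_male=float(mm), mean_female=float(mf),
            t_stat=float(t), p_value=float(max(p, np.nextafter(0, 1))),
            log2_fc=float(d), fold_change=signed_fold_change(float(d)),
        ))
    return records


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q_values(records: list[SexBiasRecord]) -> list[SexBiasRecord]:
    """Fill q_value on each record by BH across all records."""
    q = benjamini_hochberg([r.p_value for r in records])
    for r, qi in zip(records, q):
        r.q_value = float(qi)
    return records


def classify_sex_biased(
    records: Sequence[SexBiasRecord],
    fdr_threshold: float = 0.05,
    fc_criterion: float | None = None,
) -> GeneClassSets:
    """Split genes into MG / FG / unbiased at an FDR threshold.

    MG: q <= threshold and higher in males; FG: q <= threshold and higher in
    females.  ``fc_criterion``, if given, additionally requires
    |fold_change| >= fc_criterion on the signed linear scale (off by default:
    the FDR cut is the sole criterion).
    """
    if not 0 < fdr_threshold < 1:
        raise ValidationError(f"fdr_threshold must be in (0,1), got {fdr_threshold}")
    if fc_criterion is not None and fc_criterion < 1:
        raise ValidationError("fc_criterion is a linear ratio and must be >= 1")
    for r in records:
        if r.q_value is None:
            raise ValidationError(f"record {r.gene_id} has no q_value")
    mg, fg = set(), set()
    for r in records:
        passes_fc = fc_criterion is None or abs(r.fold_change) >= fc_criterion
        if r.q_value <= fdr_threshold and passes_fc and r.log2_fc > 0:
            r.bias_class = "MG"
            mg.add(r.gene_id)
        elif r.q_value <= fdr_threshold and passes_fc and r.log2_fc < 0:
            r.bias_class = "FG"
            fg.add(r.gene_id)
        else:
            r.bias_class = "none"
    return GeneClassSets(frozenset(mg), frozenset(fg),
                         frozenset(r.gene_id for r in records))


def covariate_balance_test(
    annotations: Sequence[SampleAnnotation],
    covariate: Literal["age"] = "age",
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for a covariate across sexes.

    Exact enumeration when both groups have <= 20 values and no ties;
    otherwise the normal approximation with mid-rank tie correction.
    """
    if covariate != "age":
        raise ValidationError(f"unsupported covariate {covariate!r}")
    males = [a.age for a in annotations if a.sex == "male" and a.age is not None]
    females = [a.age for a in annotations if a.sex == "female" and a.age is not None]
    if len(males) < 2 or len(females) < 2:
        raise ValidationError(
            f"need >=2 aged samples per sex, got {len(males)} / {len(females)}"
        )
    pooled = males + females
    has_ties = len(set(pooled)) < len(pooled)
    method = ("exact"
              if max(len(males), len(females)) <= 20 and not has_ties
              else "asymptotic")
    res = stats.mannwhitneyu(males, females, alternative="two-sided",
                             method=method, use_continuity=False)
    return float(min(res.pvalue, 1.0))


def sexbias_table(records: Sequence[SexBiasRecord]) -> pd.DataFrame:
    """Flatten records into a tidy per-gene DataFrame (one row per gene)."""
    return pd.DataFrame([{
        "gene_id": r.gene_id, "mean_male": r.mean_male,
        "mean_female": r.mean_female, "t_stat": r.t_stat,
        "p_value": r.p_value, "q_value": r.q_value,
        "log2_fc": r.log2_fc, "fold_change": r.fold_change,
        "bias_class": r.bias_class,
    } for r in records])
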
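"""Synthetic sexed cohorts and drug-signature collections with known truth.

The generator emulates the statistical structure the analysis assumes: log2
expression values drawn from a homoscedastic Gaussian per gene and sample,
with a fixed log2 shift added to the favoured sex's mean for planted
male-/female-biased genes, and drug signatures drawn as gene sets from the
measured universe, with planted "associated" drugs biased towards the true
sex-biased genes.  All draws run through a single NumPy Generator stream so
one seed reproduces an entire study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .drug_signatures import (DrugSignature, FoldChangeTable,
                              SignatureCollection)
from .errors import ValidationError
from .expression_io import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study.

    Defaults describe a cohort of 40+40 non-failing samples over 2,000 genes
    with 50 planted male- and 50 female-biased genes (one-unit log2 shift,
    0.5 log2-unit noise), screened against 1,000 drugs of 100+100-gene
    signatures, 20 of which draw half their genes from the planted set.
    """

    n_genes: int = 2000
    n_male: int = 40
    n_female: int = 40
    n_mg_true: int = 50
    n_fg_true: int = 50
    effect_size: float = 1.0      # log2 shift added to the favoured sex
    noise_sd: float = 0.5         # log2 units
    baseline_mean: float = 8.0    # log2 units
    n_drugs: int = 1000
    n_assoc_drugs: int = 20
    sig_size_up: int = 100
    sig_size_down: int = 100
    assoc_fraction: float = 0.5
    seed: int = 0
    heteroscedastic_sd_jitter: float = 0.0  # lognormal sigma on per-gene sd

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_male", "n_female", "n_mg_true", "n_fg_true",
                     "n_drugs", "n_assoc_drugs", "sig_size_up", "sig_size_down"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_mg_true + self.n_fg_true > self.n_genes:
            raise ValidationError("n_mg_true + n_fg_true exceeds n_genes")
        if not 0.0 <= self.assoc_fraction <= 1.0:
            raise ValidationError("assoc_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.n_assoc_drugs > self.n_drugs:
            raise ValidationError("n_assoc_drugs exceeds n_drugs")
        if self.heteroscedastic_sd_jitter < 0:
            raise ValidationError("heteroscedastic_sd_jitter must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Planted sex-biased genes and sex-associated drugs."""

    true_mg: frozenset[str]
    true_fg: frozenset[str]
    true_assoc_drugs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.true_mg & self.true_fg:
            raise ValidationError("true_mg and true_fg overlap")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, list[SampleAnnotation], GroundTruth]:
    """Simulate a sexed non-failing cohort with planted sex-biased genes.

    Values are Normal(baseline_mean, noise_sd) on the log2 scale; planted MG
    genes get +effect_size on the male mean, FG genes on the female mean.
    Ages are drawn from the same distribution for both sexes, so the cohort
    is balanced by construction.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = _gene_ids(config.n_genes)
    males = [f"M{i:03d}" for i in range(1, config.n_male + 1)]
    females = [f"F{i:03d}" for i in range(1, config.n_female + 1)]

    planted = rng.choice(config.n_genes, config.n_mg_true + config.n_fg_true,
                         replace=False)
    mg_idx = planted[: config.n_mg_true]
    fg_idx = planted[config.n_mg_true:]

    sd = np.full(config.n_genes, config.noise_sd)
    if config.heteroscedastic_sd_jitter > 0:
        sd = sd * np.exp(rng.normal(0.0, config.heteroscedastic_sd_jitter,
                                    config.n_genes))

    mean_m = np.full(config.n_genes, config.baseline_mean)
    mean_f = np.full(config.n_genes, config.baseline_mean)
    mean_m[mg_idx] += config.effect_size
    mean_f[fg_idx] += config.effect_size

    vals_m = rng.normal(mean_m[:, None], sd[:, None],
                        (config.n_genes, config.n_male))
    vals_f = rng.normal(mean_f[:, None], sd[:, None],
                        (config.n_genes, config.n_female))
    data = pd.DataFrame(np.hstack([vals_m, vals_f]), index=genes,
                        columns=males + females)
    matrix = ExpressionMatrix(data, "log2")

    ages = np.clip(rng.normal(55.0, 8.0, config.n_male + config.n_female),
                   18.0, 90.0)
    annotations = [
        SampleAnnotation(s, "male" if s.startswith("M") else "female",
                         "non_failing", float(age))
        for s, age in zip(males + females, ages)
    ]
    truth = GroundTruth(
        true_mg=frozenset(genes[i] for i in mg_idx),
        true_fg=frozenset(genes[i] for i in fg_idx),
    )
    return matrix, annotations, truth


def simulate_signatures(
    config: SimulationConfig,
    truth: GroundTruth,
    universe: Iterable[str],
    rng: np.random.Generator | None = None,
) -> tuple[SignatureCollection, GroundTruth]:
    """Simulate a drug-signature collection with planted sex associations.

    Null drugs draw UG and DG uniformly without replacement from the
    universe.  Each of the first ``n_assoc_drugs`` drugs instead draws
    round(assoc_fraction * size) genes of each set from the planted
    sex-biased pool and the rest from the remainder; UG and DG stay disjoint
    by construction.  Returns the collection and the truth augmented with
    the associated drug ids.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    universe = sorted(universe)
    pool = sorted(truth.true_mg | truth.true_fg)
    if not (set(pool) <= set(universe)):
        raise ValidationError("universe must contain all planted sex-biased genes")
    size = config.sig_size_up + config.sig_size_down
    if size > len(universe):
        raise ValidationError("signature size exceeds the universe")

    n_digits = max(4, len(str(config.n_drugs)))
    signatures: list[DrugSignature] = []
    assoc_ids: list[str] = []
    universe_arr = np.asarray(universe, dtype=object)
    pool_set = set(pool)
    nonpool_arr = np.asarray([g for g in universe if g not in pool_set],
                             dtype=object)

    for k in range(config.n_drugs):
        drug = f"drug{k + 1:0{n_digits}d}"
        planted = k < config.n_assoc_drugs
        if planted:
            n_from_pool = int(round(config.assoc_fraction * size))
            n_from_pool = min(n_from_pool, len(pool))
            chosen_pool = rng.choice(np.asarray(pool, dtype=object),
                                     n_from_pool, replace=False)
            chosen_rest = rng.choice(nonpool_arr, size - n_from_pool,
                                     replace=False)
            genes = np.concatenate([chosen_pool, chosen_rest])
            rng.shuffle(genes)
            assoc_ids.append(drug)
        else:
            genes = rng.choice(universe_arr, size, replace=False)
        up = frozenset(map(str, genes[: config.sig_size_up]))
        down = frozenset(map(str, genes[config.sig_size_up:]))
        signatures.append(DrugSignature(drug, up, down, frozenset(universe)))

    collection = SignatureCollection(
        signatures, {"source": "synthetic", "threshold": "planted sets"})
    truth_out = replace(truth, true_assoc_drugs=frozenset(assoc_ids))
    return collection, truth_out


def fold_change_tables_from_signatures(
    collection: SignatureCollection,
    rng: np.random.Generator,
    effect_fold: float = 4.0,
    jitter_sigma: float = 0.25,
) -> list[FoldChangeTable]:
    """Synthetic fold-change tables consistent with a signature collection.

    Signature genes sit near +/-effect_fold with mild lognormal jitter;
    background genes near 1-fold.  Feeding these through the +/-2.0
    threshold recovers the original sets, which exercises the thresholding
    path end to end.
    """
    tables = []
    for sig in collection:
        genes = sorted(sig.source_universe)
        ratio = np.exp(rng.normal(0.0, jitter_sigma / 4.0, len(genes)))
        up_mask = np.isin(genes, sorted(sig.up_genes))
        down_mask = np.isin(genes, sorted(sig.down_genes))
        ratio[up_mask] = effect_fold * np.exp(
            np.abs(rng.normal(0.0, jitter_sigma, int(up_mask.sum()))))
        ratio[down_mask] = 1.0 / (effect_fold * np.exp(
            np.abs(rng.normal(0.0, jitter_sigma, int(down_mask.sum())))))
        signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
        tables.append(FoldChangeTable(
            sig.drug_id, pd.Series(signed, index=genes)))
    return tables


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SignatureCollection,
           GroundTruth]:
    """Full synthetic study: cohort plus signatures from one seed stream."""
    rng = np.random.default_rng(config.seed)
    matrix, annotations, truth = simulate_expression(config, rng)
    collection, truth = simulate_signatures(config, truth, matrix.gene_ids, rng)
    return matrix, annotations, collection, truth


# ---------------------------------------------------------------------------
# recovery-based evaluation of the full pipeline on synthetic studies
# ---------------------------------------------------------------------------

def evaluate_planted_recovery(config: SimulationConfig) -> dict:
    """Run the pipeline on one planted study and score it against the truth.

    Returns gene-level recall and false-discovery proportion of the MG u FG
    call set, and the fraction of planted drugs occupying the top
    ``n_assoc_drugs`` ranks.
    """
    from .association import associate_drugs
    from .sexbias import attach_q_values, classify_sex_biased, gene_wise_ttest

    matrix, annotations, collection, truth = simulate_study(config)
    records = attach_q_values(gene_wise_ttest(matrix, annotations))
    classes = classify_sex_biased(records, 0.05)
    results = associate_drugs(classes, collection)

    found = set(classes.mg | classes.fg)
    planted = set(truth.true_mg | truth.true_fg)
    recall = len(found & planted) / len(planted) if planted else float("nan")
    fdp = len(found - planted) / max(len(found), 1)
    k = config.n_assoc_drugs
    top = {r.drug_id for r in results if r.rank <= k}
    drug_recovery = (len(top & truth.true_assoc_drugs) / k if k
                     else float("nan"))
    return {"gene_recall": recall, "gene_fdp": fdp,
            "drug_top_k_recovery": drug_recovery,
            "n_sex_biased_called": len(found),
            "n_mg_called": len(classes.mg), "n_fg_called": len(classes.fg)}


def evaluate_null_calibration(config: SimulationConfig,
                              alpha: float = 0.05) -> float:
    """Fraction of drugs with headline p <= alpha on a null study.

    The study must be null (effect_size == 0, assoc_fraction == 0).  Because
    an FDR cut returns no genes under the null, the sex-set stand-in is the
    set of genes with raw p <= alpha, which is independent of the signature
    draws and so preserves the null of the association test.
    """
    from .association import associate_drugs
    from .sexbias import GeneClassSets, gene_wise_ttest

    if config.effect_size != 0 or config.assoc_fraction != 0:
        raise ValidationError("null calibration requires effect_size=0 "
                              "and assoc_fraction=0")
    matrix, annotations, collection, _ = simulate_study(config)
    records = gene_wise_ttest(matrix, annotations)
    mg = frozenset(r.gene_id for r in records
                   if r.p_value <= alpha and r.log2_fc > 0)
    fg = frozenset(r.gene_id for r in records
                   if r.p_value <= alpha and r.log2_fc < 0)
    classes = GeneClassSets(mg, fg,
                            frozenset(r.gene_id for r in records))
    results = associate_drugs(classes, collection)
    return float(np.mean([r.p_overall <= alpha for r in results]))
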
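"""Pipeline orchestration, ranked reports, and summary-statistics t-tests.

`run_pipeline` wires the stages together — load expression and annotations,
filter to the target condition, identify sex-biased genes, load drug
signatures, test every drug's association, rank — and writes the per-gene
table, the full association table, the top-N report, a run log and a
machine-readable metadata file.  Outputs are deterministic for a fixed
config, so reruns are byte-identical.

`summary_stats_ttest` is the two-group t-test from printed summary
statistics (mean, SD, n per group) used for clinical characteristic tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from scipy import stats

from . import __version__
from .association import associate_drugs, rank_and_report
from .drug_signatures import read_signature_collection
from .errors import PipelineError, ValidationError
from .expression_io import (filter_samples, read_expression_matrix,
                            read_sample_annotations)
from .sexbias import (attach_q_values, classify_sex_biased, gene_wise_ttest,
                      sexbias_table)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs, mirroring the CLI flags."""

    expression_path: str
    annotations_path: str
    signatures_path: str
    output_dir: str
    expression_format: Literal["series_matrix_tsv", "gct"] = "series_matrix_tsv"
    condition: str = "non_failing"
    fdr_threshold: float = 0.05
    fc_criterion: float | None = None
    up_min: float = 2.0
    down_max: float = -2.0
    t_variant: Literal["welch", "pooled"] = "welch"
    alternative: Literal["two_sided", "greater"] = "two_sided"
    universe_policy: Literal["intersection", "expression_side"] = "intersection"
    top_n: int = 20
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0,1)")
        if self.up_min < 1.0 or self.down_max > -1.0:
            raise ValidationError("up_min must be >= 1 and down_max <= -1")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")


@dataclass(frozen=True)
class ClinicalSummary:
    """One group's printed summary statistics: mean, SD and sample size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"{self.label}: n must be >= 2")
        if self.sd <= 0:
            raise ValidationError(f"{self.label}: sd must be > 0")


def summary_stats_ttest(
    g1: ClinicalSummary, g2: ClinicalSummary,
    variant: Literal["pooled", "welch"] = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns (t, df, p).

    Pooled uses df = n1 + n2 - 2; Welch uses the Welch-Satterthwaite df.
    """
    v1, v2, n1, n2 = g1.sd ** 2, g2.sd ** 2, g1.n, g2.n
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}")
    t = (g1.mean - g2.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


_REPORT_COLUMNS = ["drug_id", "a", "b", "c", "d", "odds_ratio", "p_overall",
                   "p_mg_up", "p_mg_down", "p_fg_up", "p_fg_down",
                   "q_value", "rank"]


def write_report(rows: Sequence[dict], path) -> None:
    """Write ranked report rows as TSV with a fixed column order.

    Floats are printed at six significant digits.
    """
    if not rows:
        raise ValidationError("refusing to write an empty report")
    df = pd.DataFrame(list(rows))[_REPORT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write all outputs into config.output_dir.

    Returns a summary dict (also written as run_metadata.json).  Stage
    failures propagate with the stage name prefixed; no partial TSVs are
    left behind.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("sexsig")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())

    written: list[Path] = []
    stage = "load"
    try:
        matrix = read_expression_matrix(config.expression_path,
                                        config.expression_format)
        annotations = read_sample_annotations(config.annotations_path)

        stage = "filter"
        matrix, annotations = filter_samples(matrix, annotations,
                                             config.condition)
        n_male = sum(a.sex == "male" for a in annotations)
        n_female = len(annotations) - n_male
        logger.info("retained %d samples (%d male / %d female)",
                    len(annotations), n_male, n_female)

        stage = "sexbias"
        records = attach_q_values(
            gene_wise_ttest(matrix, annotations, config.t_variant))
        classes = classify_sex_biased(records, config.fdr_threshold,
                                      config.fc_criterion)
        logger.info("%d sex-biased genes (%d MG / %d FG) of %d tested",
                    len(classes.sex_biased), len(classes.mg), len(classes.fg),
                    len(classes.tested_universe))
        sexbias_path = out / "sexbias.tsv"
        sexbias_table(records).to_csv(sexbias_path, sep="\t", index=False,
                                      float_format="%.6g")
        written.append(sexbias_path)

        stage = "signatures"
        collection = read_signature_collection(config.signatures_path)

        stage = "association"
        results = associate_drugs(classes, collection, config.universe_policy,
                                  config.alternative)

        stage = "report"
        all_rows = rank_and_report(results, top_n=len(results))
        assoc_path = out / "associations.tsv"
        write_report(all_rows, assoc_path)
        written.append(assoc_path)
        top_rows = rank_and_report(results, top_n=min(config.top_n,
                                                      len(results)))
        top_path = out / f"top_{config.top_n}.tsv"
        write_report(top_rows, top_path)
        written.append(top_path)

        metadata = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "n_samples": len(annotations),
            "n_male": n_male,
            "n_female": n_female,
            "n_genes_tested": len(classes.tested_universe),
            "n_sex_biased": len(classes.sex_biased),
            "n_mg": len(classes.mg),
            "n_fg": len(classes.fg),
            "n_drugs_tested": len(results),
            "outputs": [p.name for p in written] + ["run.log"],
        }
        meta_path = out / "run_metadata.json"
        meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True)
                             + "\n")
        return metadata
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"[stage: {stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
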
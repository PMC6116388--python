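"""Fisher's exact association between sex-biased and drug-regulated gene sets.

For every drug a 2x2 contingency table is built over a shared gene universe:
rows split genes by sex-biased vs not, columns by drug-regulated vs not.  The
headline test uses the pooled sets (MG u FG against UG u DG); the four
directional tables (MG x UG, MG x DG, FG x UG, FG x DG) are always computed
alongside.  Drugs are ranked by ascending headline p, with odds ratio and
then drug id breaking ties, and BH-adjusted q-values are assigned across
drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .drug_signatures import SignatureCollection
from .errors import ValidationError
from .sexbias import GeneClassSets, benjamini_hochberg

logger = logging.getLogger(__name__)

Alternative = Literal["two_sided", "greater"]
_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater"}


@dataclass(frozen=True)
class ContingencyTable:
    """Counts over a gene universe: a = in both sets, b = sex-biased only,
    c = drug-regulated only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative contingency count: {self}")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class DrugAssociationResult:
    """Per-drug association: overall and directional tables, exact p-values,
    sample odds ratio, BH q across drugs, and rank."""

    drug_id: str
    table_overall: ContingencyTable
    tables_directional: dict[str, ContingencyTable]
    odds_ratio: float
    or_continuity_corrected: bool
    p_overall: float
    p_directional: dict[str, float]
    q_value: float | None = None
    rank: int | None = None


def build_contingency(
    set_x: Iterable[str], set_y: Iterable[str], universe: Iterable[str]
) -> ContingencyTable:
    """2x2 table of X (sex-biased) against Y (drug-regulated) within a universe.

    Both sets are intersected with the universe before counting.
    """
    u = frozenset(universe)
    if not u:
        raise ValidationError("empty gene universe")
    x = frozenset(set_x) & u
    y = frozenset(set_y) & u
    a = len(x & y)
    return ContingencyTable(a, len(x) - a, len(y) - a,
                            len(u) - len(x) - len(y) + a)


def fisher_exact(
    table: ContingencyTable, alternative: Alternative = "two_sided"
) -> tuple[float, float]:
    """Exact hypergeometric p-value and sample odds ratio for a 2x2 table.

    Two-sided p sums the probabilities of all margin-preserving tables no
    more probable than the observed one (with the conventional 1+1e-7
    relative tolerance on the comparison); 'greater' is the upper tail on
    cell a.  The odds ratio is (a*d)/(b*c); Haldane's 0.5 continuity
    correction is applied to every cell only when some cell is zero (flagged
    by the caller via `sample_odds_ratio`).
    """
    p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]],
        alternative=_SCIPY_ALT[alternative],
    ).pvalue
    odds, _ = sample_odds_ratio(table)
    return float(min(max(p, 0.0), 1.0)), odds


def sample_odds_ratio(table: ContingencyTable) -> tuple[float, bool]:
    """(a*d)/(b*c), with 0.5 added to every cell when any cell is zero.

    Returns (odds_ratio, continuity_corrected).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return float((a * d) / (b * c)), True
    return float((a * d) / (b * c)), False


_DIRECTIONS = ("mg_up", "mg_down", "fg_up", "fg_down")


def associate_drugs(
    classes: GeneClassSets,
    signatures: SignatureCollection,
    universe_policy: Literal["intersection", "expression_side"] = "intersection",
    alternative: Alternative = "two_sided",
) -> list[DrugAssociationResult]:
    """Test every drug's signature against the MG/FG sets.

    Per drug the universe is the expression-side tested genes intersected
    with the drug's measured genes (default) or the expression side alone.
    Drugs with no regulated gene inside the universe are skipped with a
    warning.  q-values are BH across tested drugs; ranks sort by
    (p ascending, odds ratio descending, drug id).
    """
    if universe_policy not in ("intersection", "expression_side"):
        raise ValidationError(f"unknown universe policy {universe_policy!r}")
    results: list[DrugAssociationResult] = []
    n_skipped = 0
    for sig in signatures:
        universe = (classes.tested_universe & sig.source_universe
                    if universe_policy == "intersection"
                    else classes.tested_universe)
        if not universe or not (sig.regulated & universe):
            n_skipped += 1
            logger.warning("%s: no regulated genes inside the universe; skipped",
                           sig.drug_id)
            continue
        overall = build_contingency(classes.sex_biased, sig.regulated, universe)
        p_overall, odds = fisher_exact(overall, alternative)
        _, corrected = sample_odds_ratio(overall)
        directional = {
            "mg_up": build_contingency(classes.mg, sig.up_genes, universe),
            "mg_down": build_contingency(classes.mg, sig.down_genes, universe),
            "fg_up": build_contingency(classes.fg, sig.up_genes, universe),
            "fg_down": build_contingency(classes.fg, sig.down_genes, universe),
        }
        p_dir = {k: fisher_exact(t, alternative)[0]
                 for k, t in directional.items()}
        results.append(DrugAssociationResult(
            drug_id=sig.drug_id, table_overall=overall,
            tables_directional=directional, odds_ratio=odds,
            or_continuity_corrected=corrected, p_overall=p_overall,
            p_directional=p_dir,
        ))
    if not results:
        raise ValidationError("zero drugs testable against the gene universe")
    if n_skipped:
        logger.warning("skipped %d of %d drugs", n_skipped, len(signatures))

    q = benjamini_hochberg([r.p_overall for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    order = sorted(
        range(len(results)),
        key=lambda i: (results[i].p_overall, -results[i].odds_ratio,
                       results[i].drug_id),
    )
    for rank, i in enumerate(order, start=1):
        results[i].rank = rank
    return results


def rank_and_report(
    results: Sequence[DrugAssociationResult], top_n: int = 20
) -> list[dict]:
    """Rows for the ranked drug report, sorted by rank and cut to top_n.

    If fewer than top_n drugs were tested the full list is returned with a
    warning rather than an error.
    """
    if not results:
        raise ValidationError("no association results to report")
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    if top_n > len(results):
        logger.warning("top_n=%d exceeds the %d tested drugs; returning all",
                       top_n, len(results))
    ordered = sorted(results, key=lambda r: (r.p_overall, -r.odds_ratio,
                                             r.drug_id))[:top_n]
    rows = []
    for r in ordered:
        t = r.table_overall
        row = {
            "drug_id": r.drug_id, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": r.odds_ratio, "p_overall": r.p_overall,
        }
        for k in _DIRECTIONS:
            row[f"p_{k}"] = r.p_directional[k]
        row["q_value"] = r.q_value
        row["rank"] = r.rank
        rows.append(row)
    return rows
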
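"""Per-drug up/down gene signatures from perturbation fold changes.

Fold changes are kept on the signed linear scale used throughout the package:
a treatment/control ratio r >= 1 is stored as r, r < 1 as -1/r, so that
down-regulation appears as a negative magnitude and the classic +/-2.0
signature thresholds read naturally (|log2 FC| >= 1).  Collections are stored
on disk as GMT with paired ``<drug>_UP`` / ``<drug>_DOWN`` entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .expression_io import ExpressionMatrix, Scale

logger = logging.getLogger(__name__)


@dataclass
class FoldChangeTable:
    """Signed linear treatment/control fold changes for one drug."""

    drug_id: str
    fold_changes: pd.Series  # index: gene ids; values: signed linear FC

    def __post_init__(self) -> None:
        if self.fold_changes.index.has_duplicates:
            raise ValidationError(f"{self.drug_id}: duplicate gene ids")
        vals = self.fold_changes.to_numpy(dtype=float)
        bad = (np.abs(vals) < 1.0) | (vals == 0)
        if bad.any():
            offenders = self.fold_changes.index[bad].tolist()
            raise ValidationError(
                f"{self.drug_id}: signed linear fold changes cannot lie in "
                f"(-1, 1): {offenders[:10]}"
            )


@dataclass
class DrugSignature:
    """Up- and down-regulated gene sets for one drug, plus the measured universe."""

    drug_id: str
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    source_universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.up_genes & self.down_genes:
            raise ValidationError(
                f"{self.drug_id}: genes in both UP and DOWN: "
                f"{sorted(self.up_genes & self.down_genes)[:10]}"
            )
        if not (self.up_genes | self.down_genes) <= self.source_universe:
            raise ValidationError(
                f"{self.drug_id}: UP/DOWN genes outside the source universe"
            )

    @property
    def regulated(self) -> frozenset[str]:
        return self.up_genes | self.down_genes


@dataclass
class SignatureCollection:
    """An ordered collection of drug signatures with shared metadata."""

    signatures: list[DrugSignature]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.drug_id for s in self.signatures]
        if len(set(ids)) != len(ids):
            dups = sorted({d for d in ids if ids.count(d) > 1})
            raise ValidationError(f"duplicate drug ids: {dups[:10]}")

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    @property
    def drug_ids(self) -> list[str]:
        return [s.drug_id for s in self.signatures]


def compute_fold_changes(
    treated: ExpressionMatrix,
    control: ExpressionMatrix,
    drug_id: str,
    aggregate: Literal["mean", "median"] = "mean",
) -> FoldChangeTable:
    """Per-gene signed linear fold change of treated vs control profiles.

    Replicate profiles within each arm are aggregated on the linear scale
    (mean by default); log2 input is unlogged first.  Genes whose control
    mean is not positive are dropped with a logged count.
    """
    shared = [g for g in treated.gene_ids if g in set(control.gene_ids)]
    if not shared:
        raise ValidationError("treated and control share no genes")
    if treated.shape[1] < 1 or control.shape[1] < 1:
        raise ValidationError("need >=1 profile in each arm")

    def linear(m: ExpressionMatrix) -> pd.DataFrame:
        return 2.0 ** m.data if m.scale_flag == "log2" else m.data

    agg = (lambda df: df.mean(axis=1)) if aggregate == "mean" else \
          (lambda df: df.median(axis=1))
    if aggregate not in ("mean", "median"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    t_mean = agg(linear(treated).loc[shared])
    c_mean = agg(linear(control).loc[shared])

    usable = (c_mean > 0) & (t_mean > 0)
    n_bad = int((~usable).sum())
    if n_bad:
        logger.warning("%s: dropping %d genes with a non-positive arm mean",
                       drug_id, n_bad)
    ratio = (t_mean[usable] / c_mean[usable]).astype(float)
    signed = ratio.where(ratio >= 1.0, -1.0 / ratio)
    return FoldChangeTable(drug_id, signed)


def threshold_signature(
    fc: FoldChangeTable, up_min: float = 2.0, down_max: float = -2.0
) -> DrugSignature:
    """Apply the +/-2.0 signed fold-change rule: UG = {fc >= up_min},
    DG = {fc <= down_max}; the source universe is every gene in the table."""
    if up_min < 1.0:
        raise ValidationError(f"up_min must be >= 1, got {up_min}")
    if down_max > -1.0:
        raise ValidationError(f"down_max must be <= -1, got {down_max}")
    s = fc.fold_changes
    up = frozenset(s.index[s >= up_min])
    down = frozenset(s.index[s <= down_max])
    return DrugSignature(fc.drug_id, up, down, frozenset(s.index))


# ---------------------------------------------------------------------------
# GMT I/O: paired <drug>_UP / <drug>_DOWN entries
# ---------------------------------------------------------------------------

_UP, _DOWN = "_UP", "_DOWN"


def read_signature_collection(path) -> SignatureCollection:
    """Read a GMT file of paired up/down sets into a SignatureCollection.

    Every line is ``name<TAB>description<TAB>gene...`` with names ending in
    ``_UP`` or ``_DOWN``.  A drug with only one of the pair gets an empty
    complementary set (warned).  The per-drug source universe is recovered
    from the description field when it carries ``universe_size=N`` metadata;
    otherwise it defaults to the union of that drug's sets.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path} line {lineno}: expected "
                                  "'name<TAB>description<TAB>gene...'")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"{path} line {lineno}: duplicate set "
                                      f"name {name!r}")
            if not (name.endswith(_UP) or name.endswith(_DOWN)):
                raise FormatError(f"{path} line {lineno}: set name {name!r} "
                                  f"must end in _UP or _DOWN")
            sets[name] = genes
            descriptions[name] = desc

    drugs: list[str] = []
    for name in sets:
        drug = name[: -len(_UP)] if name.endswith(_UP) else name[: -len(_DOWN)]
        if drug not in drugs:
            drugs.append(drug)

    signatures = []
    for drug in drugs:
        up_name, down_name = drug + _UP, drug + _DOWN
        if up_name not in sets or down_name not in sets:
            logger.warning("%s: only one of the UP/DOWN pair present; the "
                           "missing set is empty", drug)
        up = frozenset(sets.get(up_name, []))
        down = frozenset(sets.get(down_name, []))
        universe = up | down
        desc = descriptions.get(up_name) or descriptions.get(down_name) or ""
        for tok in desc.split(";"):
            if tok.startswith("universe="):
                universe = universe | frozenset(tok[len("universe="):].split(","))
        signatures.append(DrugSignature(drug, up, down, universe))
    return SignatureCollection(signatures, {"source": str(path)})


def write_signature_collection(collection: SignatureCollection, path) -> None:
    """Write paired _UP/_DOWN GMT lines readable by `read_signature_collection`.

    The source universe is preserved in the description field only when it
    exceeds UG u DG (kept compact for the common case).
    """
    with open(path, "w") as fh:
        for sig in collection:
            extra = sig.source_universe - sig.regulated
            desc = ("universe=" + ",".join(sorted(sig.source_universe))
                    if extra else "na")
            fh.write("\t".join([sig.drug_id + _UP, desc,
                                *sorted(sig.up_genes)]) + "\n")
            fh.write("\t".join([sig.drug_id + _DOWN, desc,
                                *sorted(sig.down_genes)]) + "\n")
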
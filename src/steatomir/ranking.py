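"""Biological-relevance scoring of a cross-tissue miRNA panel.

A candidate circulating biomarker of hepatic steatosis should ideally be a
guide-strand miRNA, correlate significantly with steatosis in both tissues,
target a meaningful number of lipid-metabolism genes, and be liver-enriched
(high liver/serum abundance ratio; liver-specific species such as
miR-122-5p show L/S ratios of 300-3000).  Each record is scored by an
additive penalty: every violated criterion contributes a nonpositive
increment, so 0 is best.  The rule set -- predicates, thresholds and
weights -- is configuration-driven; the defaults below are this package's
choice of a plausible rule set, not a published formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .matrix import NormalizedMatrix, ValidationError

__all__ = [
    "BiomarkerRecord",
    "PenaltyRule",
    "PenaltyRules",
    "DEFAULT_RULES",
    "liver_serum_ratio",
    "trend_concordance",
    "penalty_score",
    "rank_panel",
    "build_records",
]

#: sentinel for an undefined liver/serum ratio (zero serum mean)
UNDEFINED_RATIO = float("nan")


@dataclass
class BiomarkerRecord:
    """Per-miRNA evidence row for panel ranking."""

    mirna_id: str
    guide_strand: int  # 1 = guide, 0 = passenger
    liver_r: float
    liver_p: float
    serum_r: float
    serum_p: float
    lipid_target_count: int
    ls_ratio: float  # NaN when undefined
    trend: str = field(init=False)
    penalty: int = 0

    def __post_init__(self) -> None:
        self.trend = trend_concordance(self.liver_r, self.serum_r)


@dataclass(frozen=True)
class PenaltyRule:
    """One named criterion: (predicate name, threshold parameter, increment <= 0)."""

    criterion: str
    increment: int
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.increment > 0:
            raise ValidationError(f"penalty increment must be <= 0: {self.criterion}")
        if self.criterion not in _PREDICATES:
            raise ValidationError(
                f"unknown penalty criterion {self.criterion!r}; known: {sorted(_PREDICATES)}"
            )

    def fires(self, record: BiomarkerRecord) -> bool:
        return _PREDICATES[self.criterion](record, self.threshold)


def _is_passenger(rec: BiomarkerRecord, _thr: float) -> bool:
    return rec.guide_strand == 0


def _nonsig_liver(rec: BiomarkerRecord, thr: float) -> bool:
    return not (rec.liver_p < thr)


def _nonsig_serum(rec: BiomarkerRecord, thr: float) -> bool:
    return not (rec.serum_p < thr)


def _low_lipid_targets(rec: BiomarkerRecord, thr: float) -> bool:
    return rec.lipid_target_count < thr


def _low_ls_ratio(rec: BiomarkerRecord, thr: float) -> bool:
    # undefined ratio (zero serum mean) counts as failing the enrichment criterion
    return bool(np.isnan(rec.ls_ratio)) or rec.ls_ratio < thr


_PREDICATES = {
    "passenger_strand": _is_passenger,
    "nonsignificant_liver_correlation": _nonsig_liver,
    "nonsignificant_serum_correlation": _nonsig_serum,
    "low_lipid_target_count": _low_lipid_targets,
    "low_liver_serum_ratio": _low_ls_ratio,
}


@dataclass
class PenaltyRules:
    """Ordered, uniquely named additive penalty criteria."""

    rules: list[PenaltyRule]

    def __post_init__(self) -> None:
        names = [r.criterion for r in self.rules]
        if len(names) != len(set(names)):
            raise ValidationError("criteria names must be unique")

    @classmethod
    def from_config(cls, entries: Iterable[dict]) -> "PenaltyRules":
        """Build from a YAML-style list of {criterion, increment[, threshold]} mappings."""
        return cls([PenaltyRule(**e) for e in entries])


DEFAULT_RULES = PenaltyRules(
    [
        PenaltyRule("passenger_strand", -2),
        PenaltyRule("nonsignificant_liver_correlation", -1, threshold=0.05),
        PenaltyRule("nonsignificant_serum_correlation", -1, threshold=0.05),
        PenaltyRule("low_lipid_target_count", -1, threshold=5),
        PenaltyRule("low_liver_serum_ratio", -1, threshold=5),
    ]
)


def liver_serum_ratio(liver: NormalizedMatrix, serum: NormalizedMatrix, mirna_id: str) -> float:
    """Mean liver abundance over mean serum abundance; NaN when the serum mean is zero."""
    for mat, tissue in ((liver, "liver"), (serum, "serum")):
        if mirna_id not in mat.values.index:
            raise ValidationError(f"{mirna_id!r} absent from {tissue} matrix")
    liver_mean = float(liver.values.loc[mirna_id].mean())
    serum_mean = float(serum.values.loc[mirna_id].mean())
    if serum_mean == 0:
        return UNDEFINED_RATIO
    return liver_mean / serum_mean


def trend_concordance(liver_r: float, serum_r: float) -> str:
    """'opposite' when the correlation signs differ, 'same' when they agree,
    'undefined' when either is zero or missing."""
    if np.isnan(liver_r) or np.isnan(serum_r) or liver_r == 0 or serum_r == 0:
        return "undefined"
    return "opposite" if (liver_r > 0) != (serum_r > 0) else "same"


def penalty_score(record: BiomarkerRecord, rules: PenaltyRules = DEFAULT_RULES) -> int:
    """Sum of the increments of every rule whose predicate fires."""
    return sum(rule.increment for rule in rules.rules if rule.fires(record))


def rank_panel(
    records: Iterable[BiomarkerRecord], rules: PenaltyRules = DEFAULT_RULES
) -> list[BiomarkerRecord]:
    """Score and order records: descending penalty (0 first), ties broken by
    larger min(|liver_r|, |serum_r|), then lexicographic miRNA ID."""
    scored = []
    for rec in records:
        rec.penalty = penalty_score(rec, rules)
        scored.append(rec)

    def key(rec: BiomarkerRecord):
        strength = min(abs(rec.liver_r), abs(rec.serum_r))
        if np.isnan(strength):
            strength = -np.inf
        return (-rec.penalty, -strength, rec.mirna_id)

    return sorted(scored, key=key)


def build_records(
    panel: Iterable[str],
    liver_corr: pd.DataFrame,
    serum_corr: pd.DataFrame,
    liver_norm: NormalizedMatrix,
    serum_norm: NormalizedMatrix,
    annotation: pd.DataFrame,
) -> list[BiomarkerRecord]:
    """Assemble evidence records for a panel from the per-tissue correlation
    tables, normalized matrices, and the guide/target annotation."""
    lc = liver_corr.set_index("mirna_id")
    sc = serum_corr.set_index("mirna_id")
    ann = annotation.set_index("mirna_id")
    records = []
    for mid in panel:
        records.append(
            BiomarkerRecord(
                mirna_id=mid,
                guide_strand=int(ann.loc[mid, "guide_strand"]),
                liver_r=float(lc.loc[mid, "r"]),
                liver_p=float(lc.loc[mid, "p_value"]),
                serum_r=float(sc.loc[mid, "r"]),
                serum_p=float(sc.loc[mid, "p_value"]),
                lipid_target_count=int(ann.loc[mid, "lipid_targets"]),
                ls_ratio=liver_serum_ratio(liver_norm, serum_norm, mid),
            )
        )
    return records


def panel_to_frame(records: Iterable[BiomarkerRecord]) -> pd.DataFrame:
    """Ranked-panel table: one row per miRNA with all evidence columns."""
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "guide_strand": r.guide_strand,
                "liver_r": r.liver_r,
                "liver_p": r.liver_p,
                "serum_r": r.serum_r,
                "serum_p": r.serum_p,
                "lipid_targets": r.lipid_target_count,
                "ls_ratio": r.ls_ratio,
                "trend": r.trend,
                "penalty": r.penalty,
            }
            for r in records
        ]
    )
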
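"""Candidate-mutation selection filters.

Three independent filters feed the oligo pool design for allele reversion:

* coding-mutation prioritisation — keep all frameshift, nonsense and
  nonsynonymous mutations and mutations in non-coding RNA, plus synonymous
  changes in genes whose Keio knockout grows poorly (LB_22 < 0.7), and sort
  the keepers into three nested priority categories;
* regulatory-disruption thresholds on precomputed 5' mRNA folding (MFE) and
  RBS-strength scores — a >10% change in mean MFE across the two folding
  windows, or a >10-fold change in predicted expression, flags a mutation;
* alternate-fraction (AF) call classification — the fraction of aligned
  reads supporting the alternate allele classifies a variant call as strong
  (AF >= 0.7), marginal (0.1 < AF < 0.7) or absent (AF <= 0.1).

MFE and RBS values are consumed as precomputed columns; this module never
computes RNA structure or ribosome-binding strength itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional
import logging

logger = logging.getLogger(__name__)

EFFECT_CLASSES = (
    "frameshift",
    "nonsense",
    "nonsynonymous",
    "synonymous",
    "noncoding_rna",
    "intergenic",
)

#: effect classes included unconditionally by the coding filter
_ALWAYS_INCLUDE = {"frameshift", "nonsense", "nonsynonymous", "noncoding_rna"}


class CallClass(str, Enum):
    STRONG = "strong"
    MARGINAL = "marginal"
    ABSENT = "absent"


@dataclass(frozen=True)
class VariantCallClass:
    af: float
    call: CallClass


@dataclass
class AnnotatedMutation:
    """One candidate mutation with its precomputed annotations.

    MFE values are kcal/mol for the folding windows (-30,+100) ("w1") and
    (-15,+100) ("w2") around the start codon, in the wild-type and mutant
    sequence contexts.  RBS values are predicted expression in arbitrary
    units and must be strictly positive when present.
    """

    mutation_id: str
    effect_class: str
    keio_lb22: Optional[float] = None
    mfe_wt_w1: Optional[float] = None
    mfe_wt_w2: Optional[float] = None
    mfe_mut_w1: Optional[float] = None
    mfe_mut_w2: Optional[float] = None
    rbs_wt: Optional[float] = None
    rbs_mut: Optional[float] = None
    essential_gene: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        for name in ("rbs_wt", "rbs_mut"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


def classify_af(af: float, lower: float = 0.1, upper: float = 0.7) -> VariantCallClass:
    """Classify a variant call by its alternate fraction.

    The marginal band is the open interval (lower, upper): a call exactly at
    the lower bound is absent and exactly at the upper bound is strong.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"alternate fraction {af} outside [0, 1]")
    if af >= upper:
        call = CallClass.STRONG
    elif af > lower:
        call = CallClass.MARGINAL
    else:
        call = CallClass.ABSENT
    return VariantCallClass(af=af, call=call)


@dataclass(frozen=True)
class CodingDecision:
    mutation_id: str
    include: bool
    category: Optional[int]  # 1 | 2 | 3 | None
    reason: str


def _categorize(m: AnnotatedMutation) -> int:
    """Priority category for an included mutation.

    1 = frameshift/nonsense, or any included class hitting an essential
    gene; 2 = remaining nonsynonymous and non-coding RNA; 3 = qualifying
    synonymous.  This mapping approximates the published priority table,
    which is not algorithmically specified.
    """
    if m.effect_class in ("frameshift", "nonsense") or m.essential_gene is True:
        return 1
    if m.effect_class in ("nonsynonymous", "noncoding_rna"):
        return 2
    return 3


def prioritize_coding(
    mutations, lb22_cutoff: float = 0.7
) -> list[CodingDecision]:
    """Apply the coding-mutation inclusion rule and assign categories.

    Includes every frameshift, nonsense, nonsynonymous and non-coding-RNA
    mutation, plus synonymous mutations in genes with Keio LB_22 below the
    cutoff.  Synonymous mutations with no LB_22 value are excluded with a
    warning (no evidence of a growth-relevant gene).
    """
    decisions = []
    for m in mutations:
        if m.effect_class in _ALWAYS_INCLUDE:
            decisions.append(
                CodingDecision(m.mutation_id, True, _categorize(m), m.effect_class)
            )
        elif m.effect_class == "synonymous":
            if m.keio_lb22 is None:
                logger.warning(
                    "synonymous mutation %s has no LB_22 value; excluded",
                    m.mutation_id,
                )
                decisions.append(
                    CodingDecision(m.mutation_id, False, None, "synonymous, LB_22 missing")
                )
            elif m.keio_lb22 < lb22_cutoff:
                decisions.append(
                    CodingDecision(
                        m.mutation_id,
                        True,
                        _categorize(m),
                        f"synonymous, LB_22={m.keio_lb22} < {lb22_cutoff}",
                    )
                )
            else:
                decisions.append(
                    CodingDecision(
                        m.mutation_id,
                        False,
                        None,
                        f"synonymous, LB_22={m.keio_lb22} >= {lb22_cutoff}",
                    )
                )
        else:
            decisions.append(
                CodingDecision(m.mutation_id, False, None, m.effect_class)
            )
    return decisions


@dataclass(frozen=True)
class RegulatoryDecision:
    mutation_id: str
    include: bool
    criteria_hit: frozenset


def regulatory_disruption_filter(
    m: AnnotatedMutation,
    mfe_rel_change_cutoff: float = 0.10,
    rbs_fold_cutoff: float = 10.0,
) -> RegulatoryDecision:
    """Flag a mutation whose precomputed scores predict regulatory disruption.

    The MFE criterion compares the mean of the two folding windows between
    mutant and wild-type context; a relative change above the cutoff fires.
    The RBS criterion fires on a fold change in predicted expression above
    the cutoff in either direction.
    """
    has_mfe = None not in (m.mfe_wt_w1, m.mfe_wt_w2, m.mfe_mut_w1, m.mfe_mut_w2)
    has_rbs = None not in (m.rbs_wt, m.rbs_mut)
    if not (has_mfe or has_rbs):
        raise ValueError(
            f"{m.mutation_id}: neither MFE quartet nor RBS pair present"
        )
    hit = set()
    if has_mfe:
        mean_wt = 0.5 * (m.mfe_wt_w1 + m.mfe_wt_w2)
        mean_mut = 0.5 * (m.mfe_mut_w1 + m.mfe_mut_w2)
        if mean_wt == 0:
            raise ValueError(
                f"{m.mutation_id}: wild-type mean MFE is 0; relative change undefined"
            )
        if abs(mean_mut - mean_wt) / abs(mean_wt) > mfe_rel_change_cutoff:
            hit.add("mfe")
    if has_rbs:
        fold = max(m.rbs_mut / m.rbs_wt, m.rbs_wt / m.rbs_mut)
        if fold > rbs_fold_cutoff:
            hit.add("rbs")
    return RegulatoryDecision(m.mutation_id, bool(hit), frozenset(hit))


def build_candidate_pools(decisions) -> tuple[list, list, list]:
    """Nested oligo pools from categorised coding decisions.

    P1 = category 1; P2 = categories {1,2}; P3 = categories {1,2,3}.
    Pools preserve input order and satisfy P1 <= P2 <= P3 by construction.
    """
    p1 = [d.mutation_id for d in decisions if d.include and d.category == 1]
    p2 = [d.mutation_id for d in decisions if d.include and d.category in (1, 2)]
    p3 = [d.mutation_id for d in decisions if d.include]
    return p1, p2, p3
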
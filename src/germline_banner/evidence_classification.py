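"""Three-way evidence classification of ClinVar aggregate records.

A record is summarized as P/LP, B/LB, or VUS.  P/LP requires a
pathogenic-family aggregate significance reviewed by multiple submitters
without conflicts or by an expert panel; B/LB requires the analogous
benign-family support.  Everything else — including pathogenic assertions from
a single submitter — is treated as VUS for reporting purposes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .clinvar_snapshot_io import ClinVarRecord

__all__ = [
    "BannerClass",
    "EvidenceDetail",
    "SignificanceFamily",
    "BannerEvidence",
    "parse_significance",
    "parse_review_status",
    "classify_evidence",
    "classify_strings",
]


class BannerClass(str, enum.Enum):
    PLP = "PLP"
    BLB = "BLB"
    VUS = "VUS"


class SignificanceFamily(str, enum.Enum):
    PATHOGENIC_FAMILY = "PATHOGENIC_FAMILY"
    BENIGN_FAMILY = "BENIGN_FAMILY"
    UNCERTAIN_FAMILY = "UNCERTAIN_FAMILY"
    CONFLICTING_FAMILY = "CONFLICTING_FAMILY"
    OTHER_FAMILY = "OTHER_FAMILY"


class EvidenceDetail(str, enum.Enum):
    EXPERT_PANEL = "EXPERT_PANEL"
    MULTIPLE_SUBMITTERS_NO_CONFLICTS = "MULTIPLE_SUBMITTERS_NO_CONFLICTS"
    SINGLE_SUBMITTER = "SINGLE_SUBMITTER"
    CONFLICTING = "CONFLICTING"
    NO_ASSERTION_CRITERIA = "NO_ASSERTION_CRITERIA"
    OTHER = "OTHER"
    #: Only for variants not present in a snapshot; never produced by parsing.
    ABSENT = "ABSENT"


#: Review tiers sufficient to support a P/LP or B/LB summary.
SUFFICIENT_DETAILS = frozenset(
    {EvidenceDetail.EXPERT_PANEL, EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS}
)


@dataclass(frozen=True, slots=True)
class BannerEvidence:
    banner_class: BannerClass
    detail: EvidenceDetail
    significance_family: SignificanceFamily


def _normalize(raw: str) -> str:
    return raw.replace("_", " ").lower()


def parse_significance(clnsig_raw: str) -> SignificanceFamily:
    """Map a verbatim CLNSIG string to its significance family.

    Total function; both the older "Conflicting_interpretations_of_pathogenicity"
    and the newer "Conflicting_classifications_of_pathogenicity" spellings land
    in the conflicting family.
    """
    s = _normalize(clnsig_raw)
    if "conflicting" in s:
        return SignificanceFamily.CONFLICTING_FAMILY
    has_path = "pathogenic" in s
    has_ben = "benign" in s
    if has_path and not has_ben:
        return SignificanceFamily.PATHOGENIC_FAMILY
    if has_ben and not has_path:
        return SignificanceFamily.BENIGN_FAMILY
    if "uncertain significance" in s:
        return SignificanceFamily.UNCERTAIN_FAMILY
    return SignificanceFamily.OTHER_FAMILY


def parse_review_status(revstat_raw: str) -> EvidenceDetail:
    """Map a verbatim CLNREVSTAT string to an evidence-detail tier.

    "practice guideline" (4-star) is treated as at-least-expert-panel: it is a
    strictly higher review tier and excluding it would demote the
    best-reviewed variants.
    """
    s = _normalize(revstat_raw)
    if "expert panel" in s or "practice guideline" in s:
        return EvidenceDetail.EXPERT_PANEL
    if "multiple submitters" in s and "no conflicts" in s:
        return EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS
    if "single submitter" in s:
        return EvidenceDetail.SINGLE_SUBMITTER
    if "conflicting" in s:
        return EvidenceDetail.CONFLICTING
    if "no assertion criteria provided" in s:
        return EvidenceDetail.NO_ASSERTION_CRITERIA
    return EvidenceDetail.OTHER


def classify_strings(clnsig_raw: str, revstat_raw: str) -> BannerEvidence:
    """Classify from the two verbatim INFO strings (stateless per record)."""
    family = parse_significance(clnsig_raw)
    detail = parse_review_status(revstat_raw)
    if family is SignificanceFamily.PATHOGENIC_FAMILY and detail in SUFFICIENT_DETAILS:
        banner = BannerClass.PLP
    elif family is SignificanceFamily.BENIGN_FAMILY and detail in SUFFICIENT_DETAILS:
        banner = BannerClass.BLB
    else:
        banner = BannerClass.VUS
    return BannerEvidence(banner_class=banner, detail=detail, significance_family=family)


def classify_evidence(record: ClinVarRecord) -> BannerEvidence:
    """Classify a parsed snapshot record."""
    return classify_strings(record.clnsig_raw, record.revstat_raw)
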
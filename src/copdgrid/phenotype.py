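"""Deterministic COPD phenotyping and control rules.

All clinical logic here is rule-based and free of randomness: input
capping to a bounded integer domain, GOLD-style ABE category assignment
(collapsed to A0/B0, A1/B1, E), the high/low rescue-use stratification,
the composite poor-control outcome, the Pseudomonas-surveillance flag,
and the eosinophil-gated treatment-concordance audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "GoldCategory",
    "UseLevel",
    "Regimen",
    "DomainBounds",
    "GRID126",
    "GRID21",
    "ExacerbationHistory",
    "ExpandedPhenotype",
    "ControlStatus",
    "AuditCode",
    "TreatmentAuditFlag",
    "TreatmentAudit",
    "cap_inputs",
    "assign_basic_phenotype",
    "assign_expanded_phenotype",
    "classify_control",
    "flag_pseudomonas_risk",
    "audit_treatment",
    "HIGH_USE_CUTOFF",
    "POOR_CONTROL_CANISTER_CUTOFF",
    "PSEUDOMONAS_B_CUTOFF",
    "PSEUDOMONAS_PR_CUTOFF",
    "EOSINOPHIL_ICS_THRESHOLD",
]

#: Canisters/year at or above which a patient counts as a high rescue user (H).
HIGH_USE_CUTOFF = 3
#: Canisters/year at or above which rescue use alone marks poor control.
POOR_CONTROL_CANISTER_CUTOFF = 3
#: Uncapped antibiotic courses/year triggering Pseudomonas surveillance.
PSEUDOMONAS_B_CUTOFF = 5
#: Predicted poor-control probability triggering Pseudomonas surveillance.
PSEUDOMONAS_PR_CUTOFF = 0.99
#: Blood eosinophil count (cells/uL) below which ICS is generally not recommended.
EOSINOPHIL_ICS_THRESHOLD = 100.0


class GoldCategory(str, Enum):
    """Collapsed GOLD ABE category (symptom scales intentionally not modelled)."""

    A0B0 = "A0/B0"
    A1B1 = "A1/B1"
    E = "E"


class UseLevel(str, Enum):
    """Rescue-inhaler use stratum: high (>=3 canisters/year) or low."""

    H = "H"
    L = "L"


class Regimen(str, Enum):
    """Maintenance inhaled regimen classes used by the treatment audit."""

    MONO = "MONO"
    LABA_LAMA = "LABA_LAMA"
    ICS_LABA = "ICS_LABA"
    TRIPLE = "TRIPLE"

    @property
    def contains_ics(self) -> bool:
        return self in (Regimen.ICS_LABA, Regimen.TRIPLE)


@dataclass(frozen=True)
class DomainBounds:
    """Inclusive upper bounds of the integer (a, b) input domain."""

    a_max: int
    b_max: int
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.a_max < 0 or self.b_max < 0:
            raise ValueError("domain bounds must be nonnegative")

    @property
    def n_cells(self) -> int:
        return (self.a_max + 1) * (self.b_max + 1)


#: High-resolution domain: a in [0, 20], b in [0, 5] -> 126 cells.
GRID126 = DomainBounds(20, 5, "grid126")
#: Streamlined domain: a in [0, 6], b in [0, 2] -> 21 cells.
GRID21 = DomainBounds(6, 2, "grid21")


@dataclass(frozen=True)
class ExacerbationHistory:
    """Moderate/severe exacerbation counts over the last 12 months."""

    moderate_count: int = 0
    severe_count: int = 0

    def __post_init__(self) -> None:
        if self.moderate_count < 0 or self.severe_count < 0:
            raise ValueError("exacerbation counts must be nonnegative")

    @property
    def any_exacerbation(self) -> bool:
        return self.moderate_count >= 1 or self.severe_count >= 1


@dataclass(frozen=True)
class ExpandedPhenotype:
    """GOLD category crossed with the rescue-use stratum, e.g. ``A1/B1-H``."""

    gold: GoldCategory
    use_level: UseLevel

    @property
    def label(self) -> str:
        return f"{self.gold.value}-{self.use_level.value}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class ControlStatus:
    """Poor-control verdict plus the identifiers of every rule that fired."""

    poorly_controlled: bool
    triggering_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.poorly_controlled != bool(self.triggering_rules):
            raise ValueError("poorly_controlled must mirror triggering_rules")


class AuditCode(str, Enum):
    ICS_NOT_RECOMMENDED = "ICS_NOT_RECOMMENDED"
    ESCALATE_TO_DUAL_BRONCHODILATION = "ESCALATE_TO_DUAL_BRONCHODILATION"
    CONSIDER_TRIPLE_THERAPY = "CONSIDER_TRIPLE_THERAPY"
    CONCORDANT = "CONCORDANT"


@dataclass(frozen=True)
class TreatmentAuditFlag:
    code: AuditCode
    rationale: str = ""


@dataclass(frozen=True)
class TreatmentAudit:
    """Audit outcome; ``auditable`` is False when eosinophil data are missing."""

    auditable: bool
    flags: tuple[TreatmentAuditFlag, ...] = ()

    @property
    def codes(self) -> tuple[AuditCode, ...]:
        return tuple(f.code for f in self.flags)

    @property
    def concordant(self) -> bool:
        return self.auditable and self.codes == (AuditCode.CONCORDANT,)


def _check_count(value, name: str) -> int:
    if isinstance(value, bool) or not isinstance(value, (int,)):
        try:
            import numpy as _np

            if isinstance(value, _np.integer):
                value = int(value)
            else:
                raise TypeError
        except (TypeError, ImportError):
            raise TypeError(f"{name} must be an integer, got {value!r}") from None
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value}")
    return int(value)


def cap_inputs(a_raw: int, b_raw: int, bounds: DomainBounds) -> tuple[int, int, bool]:
    """Truncate raw annual counts to the bounded domain.

    Returns ``(a, b, capped)`` with ``a = min(a_raw, a_max)``,
    ``b = min(b_raw, b_max)``. Idempotent by construction.
    """
    a_raw = _check_count(a_raw, "a_raw")
    b_raw = _check_count(b_raw, "b_raw")
    a = min(a_raw, bounds.a_max)
    b = min(b_raw, bounds.b_max)
    return a, b, (a != a_raw or b != b_raw)


def assign_basic_phenotype(
    history: Optional[ExacerbationHistory] = None,
    b: Optional[int] = None,
) -> GoldCategory:
    """Assign the collapsed GOLD ABE category.

    With an explicit exacerbation ``history`` (which takes precedence):
    E if >=2 moderate or >=1 severe; A1/B1 if exactly one moderate and no
    severe; otherwise A0/B0. With only the antibiotic-course proxy ``b``:
    E if b >= 2, A1/B1 if b == 1, A0/B0 if b == 0.
    """
    if history is not None:
        if history.severe_count >= 1 or history.moderate_count >= 2:
            return GoldCategory.E
        if history.moderate_count == 1:
            return GoldCategory.A1B1
        return GoldCategory.A0B0
    if b is None:
        raise ValueError("either an exacerbation history or the proxy b is required")
    b = _check_count(b, "b")
    if b >= 2:
        return GoldCategory.E
    if b == 1:
        return GoldCategory.A1B1
    return GoldCategory.A0B0


def assign_expanded_phenotype(
    a: int,
    b: Optional[int] = None,
    history: Optional[ExacerbationHistory] = None,
) -> ExpandedPhenotype:
    """GOLD category plus high/low rescue-use stratum (H iff a >= 3).

    The H/L cutoff (3) lies below both domain caps on ``a`` (6 and 20) and
    the proxy cutoff for E (2) lies at or below both caps on ``b``, so the
    assignment is invariant under capping by either grid.
    """
    a = _check_count(a, "a")
    gold = assign_basic_phenotype(history=history, b=b)
    level = UseLevel.H if a >= HIGH_USE_CUTOFF else UseLevel.L
    return ExpandedPhenotype(gold, level)


def classify_control(record) -> ControlStatus:
    """Composite poor-control outcome.

    Poorly controlled iff any moderate exacerbation, any severe
    exacerbation, or >=3 rescue canisters/year (uncapped). When the record
    has no exacerbation history the antibiotic proxy ``b_raw`` stands in
    (b >= 1 treated as at least one moderate exacerbation).
    """
    a_raw = _check_count(record.a_raw, "a_raw")
    rules: list[str] = []
    history = getattr(record, "history", None)
    if history is not None:
        if history.moderate_count >= 1:
            rules.append("moderate_exacerbation")
        if history.severe_count >= 1:
            rules.append("severe_exacerbation")
    else:
        b_raw = _check_count(record.b_raw, "b_raw")
        if b_raw >= 1:
            rules.append("moderate_exacerbation_proxy")
    if a_raw >= POOR_CONTROL_CANISTER_CUTOFF:
        rules.append("rescue_use")
    return ControlStatus(bool(rules), tuple(rules))


def flag_pseudomonas_risk(b_raw: int, pr: float) -> bool:
    """Surveillance flag: uncapped b_raw >= 5 AND predicted Pr >= 0.99.

    Deliberately uses the uncapped course count: the streamlined 21-cell
    domain caps b at 2 and would otherwise mask this severe profile. The
    rescue-use stratum plays no role (both H and L qualify).
    """
    b_raw = _check_count(b_raw, "b_raw")
    if not (0.0 < pr < 1.0):
        raise ValueError(f"pr must be in (0, 1), got {pr}")
    return b_raw >= PSEUDOMONAS_B_CUTOFF and pr >= PSEUDOMONAS_PR_CUTOFF


def audit_treatment(record) -> TreatmentAudit:
    """Guideline-concordance audit of the maintenance regimen.

    Encodes three discrepancy rules gated on blood eosinophils:

    * ``ICS_NOT_RECOMMENDED`` — an ICS-containing regimen with current
      eosinophils < 100 cells/uL and no historical count >= 100 (a
      previously recorded high count justifies continued ICS).
    * ``ESCALATE_TO_DUAL_BRONCHODILATION`` — an exacerbator (gold != A0/B0)
      on bronchodilator monotherapy, or on ICS+LABA with eosinophils < 100,
      where dual bronchodilation is preferred.
    * ``CONSIDER_TRIPLE_THERAPY`` — gold E with eosinophils >= 100 on a
      regimen lacking ICS.

    Records without a current eosinophil count are reported unauditable
    rather than raising.
    """
    eos = getattr(record, "eosinophils_current", None)
    if eos is None or (isinstance(eos, float) and eos != eos):
        return TreatmentAudit(auditable=False, flags=())
    regimen = record.regimen
    if isinstance(regimen, str):
        regimen = Regimen(regimen)
    gold = assign_basic_phenotype(
        history=getattr(record, "history", None),
        b=getattr(record, "b_raw", None),
    )
    prior = getattr(record, "eosinophils_prior_max", None)
    if isinstance(prior, float) and prior != prior:
        prior = None
    low_eos = eos < EOSINOPHIL_ICS_THRESHOLD
    prior_high = prior is not None and prior >= EOSINOPHIL_ICS_THRESHOLD

    flags: list[TreatmentAuditFlag] = []
    if regimen.contains_ics and low_eos and not prior_high:
        flags.append(
            TreatmentAuditFlag(
                AuditCode.ICS_NOT_RECOMMENDED,
                f"ICS-containing regimen with eosinophils {eos:.0f} cells/uL "
                "and no prior count >= 100",
            )
        )
    if gold != GoldCategory.A0B0 and (
        regimen == Regimen.MONO or (regimen == Regimen.ICS_LABA and low_eos)
    ):
        flags.append(
            TreatmentAuditFlag(
                AuditCode.ESCALATE_TO_DUAL_BRONCHODILATION,
                f"exacerbator ({gold.value}) on {regimen.value}; "
                "dual bronchodilation preferred",
            )
        )
    if gold == GoldCategory.E and not low_eos and not regimen.contains_ics:
        flags.append(
            TreatmentAuditFlag(
                AuditCode.CONSIDER_TRIPLE_THERAPY,
                f"frequent exacerbator with eosinophils {eos:.0f} cells/uL "
                "on ICS-free regimen",
            )
        )
    if not flags:
        flags.append(TreatmentAuditFlag(AuditCode.CONCORDANT, "no rule fired"))
    return TreatmentAudit(auditable=True, flags=tuple(flags))
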
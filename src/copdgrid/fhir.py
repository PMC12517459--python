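"""FHIR-R5-shaped clinical decision support payloads.

Each patient yields a bundle of up to four resources — RiskAssessment
(the predicted probability and its (a, b) rationale), DetectedIssue
(threshold-driven recommendations, present only when a rule fires),
Condition (the phenotype as a disease-state coding) and Provenance
(model version, coefficient digest, timestamp). The package emits
schema-shaped JSON documents; running an external FHIR validator is out
of scope.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import ModelCoefficients, RiskEstimate
from .phenotype import (
    AuditCode,
    ExpandedPhenotype,
    TreatmentAuditFlag,
    cap_inputs,
    flag_pseudomonas_risk,
    GRID126,
    DomainBounds,
)

__all__ = ["AlertConfig", "FhirBundle", "build_fhir_bundle", "ConsistencyError"]

log = logging.getLogger(__name__)

#: SNOMED-CT-style placeholder codings for the phenotype Condition;
#: deployments substitute their terminology through `condition_codes`.
_DEFAULT_CONDITION_CODES = {
    "A0/B0-L": "copd-a0b0-low-rescue-use",
    "A0/B0-H": "copd-a0b0-high-rescue-use",
    "A1/B1-L": "copd-a1b1-low-rescue-use",
    "A1/B1-H": "copd-a1b1-high-rescue-use",
    "E-L": "copd-e-low-rescue-use",
    "E-H": "copd-e-high-rescue-use",
}


class ConsistencyError(ValueError):
    """The risk estimate does not correspond to the record's counts."""


@dataclass(frozen=True)
class AlertConfig:
    """Alert thresholds for DetectedIssue generation.

    ``inhaler_threshold`` is the first alerting canister count (default 4,
    i.e. strictly more than 3 inhalers/year); ``antibiotic_threshold`` the
    first alerting course count (default 2). ``pr_flag`` is the
    operational poor-control flag (Pr > 0.50) and ``pr_priority`` the
    higher-risk prioritization level (Pr > 0.70).
    """

    inhaler_threshold: int = 4
    antibiotic_threshold: int = 2
    pr_flag: float = 0.50
    pr_priority: float = 0.70

    def __post_init__(self) -> None:
        if not (0.0 < self.pr_flag <= self.pr_priority < 1.0):
            raise ValueError("need 0 < pr_flag <= pr_priority < 1")


@dataclass(frozen=True)
class FhirBundle:
    """Ordered resource documents for one patient."""

    patient_ref: str
    risk_assessment: dict
    condition: dict
    provenance: dict
    detected_issue: Optional[dict] = None

    @property
    def resources(self) -> tuple[dict, ...]:
        out = [self.risk_assessment]
        if self.detected_issue is not None:
            out.append(self.detected_issue)
        out.append(self.condition)
        out.append(self.provenance)
        return tuple(out)

    def to_dict(self) -> dict:
        return {
            "resourceType": "Bundle",
            "type": "collection",
            "entry": [{"resource": r} for r in self.resources],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def detected_issue_rules(
    a_raw: int,
    b_raw: int,
    pr: float,
    audit_codes: Sequence[AuditCode],
    config: AlertConfig,
) -> list[str]:
    """The alert rules fired by one patient's state (pure function)."""
    rules = []
    if a_raw >= config.inhaler_threshold:
        rules.append("rescue_inhaler_overuse")
    if b_raw >= config.antibiotic_threshold:
        rules.append("repeated_antibiotic_courses")
    if pr > config.pr_flag:
        rules.append("predicted_poor_control")
    if pr > config.pr_priority:
        rules.append("high_risk_priority")
    if flag_pseudomonas_risk(b_raw, pr):
        rules.append("pseudomonas_surveillance")
    for code in audit_codes:
        if code != AuditCode.CONCORDANT:
            rules.append(f"treatment_audit:{code.value}")
    return rules


_RULE_TEXT = {
    "rescue_inhaler_overuse": "More than 3 rescue inhaler canisters dispensed "
                              "in the last year; reassess maintenance therapy.",
    "repeated_antibiotic_courses": "At least 2 respiratory antibiotic courses "
                                   "in the last year; review exacerbation control.",
    "predicted_poor_control": "Predicted probability of poor control exceeds "
                              "the operational 0.50 flag.",
    "high_risk_priority": "Predicted probability exceeds the 0.70 priority "
                          "level; schedule proactive review.",
    "pseudomonas_surveillance": "High predicted risk with >=5 antibiotic "
                                "courses/year; prioritize sputum culture "
                                "screening and consider pulmonology referral.",
}


def build_fhir_bundle(
    record,
    estimate: RiskEstimate,
    phenotype: ExpandedPhenotype,
    flags: Sequence[TreatmentAuditFlag] = (),
    config: AlertConfig = AlertConfig(),
    coeffs: Optional[ModelCoefficients] = None,
    bounds: DomainBounds = GRID126,
    model_version: str = "copdgrid-0.1.0",
    timestamp: Optional[str] = None,
    condition_codes: Optional[dict] = None,
) -> FhirBundle:
    """Assemble the per-patient decision-support bundle.

    RiskAssessment, Condition and Provenance are always present;
    DetectedIssue appears iff at least one alert rule fires (inhaler or
    antibiotic threshold, probability flags, Pseudomonas surveillance, or
    a non-concordant treatment audit). Raises ``ConsistencyError`` when
    the estimate's (a, b) does not equal the record's counts capped to
    ``bounds``.
    """
    a_cap, b_cap, _ = cap_inputs(record.a_raw, record.b_raw, bounds)
    if (estimate.a, estimate.b) != (a_cap, b_cap):
        raise ConsistencyError(
            f"estimate cell ({estimate.a}, {estimate.b}) != record's capped "
            f"counts ({a_cap}, {b_cap})"
        )
    ts = timestamp or _dt.datetime.now(_dt.timezone.utc).isoformat()
    pid = str(record.id)
    subject = {"reference": f"Patient/{pid}"}
    codes = condition_codes or _DEFAULT_CONDITION_CODES

    risk_assessment = {
        "resourceType": "RiskAssessment",
        "status": "final",
        "subject": subject,
        "method": {"text": "deterministic bijective logistic risk grid"},
        "basis": [
            {"display": f"annual rescue canisters a={estimate.a}"},
            {"display": f"annual respiratory antibiotic courses b={estimate.b}"},
        ],
        "prediction": [
            {
                "outcome": {"text": "poor COPD control"},
                "probabilityDecimal": round(estimate.pr, 10),
            }
        ],
    }
    condition = {
        "resourceType": "Condition",
        "subject": subject,
        "clinicalStatus": {"coding": [{"code": "active"}]},
        "code": {
            "coding": [
                {
                    "system": "urn:copdgrid:phenotype",
                    "code": codes.get(phenotype.label, phenotype.label),
                    "display": f"COPD phenotype {phenotype.label}",
                }
            ],
            "text": f"COPD, GOLD {phenotype.gold.value}, "
                    f"{'high' if phenotype.use_level.value == 'H' else 'low'} "
                    "rescue inhaler use",
        },
    }
    provenance = {
        "resourceType": "Provenance",
        "target": [{"reference": f"Patient/{pid}"}],
        "recorded": ts,
        "agent": [
            {
                "type": {"text": "model"},
                "who": {"display": model_version},
            }
        ],
        "entity": [
            {
                "role": "source",
                "what": {
                    "display": "coefficients:"
                    + (coeffs.digest() if coeffs is not None else "unspecified")
                },
            }
        ],
    }

    audit_codes = [f.code for f in flags]
    rules = detected_issue_rules(record.a_raw, record.b_raw, estimate.pr,
                                 audit_codes, config)
    detected_issue = None
    if rules:
        recommendations = [
            _RULE_TEXT.get(r, next((f.rationale for f in flags
                                    if r.endswith(f.code.value)), r))
            for r in rules
        ]
        detected_issue = {
            "resourceType": "DetectedIssue",
            "status": "preliminary",
            "subject": subject,
            "severity": "high" if estimate.pr > config.pr_priority else "moderate",
            "code": {"text": "COPD control alert"},
            "evidence": [{"detail": [{"display": r}]} for r in rules],
            "mitigation": [{"action": {"text": t}} for t in recommendations],
        }
        log.info("patient %s: detected issue rules=%s", pid, rules)
    else:
        log.info("patient %s: no alert rules fired", pid)

    return FhirBundle(
        patient_ref=pid,
        risk_assessment=risk_assessment,
        condition=condition,
        provenance=provenance,
        detected_issue=detected_issue,
    )
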
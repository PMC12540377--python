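"""Rule-based cognitive staging: NC, SCD, SCD-plus, MCI.

The four ordered stages are assigned from an objective scale battery and a
subjective-report questionnaire:

* MCI (actuarial, Jak-Bondi style): impaired scores on >= 2 indicators of one
  cognitive domain, or >= 1 impaired test in each of the three domains
  (memory, execution, language), or FAQ >= 9.  A score is "impaired" when it
  is worse than ``z_cutoff`` standard deviations from its normative mean in
  the disadvantaged direction (default z = 1, a common actuarial choice; the
  threshold is configurable because published operationalizations vary).
* SCD: a chief complaint of long-term/sustained cognitive decline not tied to
  an acute event, without meeting MCI criteria.
* SCD-plus: SCD plus the high-risk profile — concern about the decline
  (condition 4, mandatory) together with at least one of the seven other
  risk conditions (memory-specific decline; onset < 5 years; onset age >= 60;
  feeling worse than peers; informant confirmation; ApoE-e4 carriage; AD
  biomarker positivity).
* NC: none of the above.

Condition values may be unknown (``None``); an unknown never satisfies a rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

__all__ = [
    "Stage",
    "Score",
    "ScaleBattery",
    "SubjectiveReport",
    "CognitionStage",
    "is_impaired",
    "classify_mci",
    "classify_stage",
]

MEMORY = ("avlt_long_delay", "avlt_recognition")
EXECUTION = ("stt_a", "stt_b")
LANGUAGE = ("aft", "bnt")
DOMAINS = {"memory": MEMORY, "execution": EXECUTION, "language": LANGUAGE}

FAQ_MCI_CUTOFF = 9


class StagingError(ValueError):
    """A subject cannot be staged (missing score or norm)."""


class Stage(IntEnum):
    """Ordered cognitive stages, worst last."""

    NC = 0
    SCD = 1
    SCD_PLUS = 2
    MCI = 3


@dataclass(frozen=True)
class Score:
    """One test score with its normative reference.

    ``higher_better`` is True for accuracy-like scores (AVLT, AFT, BNT) and
    False for timed scores where longer is worse (STT-A, STT-B).
    """

    value: float
    norm_mean: float
    norm_sd: float
    higher_better: bool = True

    def __post_init__(self) -> None:
        if self.norm_sd <= 0:
            raise StagingError(f"norm sd must be positive, got {self.norm_sd}")


@dataclass(frozen=True)
class ScaleBattery:
    """The six domain scores plus the FAQ total."""

    avlt_long_delay: Score
    avlt_recognition: Score
    stt_a: Score
    stt_b: Score
    aft: Score
    bnt: Score
    faq: float

    def __post_init__(self) -> None:
        missing = [f for f in (*MEMORY, *EXECUTION, *LANGUAGE)
                   if getattr(self, f) is None]
        if missing or self.faq is None:
            missing += ["faq"] if self.faq is None else []
            raise StagingError(f"missing battery scores: {', '.join(missing)}")
        if self.faq < 0:
            raise StagingError("FAQ total cannot be negative")


@dataclass(frozen=True)
class SubjectiveReport:
    """Subjective complaint flags; ``None`` means unknown and never fires a rule."""

    complaint: bool | None = None
    acute_onset: bool | None = None
    memory_only_decline: bool | None = None  # condition 1
    onset_years: float | None = None         # condition 2: < 5 years
    age_at_onset: float | None = None        # condition 3: >= 60
    concern: bool | None = None               # condition 4 (mandatory for SCD-plus)
    worse_than_peers: bool | None = None      # condition 5
    informant_confirms: bool | None = None    # condition 6
    apoe_e4_carrier: bool | None = None       # condition 7
    ad_biomarker_positive: bool | None = None  # condition 8

    def __post_init__(self) -> None:
        if self.onset_years is not None and self.onset_years < 0:
            raise ValueError("onset_years cannot be negative")


@dataclass(frozen=True)
class CognitionStage:
    stage: Stage
    trace: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.stage is not Stage.NC and not self.trace:
            raise ValueError("non-NC stage requires a rationale trace")


def is_impaired(
    score: float,
    norm_mean: float,
    norm_sd: float,
    higher_better: bool = True,
    z_cutoff: float = 1.0,
) -> bool:
    """Is a score worse than ``z_cutoff`` SDs from the norm in the bad direction?"""
    if norm_sd <= 0:
        raise StagingError("norm sd must be positive")
    z = (score - norm_mean) / norm_sd
    return z < -z_cutoff if higher_better else z > z_cutoff


def _score_impaired(s: Score, z_cutoff: float) -> bool:
    return is_impaired(s.value, s.norm_mean, s.norm_sd, s.higher_better, z_cutoff)


def classify_mci(battery: ScaleBattery, z_cutoff: float = 1.0) -> tuple[bool, list[str]]:
    """Actuarial MCI test; returns (flag, fired rules)."""
    fired: list[str] = []
    impaired = {
        name: _score_impaired(getattr(battery, name), z_cutoff)
        for domain in DOMAINS.values() for name in domain
    }
    domains_hit = 0
    for domain, tests in DOMAINS.items():
        n_imp = sum(impaired[t] for t in tests)
        if n_imp >= 2:
            fired.append(f"mci:two_impaired_in_{domain}")
        if n_imp >= 1:
            domains_hit += 1
    if domains_hit == len(DOMAINS):
        fired.append("mci:one_impaired_in_each_domain")
    if battery.faq >= FAQ_MCI_CUTOFF:
        fired.append(f"mci:faq>={FAQ_MCI_CUTOFF}")
    return bool(fired), fired


def _scd_plus_conditions(rep: SubjectiveReport) -> list[str]:
    """The seven non-mandatory high-risk conditions that hold (unknown = no)."""
    fired = []
    if rep.memory_only_decline is True:
        fired.append("scd+:memory_only_decline")
    if rep.onset_years is not None and rep.onset_years < 5:
        fired.append("scd+:onset<5y")
    if rep.age_at_onset is not None and rep.age_at_onset >= 60:
        fired.append("scd+:onset_age>=60")
    if rep.worse_than_peers is True:
        fired.append("scd+:worse_than_peers")
    if rep.informant_confirms is True:
        fired.append("scd+:informant_confirms")
    if rep.apoe_e4_carrier is True:
        fired.append("scd+:apoe_e4")
    if rep.ad_biomarker_positive is True:
        fired.append("scd+:ad_biomarker")
    return fired


def classify_stage(
    subjective: SubjectiveReport,
    battery: ScaleBattery,
    z_cutoff: float = 1.0,
    concern_alone_suffices: bool = False,
) -> CognitionStage:
    """Assign the subject's stage with a trace of the rules that fired.

    Precedence: MCI dominates (a subject meeting MCI criteria is MCI whatever
    they report); then the subjective-decline ladder.  SCD requires a
    complaint of sustained decline that is affirmatively *not* acute-onset.
    SCD-plus additionally requires concern (mandatory condition 4) and — by
    default — at least one of the other seven conditions;
    ``concern_alone_suffices`` switches to the reading where condition 4 by
    itself promotes.
    """
    mci, mci_trace = classify_mci(battery, z_cutoff)
    if mci:
        return CognitionStage(Stage.MCI, tuple(mci_trace))

    if subjective.complaint is True and subjective.acute_onset is False:
        trace = ["scd:sustained_complaint", "scd:not_acute"]
        if subjective.concern is True:
            others = _scd_plus_conditions(subjective)
            if others or concern_alone_suffices:
                return CognitionStage(
                    Stage.SCD_PLUS, tuple(trace + ["scd+:concern"] + others)
                )
        return CognitionStage(Stage.SCD, tuple(trace))

    return CognitionStage(Stage.NC)
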
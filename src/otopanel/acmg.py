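"""ACMG/AMP evidence criteria and combining rules (five-class output).

Evidence items are coded criteria: pathogenic-side PVS1, PS1-PS4, PM1-PM6,
PP1-PP5 and benign-side BA1, BS1-BS4, BP1-BP7.  Each code carries a default
strength implied by its prefix (PVS = very strong, PS/BS = strong,
PM = moderate, PP/BP = supporting, BA = stand-alone), but a criterion may be
applied at a different strength, written ``STRENGTH(code)`` -- e.g.
``PS(PM3)`` applies PM3 at strong, ``PP(PM2)`` applies PM2 at supporting.
Nesting is rejected.

:func:`acmg_classify` is a total, deterministic function of the criteria
multiset: it counts applied strengths on each side, fires the guideline
combining rules, and resolves conflicts (both sides firing) to class 3
(uncertain significance), as it does when no rule fires.  A manual override
(with justification) may replace the rule-derived class; the rule-derived
class and the fired rule are retained so the deviation is never silent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

# class codes: 1 benign .. 5 pathogenic
BENIGN, LIKELY_BENIGN, VUS, LIKELY_PATHOGENIC, PATHOGENIC = 1, 2, 3, 4, 5

CLASS_NAMES = {
    BENIGN: "benign",
    LIKELY_BENIGN: "likely_benign",
    VUS: "uncertain_significance",
    LIKELY_PATHOGENIC: "likely_pathogenic",
    PATHOGENIC: "pathogenic",
}

STAND_ALONE = "stand_alone"
VERY_STRONG = "very_strong"
STRONG = "strong"
MODERATE = "moderate"
SUPPORTING = "supporting"

PATHOGENIC_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = frozenset(
    ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
)
ALL_CODES = PATHOGENIC_CODES | BENIGN_CODES

_PREFIX_STRENGTH = {
    "PVS": VERY_STRONG,
    "PS": STRONG,
    "PM": MODERATE,
    "PP": SUPPORTING,
    "BA": STAND_ALONE,
    "BS": STRONG,
    "BP": SUPPORTING,
}

_TOKEN_RE = re.compile(r"^(?:(?P<wrap>PVS|PS|PM|PP|BA|BS|BP)\((?P<inner>[A-Z0-9]+)\))$|^(?P<bare>[A-Z0-9]+)$")


class CriteriaParseError(ValueError):
    pass


def default_strength(code: str) -> str:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _PREFIX_STRENGTH[prefix]
    raise CriteriaParseError(f"unknown criterion code {code!r}")


@dataclass(frozen=True)
class Criterion:
    code: str
    strength: str

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise CriteriaParseError(f"unknown criterion code {self.code!r}")
        if self.strength not in (STAND_ALONE, VERY_STRONG, STRONG, MODERATE, SUPPORTING):
            raise CriteriaParseError(f"unknown strength {self.strength!r}")

    @property
    def benign_side(self) -> bool:
        return self.code in BENIGN_CODES


def criterion(code: str) -> Criterion:
    """A criterion at its default (prefix-implied) strength."""
    return Criterion(code, default_strength(code))


def parse_criterion(token: str) -> Criterion:
    token = token.strip()
    m = _TOKEN_RE.match(token)
    if not m:
        raise CriteriaParseError(f"cannot parse criterion token {token!r}")
    if m.group("wrap"):
        inner = m.group("inner")
        if "(" in inner or inner not in ALL_CODES:
            raise CriteriaParseError(f"cannot parse criterion token {token!r}")
        return Criterion(inner, _PREFIX_STRENGTH[m.group("wrap")])
    bare = m.group("bare")
    if bare not in ALL_CODES:
        raise CriteriaParseError(f"unknown criterion token {token!r}")
    return Criterion(bare, default_strength(bare))


def parse_criteria(tokens: Iterable[str]) -> list[Criterion]:
    """Parse a list of tokens like ``["PVS1", "PS(PM3)", "PP3"]``."""
    return [parse_criterion(t) for t in tokens]


@dataclass(frozen=True)
class AcmgResult:
    classification: int  # 1..5
    fired_rule: str
    criteria: tuple[Criterion, ...] = ()
    override: "Override | None" = None

    @property
    def class_name(self) -> str:
        return CLASS_NAMES[self.classification]

    @property
    def rule_classification(self) -> int:
        """The class the combining rules produced, ignoring any override."""
        return self.override.from_class if self.override else self.classification


@dataclass(frozen=True)
class Override:
    from_class: int
    to_class: int
    justification: str


def apply_override(result: AcmgResult, to_class: int, justification: str) -> AcmgResult:
    """Manually override a rule-derived class, keeping an audit record."""
    if not justification:
        raise ValueError("an override requires a justification")
    return AcmgResult(
        classification=to_class,
        fired_rule=result.fired_rule,
        criteria=result.criteria,
        override=Override(result.classification, to_class, justification),
    )


def _counts(criteria: Sequence[Criterion]) -> tuple[dict[str, int], dict[str, int]]:
    path = {VERY_STRONG: 0, STRONG: 0, MODERATE: 0, SUPPORTING: 0}
    benign = {STAND_ALONE: 0, STRONG: 0, SUPPORTING: 0}
    for c in criteria:
        if c.benign_side:
            # the guideline defines no very-strong/moderate benign level;
            # anything at or above strong counts as BS, else as BP,
            # stand-alone stays stand-alone
            if c.strength == STAND_ALONE:
                benign[STAND_ALONE] += 1
            elif c.strength in (VERY_STRONG, STRONG, MODERATE):
                benign[STRONG] += 1
            else:
                benign[SUPPORTING] += 1
        else:
            strength = VERY_STRONG if c.strength == STAND_ALONE else c.strength
            path[strength] += 1
    return path, benign


def _pathogenic_rule(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if pvs >= 2:
        return ">=2 very-strong"
    if pvs == 1:
        if ps >= 1:
            return "1 very-strong + >=1 strong"
        if pm >= 2:
            return "1 very-strong + >=2 moderate"
        if pm == 1 and pp == 1:
            return "1 very-strong + 1 moderate + 1 supporting"
        if pp >= 2:
            return "1 very-strong + >=2 supporting"
    if ps >= 2:
        return ">=2 strong"
    if ps == 1:
        if pm >= 3:
            return "1 strong + >=3 moderate"
        if pm == 2 and pp >= 2:
            return "1 strong + 2 moderate + >=2 supporting"
        if pm == 1 and pp >= 4:
            return "1 strong + 1 moderate + >=4 supporting"
    return None


def _likely_pathogenic_rule(pvs: int, ps: int, pm: int, pp: int) -> str | None:
    if pvs == 1 and pm == 1:
        return "1 very-strong + 1 moderate"
    if ps == 1 and 1 <= pm <= 2:
        return "1 strong + 1-2 moderate"
    if ps == 1 and pp >= 2:
        return "1 strong + >=2 supporting"
    if pm >= 3:
        return ">=3 moderate"
    if pm == 2 and pp >= 2:
        return "2 moderate + >=2 supporting"
    if pm == 1 and pp >= 4:
        return "1 moderate + >=4 supporting"
    return None


def acmg_classify(criteria: Sequence[Criterion]) -> AcmgResult:
    """Combine criteria into the five-class result.

    Pathogenic and benign evidence may co-occur; if rules fire on both
    sides the result is class 3 with rule "conflicting_evidence".  With no
    criteria, or criteria insufficient for any rule, the result is class 3.
    """
    path, benign = _counts(criteria)
    pvs, ps, pm, pp = (
        path[VERY_STRONG],
        path[STRONG],
        path[MODERATE],
        path[SUPPORTING],
    )
    ba, bs, bp = benign[STAND_ALONE], benign[STRONG], benign[SUPPORTING]

    path_class = path_rule = None
    rule = _pathogenic_rule(pvs, ps, pm, pp)
    if rule:
        path_class, path_rule = PATHOGENIC, f"pathogenic: {rule}"
    else:
        rule = _likely_pathogenic_rule(pvs, ps, pm, pp)
        if rule:
            path_class, path_rule = LIKELY_PATHOGENIC, f"likely_pathogenic: {rule}"

    benign_class = benign_rule = None
    if ba >= 1:
        benign_class, benign_rule = BENIGN, "benign: stand-alone"
    elif bs >= 2:
        benign_class, benign_rule = BENIGN, "benign: >=2 strong"
    elif bs == 1 and bp >= 1:
        benign_class, benign_rule = LIKELY_BENIGN, "likely_benign: 1 strong + 1 supporting"
    elif bp >= 2:
        benign_class, benign_rule = LIKELY_BENIGN, "likely_benign: >=2 supporting"

    frozen = tuple(criteria)
    if path_class and benign_class:
        return AcmgResult(VUS, "conflicting_evidence", frozen)
    if path_class:
        return AcmgResult(path_class, path_rule, frozen)
    if benign_class:
        return AcmgResult(benign_class, benign_rule, frozen)
    return AcmgResult(VUS, "no_rule_fired", frozen)


def classify_tokens(tokens: Iterable[str]) -> AcmgResult:
    """Convenience wrapper: parse tokens, then classify."""
    return acmg_classify(parse_criteria(tokens))
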
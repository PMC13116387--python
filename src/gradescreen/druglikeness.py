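"""Seven-criterion weighted drug-likeness scoring and A–F grading.

Each compound receives seven component scores on [0, 1] — Lipinski, Veber,
Ghose, QED, synthetic accessibility, rule-based ADMET, and structural
alerts — which are combined by a weighted linear model

    S_total = 0.15·S_Lipinski + 0.10·S_Veber + 0.10·S_Ghose + 0.20·S_QED
            + 0.15·S_SA + 0.20·S_ADMET + 0.10·S_alerts

and mapped onto five left-closed grade bands:

    A ≥ 0.85 > B ≥ 0.70 > C ≥ 0.55 > D ≥ 0.40 > F.

Rule-based dimensions (Lipinski/Veber/Ghose/ADMET) are scored as the
fraction of their individual criteria passed, giving graded rather than
binary values; QED is used raw; the SA score is reversed onto [0, 1] so
that higher means easier to make; each structural alert costs 0.5, floored
at 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .compound_io import CompoundRecord
from .descriptors import DescriptorSet, compute_descriptors

GRADES = ("A", "B", "C", "D", "F")

#: Lower edges of the A, B, C, D bands; anything below the last is F.
GRADE_BOUNDS = {"A": 0.85, "B": 0.70, "C": 0.55, "D": 0.40}

COMPONENT_NAMES = ("lipinski", "veber", "ghose", "qed", "sa", "admet", "pains")


@dataclass(frozen=True)
class WeightVector:
    """Component weights; must be non-negative and sum to 1."""

    lipinski: float = 0.15
    veber: float = 0.10
    ghose: float = 0.10
    qed: float = 0.20
    sa: float = 0.15
    admet: float = 0.20
    pains: float = 0.10

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in COMPONENT_NAMES)

    def validate(self) -> None:
        vals = self.as_tuple()
        if any(w < 0 for w in vals):
            raise ValueError(f"negative weight in {vals}")
        if abs(sum(vals) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {sum(vals)!r}")


@dataclass(frozen=True)
class ComponentScores:
    lipinski: float
    veber: float
    ghose: float
    qed: float
    sa: float
    admet: float
    pains: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in COMPONENT_NAMES)


@dataclass(frozen=True)
class ScoreCard:
    identifier: str
    components: ComponentScores
    weights: WeightVector
    s_total: float
    grade: str


@dataclass(frozen=True)
class GradeSummary:
    counts: dict[str, int]
    percentages: dict[str, float]  # one decimal, half-up
    mean_total: float
    median_total: float
    n: int = field(default=0)


def _fraction_passed(checks: list[bool]) -> float:
    return sum(checks) / len(checks)


def score_lipinski(d: DescriptorSet) -> float:
    """Fraction of the rule-of-five criteria passed (MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10)."""
    return _fraction_passed([d.mw <= 500, d.logp <= 5, d.hbd <= 5, d.hba <= 10])


def score_veber(d: DescriptorSet) -> float:
    """Fraction of Veber's two oral-bioavailability criteria (RotB ≤ 10, TPSA ≤ 140 Å²)."""
    return _fraction_passed([d.rotb <= 10, d.tpsa <= 140])


def score_ghose(d: DescriptorSet) -> float:
    """Fraction of Ghose's four drug-like property windows."""
    return _fraction_passed(
        [
            160 <= d.mw <= 480,
            -0.4 <= d.logp <= 5.6,
            40 <= d.molar_refractivity <= 130,
            20 <= d.atom_count <= 70,
        ]
    )


def score_qed(d: DescriptorSet) -> float:
    """QED passes through unchanged (already on [0, 1])."""
    return d.qed_raw


def score_sa(d: DescriptorSet) -> float:
    """Reverse the 1–10 synthetic-accessibility scale onto [0, 1], higher = easier."""
    raw = d.sa_raw
    if not 1.0 <= raw <= 10.0:
        warnings.warn(f"SA score {raw} outside [1, 10]; clamping", stacklevel=2)
        raw = min(10.0, max(1.0, raw))
    return (10.0 - raw) / 9.0


#: Property windows for the rule-based ADMET screen.
ADMET_RULES = (
    ("mw", lambda d: 150 <= d.mw <= 500),
    ("logp", lambda d: -0.7 <= d.logp <= 5.0),
    ("tpsa", lambda d: d.tpsa <= 140),
    ("rotb", lambda d: d.rotb <= 10),
    ("hbd", lambda d: d.hbd <= 5),
    ("aromatic_rings", lambda d: d.aromatic_rings <= 4),
)


def score_admet(d: DescriptorSet) -> float:
    """Fraction passed of six fixed property-window checks standing in for ADMET liability."""
    return _fraction_passed([rule(d) for _, rule in ADMET_RULES])


def score_alerts(alerts) -> float:
    """1.0 when alert-free; each PAINS/BRENK hit costs 0.5, floored at 0."""
    return max(0.0, 1.0 - 0.5 * len(alerts))


def aggregate_total(c: ComponentScores, w: WeightVector) -> float:
    """Weighted sum of the seven components; errors if weights are invalid."""
    w.validate()
    return math.fsum(wi * si for wi, si in zip(w.as_tuple(), c.as_tuple()))


def assign_grade(s_total: float) -> str:
    """Map a total score onto the A–F bands (left-closed at 0.85/0.70/0.55/0.40)."""
    if not 0.0 <= s_total <= 1.0:
        raise ValueError(f"total score {s_total} outside [0, 1]")
    for grade, lower in GRADE_BOUNDS.items():
        if s_total >= lower:
            return grade
    return "F"


def score_components(d: DescriptorSet) -> ComponentScores:
    return ComponentScores(
        lipinski=score_lipinski(d),
        veber=score_veber(d),
        ghose=score_ghose(d),
        qed=score_qed(d),
        sa=score_sa(d),
        admet=score_admet(d),
        pains=score_alerts(d.alerts),
    )


def score_compound(
    record: CompoundRecord, weights: WeightVector = WeightVector()
) -> ScoreCard:
    """Descriptor computation, seven component scores, aggregation, and grading."""
    d = compute_descriptors(record)
    comps = score_components(d)
    total = aggregate_total(comps, weights)
    return ScoreCard(record.identifier, comps, weights, total, assign_grade(total))


def _round_half_up(x: float, decimals: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_library(cards: list[ScoreCard]) -> GradeSummary:
    """Grade counts, half-up one-decimal percentages, mean/median total score."""
    if not cards:
        raise ValueError("cannot summarize an empty library")
    counts = {g: 0 for g in GRADES}
    for card in cards:
        counts[card.grade] += 1
    return summarize_counts(counts, [c.s_total for c in cards])


def summarize_counts(counts: dict[str, int], totals: list[float]) -> GradeSummary:
    """Summary from pre-tabulated grade counts plus the raw total scores."""
    n = sum(counts.values())
    if n == 0:
        raise ValueError("cannot summarize an empty library")
    percentages = {g: _round_half_up(100.0 * counts.get(g, 0) / n, 1) for g in GRADES}
    totals_sorted = sorted(totals)
    m = len(totals_sorted)
    if m:
        mean = _round_half_up(math.fsum(totals_sorted) / m, 3)
        mid = m // 2
        median_raw = (
            totals_sorted[mid]
            if m % 2
            else (totals_sorted[mid - 1] + totals_sorted[mid]) / 2
        )
        median = _round_half_up(median_raw, 3)
    else:
        mean = median = float("nan")
    return GradeSummary(
        counts={g: counts.get(g, 0) for g in GRADES},
        percentages=percentages,
        mean_total=mean,
        median_total=median,
        n=n,
    )


def scorecards_to_frame(cards: list[ScoreCard]):
    import pandas as pd

    rows = []
    for c in cards:
        row = {"identifier": c.identifier}
        row.update({f"s_{n}": v for n, v in zip(COMPONENT_NAMES, c.components.as_tuple())})
        row["s_total"] = c.s_total
        row["grade"] = c.grade
        rows.append(row)
    return pd.DataFrame(rows)
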
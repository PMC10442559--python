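"""Bundled demonstration case: a Ukrainian healthcare research competition.

Five state-funded healthcare research projects (P1..P5) across four oblasts
(Zakarpattia, Kyiv, Kharkiv, Lviv).  P1 carries a full consolidated expert
score sheet; P2..P5 enter with project scores taken from the published
competition results.  The region table holds five "availability and quality
of healthcare services" indicators with the national values of Ukraine as
normalization references.

Besides the raw inputs, :func:`demo_case` ships the hand-worked reference
intermediates of the original desk evaluation (fuzzified memberships, term
confidences, development levels, proximity coefficients, output scores and
the final ranking).  Some of those desk figures contain small arithmetic
slips — e.g. a fuzzified score recorded as 0.97 where the formula gives
0.9644, and one pair of term confidences (0.78/0.22) that the formulas do
not reproduce — so regression tests pin either the recorded values or the
recomputed ones, each with its own tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fuzzy_core import CharacteristicValues
from .project_eval import (
    Criterion,
    CriteriaSchema,
    CriterionGroup,
    InvestorProfile,
    ScoreSheet,
)
from .region_eval import RegionCriterion, RegionTable

__all__ = ["DemoCase", "demo_case", "get_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("demo",)


@dataclass(frozen=True)
class DemoCase:
    """All inputs of the bundled case plus recorded desk-evaluation values."""

    schema: CriteriaSchema
    profile: InvestorProfile
    sheets: tuple[ScoreSheet, ...]
    table: RegionTable
    given_scores: dict[str, float]
    given_regions: dict[str, str]
    #: hand-worked desk values for regression checks (see module docstring)
    reference: dict = field(default_factory=dict)


def demo_case() -> DemoCase:
    """Construct the bundled competition case from its source numbers."""
    schema = CriteriaSchema(
        groups=(
            CriterionGroup(
                id="G1",
                label="Idea and quality of the project",
                criteria=(
                    Criterion("K11", "Relevance to healthcare development policies"),
                    Criterion("K12", "Relevance of purpose, results and audiences"),
                    Criterion("K13", "Motivation and validity of the concept"),
                    Criterion("K14", "Innovativeness of ideas"),
                    Criterion("K15", "Adequacy of proposed approaches and methods"),
                ),
            ),
            CriterionGroup(
                id="G2",
                label="Significance for development of society",
                criteria=(
                    Criterion("K21", "Importance of expected results"),
                    Criterion("K22", "Ways of publicizing/using results"),
                ),
            ),
            CriterionGroup(
                id="G3",
                label="Quality and realism of the implementation plan",
                criteria=(
                    Criterion("K31", "Validity of the work plan"),
                    Criterion("K32", "Material and technical base"),
                    Criterion("K33", "Balance of the budget"),
                    Criterion("K34", "Risk assessment"),
                ),
            ),
            CriterionGroup(
                id="G4",
                label="Subjects involved in implementation",
                criteria=(
                    Criterion("K41", "Project partners"),
                    Criterion("K42", "Project team"),
                    Criterion("K43", "Experience in project activities"),
                ),
            ),
        ),
        score_range=(1, 10),
    )

    profile = InvestorProfile(
        wishes=(40, 18, 37, 25),
        group_weights=(10, 9, 8, 8),
        sigma=CharacteristicValues(),
        regional_criterion_weights=None,  # use the region table's weights
        kr=0.8,
    )

    p1 = ScoreSheet(
        project_id="P1",
        region_id="Zakarpattia",
        scores={
            "K11": 9, "K12": 10, "K13": 8, "K14": 7, "K15": 10,
            "K21": 10, "K22": 8,
            "K31": 9, "K32": 10, "K33": 10, "K34": 7,
            "K41": 8, "K42": 10, "K43": 10,
        },
    )

    table = RegionTable(
        criteria=(
            RegionCriterion("RC1", "Total mortality per 1,000", "cost", 10, 14.8),
            RegionCriterion("RC2", "Life expectancy at birth (years)", "benefit", 9, 73.5),
            RegionCriterion("RC3", "Live births per 1,000", "benefit", 9, 10.2),
            RegionCriterion(
                "RC4", "Outpatient-clinic capacity per 10,000", "benefit", 8, 306.8
            ),
            RegionCriterion("RC5", "New TB cases per 100,000", "cost", 7, 18.4),
        ),
        regions=("Zakarpattia", "Kyiv", "Kharkiv", "Lviv"),
        values=np.array(
            [
                [14.8, 15.3, 21.0, 16.0],
                [70.47, 73.5, 71.11, 72.42],
                [10.1, 10.0, 5.9, 7.8],
                [250.6, 287.9, 298.1, 201.6],
                [44.0, 24.5, 28.2, 35.3],
            ]
        ),
    )

    given_scores = {"P2": 96.1, "P3": 94.4, "P4": 93.4, "P5": 92.8}
    given_regions = {"P2": "Kyiv", "P3": "Kharkiv", "P4": "Kyiv", "P5": "Lviv"}

    reference = {
        # stage 1, project P1 (desk values; gamma_G1 recorded as 0.97,
        # formula gives 0.9644)
        "group_sums": {"G1": 44, "G2": 18, "G3": 36, "G4": 28},
        "gamma": {"G1": 0.97, "G2": 0.98, "G3": 0.98, "G4": 0.99},
        "alpha": {"G1": 0.90, "G2": 0.98, "G3": 0.99, "G4": 0.93},
        "confidences": {
            "G1": {3: 0.69, 4: 0.31},
            "G2": {2: 0.0, 3: 1.0},
            "G3": {2: 0.04, 3: 0.96},
            "G4": {3: 0.78, 4: 0.22},  # formulas give ~0.74/0.26
        },
        "group_satisfaction": {"G1": 92.25, "G2": 100.0, "G3": 99.0, "G4": 94.5},
        "normalized_group_weights": (0.28, 0.26, 0.23, 0.23),
        "project_score_P1": 96.4,  # printed operands give 96.335, full precision ~96.29
        # stage 2
        "normalized_values": np.array(
            [
                [1.0, 0.967, 0.705, 0.925],
                [0.959, 1.0, 0.967, 0.985],
                [0.99, 0.98, 0.578, 0.765],
                [0.817, 0.938, 0.972, 0.657],
                [0.418, 0.751, 0.652, 0.521],
            ]
        ),
        "normalized_region_weights": (0.23, 0.21, 0.21, 0.19, 0.16),
        "development_levels": {
            "Zakarpattia": 0.861,
            "Kyiv": 0.936,
            "Kharkiv": 0.774,
            "Lviv": 0.789,
        },
        # stage 3 (from the recorded development levels, KR = 0.8)
        "proximity": {"Zakarpattia": 0.56, "Kyiv": 0.0, "Kharkiv": 0.81, "Lviv": 0.92},
        "output_scores": {"P1": 53.59, "P2": 0.0, "P3": 76.71, "P4": 0.0, "P5": 84.97},
        "ranking": ("P5", "P3", "P1", "P2", "P4"),
    }

    return DemoCase(
        schema=schema,
        profile=profile,
        sheets=(p1,),
        table=table,
        given_scores=given_scores,
        given_regions=given_regions,
        reference=reference,
    )


def get_fixture(name: str) -> DemoCase:
    """Look up a bundled fixture by name (currently only ``"demo"``)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return demo_case()
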
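"""Study fixtures: the published-map ground-truth network and the
deterministic descriptive-table cohort.

``paper_network`` encodes the four clusters of the published
conditional-independence map — person-centred (CAMHS hub and repeat ED
attendance), household risk (neglect/abuse/domestic violence plus family
structure), parental risk (mental health / drug misuse / crime triangle)
and the sex / means-of-self-harm / risk-to-life group — with every CPT
calibrated so that each published edge attains its printed mutual
information (bits) and every printed prevalence is matched exactly.
Strengths and prevalences the source tables do not print fall back to
documented defaults and are flagged ``published: False`` in the network
metadata.

``table1_fixture`` is a deterministic 240-record cohort whose per-variable
level counts reproduce the printed descriptive table cell-for-cell, both
overall and within the previous-attender stratum (the printed table's
stratified columns each sum to 57, so the fixture contains 57 previous
attenders; see docs/methods.md for the one-cell discrepancy this implies).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import (
    calibrate_conditional_matrix,
    calibrate_pairwise_joint,
    calibrate_two_parent_cpt,
    discretised_age_distribution,
)
from .cohort import Cohort, VariableDictionary, VariableSpec
from .network import CPT, GroundTruthNetwork

# Published prevalences (fractions of n=240) and MI edge strengths (bits).
_PREV = 58 / 240
_FEMALE = 160 / 240
_DSH = 162 / 240
_CAMHS = 154 / 240
_ASD_TRAITS = 51 / 240
_ANXIETY = 43 / 240
_LOW_MOOD = 40 / 240
_DX_OTHER = 35 / 240
_SEN = 58 / 240

# Unpublished defaults (flagged in metadata): 0.15 prevalence and 0.15-bit
# edges, except the neglect/violence/abuse subnetwork whose published MI of
# 0.80/0.72 bits is only attainable at higher prevalence (max MI between two
# binaries of prevalence m is H(m); H(0.15)=0.61 < 0.80), hence 0.30.
_UNPUB_PREV = 0.15
_HOUSEHOLD_PREV = 0.30
_UNPUB_MI = 0.15

_MEANS_LEVELS = ("none_ideation_only", "overdose", "cutting", "suffocation", "other")
_MEANS_BASE = np.array([0.65, 0.18, 0.10, 0.03, 0.04])
_RISK_LEVELS = ("low", "medium", "high")
_RISK_BASE = np.array([0.45, 0.35, 0.20])

# Score patterns steering the categorical tilts: females toward overdose,
# males toward cutting; ideation-only toward low risk, overdose/suffocation
# toward high, cutting/other toward medium (matching the follow-up findings).
_SEX_MEANS_SCORE = np.array(
    [
        [0.0, 1.0, 0.0, 0.0, 0.0],  # female
        [0.0, 0.0, 1.0, 0.0, 0.0],  # male
    ]
)
_MEANS_RISK_SCORE = np.array(
    [
        [1.0, 0.0, 0.0],  # none/ideation-only -> low
        [0.0, 0.0, 1.0],  # overdose -> high
        [0.0, 1.0, 0.0],  # cutting -> medium
        [0.0, 0.0, 1.0],  # suffocation -> high
        [0.0, 1.0, 0.0],  # other -> medium
    ]
)


def _binary(name, role="clinical"):
    return VariableSpec(name=name, kind="binary", levels=("0", "1"), role=role)


def _root_cpt(name, p1):
    return CPT(name, (), np.array([1.0 - p1, p1]))


def _edge_cpt(child, parent, parent_prev, child_prev, target_mi):
    """Single-parent binary CPT calibrated to a pairwise MI target."""
    joint = calibrate_pairwise_joint(target_mi, parent_prev, child_prev)
    return CPT(child, (parent,), joint.conditional_child_given_parent()), joint


def paper_network() -> GroundTruthNetwork:
    """Ground-truth network calibrated to the published CI-Map.

    Every edge named in the published results carries its printed MI; CPTs
    are exact in the population, so large ancestral samples recover the
    printed strengths to sampling error.
    """
    specs = [
        VariableSpec("age", "integer_bounded", tuple(str(a) for a in range(8, 17)),
                     role="demographic"),
        VariableSpec("sex", "binary", ("female", "male"), role="demographic"),
        _binary("previous_attendance", role="outcome"),
        _binary("history_dsh"),
        _binary("low_mood"),
        _binary("known_camhs"),
        _binary("asd_traits"),
        _binary("anxiety"),
        _binary("diagnosis_other"),
        _binary("sen", role="demographic"),
        _binary("neglect", role="ACE"),
        _binary("domestic_violence", role="ACE"),
        _binary("abuse", role="ACE"),
        _binary("social_worker"),
        _binary("single_parent", role="ACE"),
        _binary("step_parent", role="ACE"),
        _binary("siblings", role="demographic"),
        _binary("sep_loss_parent", role="ACE"),
        _binary("parental_mental_health", role="ACE"),
        _binary("parent_drug_misuse", role="ACE"),
        _binary("parental_crime", role="ACE"),
        VariableSpec("means", "categorical", _MEANS_LEVELS),
        VariableSpec("risk", "categorical", _RISK_LEVELS),
    ]
    dictionary = VariableDictionary(specs)

    cpts = {}
    edges_meta = []

    def note(source, target, mi, published):
        edges_meta.append(
            {"source": source, "target": target, "target_mi": mi, "published": published}
        )

    # --- roots ----------------------------------------------------------
    ages, age_p = discretised_age_distribution(13.5, 1.42, 8, 16)
    cpts["age"] = CPT("age", (), age_p)
    # sex levels (female, male): index 0 is female
    cpts["sex"] = CPT("sex", (), np.array([_FEMALE, 1.0 - _FEMALE]))
    cpts["previous_attendance"] = _root_cpt("previous_attendance", _PREV)
    cpts["sen"] = _root_cpt("sen", _SEN)
    cpts["neglect"] = _root_cpt("neglect", _HOUSEHOLD_PREV)
    cpts["parental_mental_health"] = _root_cpt("parental_mental_health", _UNPUB_PREV)

    # --- person-centred cluster ----------------------------------------
    cpts["history_dsh"], _ = _edge_cpt(
        "history_dsh", "previous_attendance", _PREV, _DSH, 0.11
    )
    note("previous_attendance", "history_dsh", 0.11, True)
    cpts["low_mood"], prev_low_joint = _edge_cpt(
        "low_mood", "previous_attendance", _PREV, _LOW_MOOD, 0.07
    )
    note("previous_attendance", "low_mood", 0.07, True)
    # CAMHS closes the prev/low-mood/CAMHS triangle: two parents, both MI
    # targets and the CAMHS prevalence solved simultaneously.
    cpts["known_camhs"] = CPT(
        "known_camhs",
        ("previous_attendance", "low_mood"),
        calibrate_two_parent_cpt(prev_low_joint.cells, _CAMHS, 0.13, 0.09),
    )
    note("previous_attendance", "known_camhs", 0.13, True)
    note("low_mood", "known_camhs", 0.09, True)
    for child, prev_child, mi in [
        ("asd_traits", _ASD_TRAITS, 0.03),
        ("anxiety", _ANXIETY, 0.10),
        ("diagnosis_other", _DX_OTHER, 0.06),
    ]:
        cpts[child], _ = _edge_cpt(child, "known_camhs", _CAMHS, prev_child, mi)
        note("known_camhs", child, mi, True)

    # --- household-risk cluster -----------------------------------------
    cpts["domestic_violence"], _ = _edge_cpt(
        "domestic_violence", "neglect", _HOUSEHOLD_PREV, _HOUSEHOLD_PREV, 0.80
    )
    note("neglect", "domestic_violence", 0.80, True)
    cpts["abuse"], _ = _edge_cpt(
        "abuse", "neglect", _HOUSEHOLD_PREV, _HOUSEHOLD_PREV, 0.72
    )
    note("neglect", "abuse", 0.72, True)
    cpts["social_worker"], _ = _edge_cpt(
        "social_worker", "neglect", _HOUSEHOLD_PREV, _UNPUB_PREV, 0.12
    )
    note("neglect", "social_worker", 0.12, True)
    cpts["single_parent"], _ = _edge_cpt(
        "single_parent", "domestic_violence", _HOUSEHOLD_PREV, _UNPUB_PREV, _UNPUB_MI
    )
    note("domestic_violence", "single_parent", _UNPUB_MI, False)
    for child in ("step_parent", "siblings", "sep_loss_parent"):
        cpts[child], _ = _edge_cpt(
            child, "single_parent", _UNPUB_PREV, _UNPUB_PREV, _UNPUB_MI
        )
        note("single_parent", child, _UNPUB_MI, False)

    # --- parental-risk triangle -----------------------------------------
    cpts["parent_drug_misuse"], pmh_drug_joint = _edge_cpt(
        "parent_drug_misuse", "parental_mental_health", _UNPUB_PREV, _UNPUB_PREV,
        _UNPUB_MI,
    )
    note("parental_mental_health", "parent_drug_misuse", _UNPUB_MI, False)
    cpts["parental_crime"] = CPT(
        "parental_crime",
        ("parental_mental_health", "parent_drug_misuse"),
        calibrate_two_parent_cpt(
            pmh_drug_joint.cells, _UNPUB_PREV, _UNPUB_MI, _UNPUB_MI
        ),
    )
    note("parental_mental_health", "parental_crime", _UNPUB_MI, False)
    note("parent_drug_misuse", "parental_crime", _UNPUB_MI, False)

    # --- sex / means / risk cluster -------------------------------------
    sex_marginal = np.array([_FEMALE, 1.0 - _FEMALE])
    means_cond = calibrate_conditional_matrix(
        sex_marginal, _MEANS_BASE, _SEX_MEANS_SCORE, 0.05
    )
    cpts["means"] = CPT("means", ("sex",), means_cond)
    note("sex", "means", 0.05, True)
    means_marginal = sex_marginal @ means_cond
    risk_cond = calibrate_conditional_matrix(
        means_marginal, _RISK_BASE, _MEANS_RISK_SCORE, 0.24
    )
    cpts["risk"] = CPT("risk", ("means",), risk_cond)
    note("means", "risk", 0.24, True)

    metadata = {
        "edges": edges_meta,
        "unpublished_prevalence_default": _UNPUB_PREV,
        "household_prevalence": _HOUSEHOLD_PREV,
        "unpublished_mi_default": _UNPUB_MI,
        "age_model": {"mean": 13.5, "sd": 1.42, "range": [8, 16]},
    }
    return GroundTruthNetwork(dictionary, cpts, metadata)


# ---------------------------------------------------------------------------
# Deterministic descriptive-table cohort
# ---------------------------------------------------------------------------

# (level, overall count, count within previous attenders). Stratified
# columns each sum to 57; overall columns sum to 240.
TABLE1_COUNTS = {
    "sex": [("female", 160, 45), ("male", 80, 12)],
    "ethnicity": [
        ("white_british", 222, 51),
        ("other", 16, 5),
        ("unknown", 2, 1),
    ],
    "mental_health": [
        ("anxiety", 43, 10),
        ("anxiety_comorbidities", 10, 3),
        ("anxiety_low_mood", 9, 4),
        ("low_mood", 40, 20),
        ("low_mood_comorbidity", 5, 3),
        ("other", 35, 10),
        ("none", 98, 7),
    ],
    "sen": [
        ("adhd", 12, 7),
        ("adhd_learning_disabilities", 3, 0),
        ("asc", 21, 8),
        ("asc_adhd", 12, 5),
        ("asc_adhd_learning_disabilities", 1, 0),
        ("asc_learning_disabilities", 3, 0),
        ("learning_disabilities", 6, 1),
        ("no_sen", 182, 36),
    ],
    "asc_traits": [("no", 189, 41), ("yes", 51, 16)],
    "known_camhs": [("no", 86, 2), ("yes", 154, 55)],
    "open_camhs": [("no", 186, 32), ("yes", 54, 25)],
    "history_dsh": [("no", 78, 2), ("yes", 162, 55)],
}

_N_TOTAL = 240
_N_PREV = 57  # each stratified column of the printed table sums to 57

# Deterministic integer ages: overall mean exactly 13.5 (sum 3240), previous
# attenders mean 781/57 = 13.70 (printed 13.7), range 8-16 realised.
_AGES_PREV = [8, 16] + [14] * 42 + [13] * 13
_AGES_REST = [14] * 80 + [13] * 103


def _table1_dictionary() -> VariableDictionary:
    specs = [
        VariableSpec("previous_attendance", "binary", ("no", "yes"), role="outcome"),
        VariableSpec("sex", "binary", ("female", "male"), role="demographic"),
        VariableSpec("age", "integer_bounded", tuple(str(a) for a in range(8, 17)),
                     role="demographic"),
        VariableSpec("ethnicity", "categorical",
                     ("white_british", "other", "unknown"), role="demographic"),
        VariableSpec("mental_health", "categorical",
                     tuple(lv for lv, _, _ in TABLE1_COUNTS["mental_health"])),
        VariableSpec("sen", "categorical",
                     tuple(lv for lv, _, _ in TABLE1_COUNTS["sen"]),
                     role="demographic"),
        VariableSpec("asc_traits", "binary", ("no", "yes")),
        VariableSpec("known_camhs", "binary", ("no", "yes")),
        VariableSpec("open_camhs", "binary", ("no", "yes")),
        VariableSpec("history_dsh", "binary", ("no", "yes")),
    ]
    return VariableDictionary(specs)


def _fill(block_counts) -> list:
    """Expand [(level, count), ...] to a flat value list in level order."""
    out = []
    for level, count in block_counts:
        out.extend([level] * count)
    return out


def table1_fixture() -> Cohort:
    """Deterministic 240-record cohort reproducing the printed Table-1 cells.

    Records 0..56 are the previous attenders. Within each block every
    variable is filled sequentially in declared level order with the
    printed within-block counts — a documented deterministic fill, so
    repeated calls return identical cohorts.
    """
    data = {
        "previous_attendance": ["yes"] * _N_PREV + ["no"] * (_N_TOTAL - _N_PREV),
        "age": [str(a) for a in _AGES_PREV + _AGES_REST],
    }
    for var, rows in TABLE1_COUNTS.items():
        prev_block = _fill([(lv, c_prev) for lv, _, c_prev in rows])
        rest_block = _fill([(lv, c_all - c_prev) for lv, c_all, c_prev in rows])
        assert len(prev_block) == _N_PREV and len(rest_block) == _N_TOTAL - _N_PREV
        data[var] = prev_block + rest_block
    df = pd.DataFrame(data, dtype=object)
    return Cohort(df, _table1_dictionary())
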
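"""Published cohort summary of the study population the simulator emulates.

These printed counts and group means are inputs: they seed the default
:class:`~fetalsurf.simulate.SimulationConfig` and support bookkeeping
checks (scan totals, follow-up and longitudinal percentages, outcome
group differences) without access to the clinical data themselves.
"""

from __future__ import annotations

COHORT = {
    "CHD": {
        "scans": 135,
        "subjects": 91,
        "longitudinal_subjects": 44,
        "followup": 51,
        "hlhs_tga_subjects": 39,
        "male_subjects": 58,
        "scan1_ga_range": (19.6, 30.4),
        "scan2_ga_range": (30.0, 38.8),
    },
    "Control": {
        "scans": 157,
        "subjects": 125,
        "longitudinal_subjects": 32,
        "followup": 38,
        "male_subjects": 59,
        "scan1_ga_range": (22.0, 30.0),
        "scan2_ga_range": (29.1, 38.7),
    },
}

#: Bayley-III composite group means in the follow-up subset.
BAYLEY_GROUP_MEANS = {
    "cognitive": {"CHD": 99.9, "Control": 104.8},
    "motor": {"CHD": 95.9, "Control": 102.6},
    "language": {"CHD": 97.7, "Control": 107.7},
}


def total_scans() -> int:
    """Total scan count across groups."""
    return sum(g["scans"] for g in COHORT.values())


def longitudinal_percent(group: str) -> float:
    """Percent of a group's subjects with two in-utero scans."""
    g = COHORT[group]
    return 100.0 * g["longitudinal_subjects"] / g["subjects"]


def followup_percent(group: str) -> float:
    """A group's share of the 2-year follow-up subset, in percent."""
    fu = sum(g["followup"] for g in COHORT.values())
    return 100.0 * COHORT[group]["followup"] / fu


def hlhs_tga_percent() -> float:
    """Percent of CHD subjects with HLHS/TGA physiology."""
    g = COHORT["CHD"]
    return 100.0 * g["hlhs_tga_subjects"] / g["subjects"]


def bayley_group_difference(domain: str) -> float:
    """CHD-minus-control difference of a Bayley-III composite group mean."""
    m = BAYLEY_GROUP_MEANS[domain]
    return m["CHD"] - m["Control"]
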
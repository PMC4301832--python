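"""Published 2006 reference tables, shipped as transcription fixtures.

The raw insurer claims are not redistributable, but the published triad
tables (57 female / 51 male selected triads with O/E ratio, prevalence and
cluster-section heading) and the per-condition centrality table (prevalence,
edge counts, degree and betweenness centralities, cluster membership) are
in-paper inputs: the network stage is a pure function of the selected triads,
so the full network analysis can be reproduced from these fixtures alone.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .triads import TriadSelection

FIXTURE_IDS = ("female_2006", "male_2006")


def _data_path(name: str):
    return importlib.resources.files("triadnet.data") / name


def load_fixture_triads(which: str) -> TriadSelection:
    """The published selected triads as a ready-made TriadSelection.

    ``which`` is ``'female_2006'`` or ``'male_2006'``. O/E ratios and
    prevalences are the printed (rounded) values; all satisfy the published
    inclusion thresholds (prevalence ≥ 1%, O/E ≥ 2).
    """
    if which not in FIXTURE_IDS:
        raise KeyError(f"unknown fixture {which!r}; expected one of {FIXTURE_IDS}")
    name = f"triads_{which}.csv"
    with importlib.resources.as_file(_data_path(name)) as path:
        raw = pd.read_csv(path)
    stats = pd.DataFrame(
        {
            "group_a": raw["group_a"],
            "group_b": raw["group_b"],
            "group_c": raw["group_c"],
            "observed_prev": raw["prevalence_pct"] / 100.0,
            "expected_prev": raw["prevalence_pct"] / 100.0 / raw["oe_ratio"],
            "oe_ratio": raw["oe_ratio"],
            "passes_prevalence": True,
            "passes_oe": True,
            "selected": True,
        }
    )
    return TriadSelection(
        gender="F" if which.startswith("female") else "M",
        min_prev=0.01,
        min_oe=2.0,
        stats=stats,
        section=raw["section"],
    )


def load_centrality_table() -> pd.DataFrame:
    """Published per-condition table: prevalences, edges, centralities, cluster."""
    with importlib.resources.as_file(_data_path("table_centrality_2006.csv")) as path:
        return pd.read_csv(path, index_col="group_id")


def load_cluster_membership() -> dict[str, frozenset[str]]:
    """Published cluster membership: condition → {'ads_pain'} / {'cardiometabolic'} / ∅."""
    table = load_centrality_table()
    return {
        gid: (frozenset() if cl == "none" else frozenset([cl]))
        for gid, cl in table["cluster"].items()
    }


def fixture_prevalence(gender: str) -> pd.Series:
    """Published gender-specific prevalences (fractions) of the table conditions."""
    table = load_centrality_table()
    col = "prev_female_pct" if gender == "F" else "prev_male_pct"
    prev = (table[col] / 100.0).dropna()
    prev.name = "prevalence"
    return prev
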
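"""End-to-end orchestration: cohort → prevalence → triads → clusters → network.

The pipeline is gender-stratified throughout. Input is either a claims CSV,
the internal synthetic generator, or — in network-only mode — the published
triad fixtures, since the network stage is a pure function of the selected
triads. Every stage persists its output under the configured directory and a
JSON manifest ties the bundle together.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .cohort import (
    CohortBuilder,
    ConditionMatrix,
    EmptyCohortError,
    compute_prevalence,
)
from .clusters import TetrachoricFactorClusters, classify_triad
from .fixtures import fixture_prevalence, load_cluster_membership, load_fixture_triads
from .groups import default_groups, load_groups
from .network import (
    annotate_clusters,
    extract_edgelist,
    layout_mds,
    network_metrics,
    plot_network,
)
from .simulate import build_default_config, simulate_claims
from .triads import TriadScreen, TriadSelection

logger = logging.getLogger(__name__)


class NoTriadsError(RuntimeError):
    """The screen selected zero triads; the network stage cannot run."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (defaults = the 2006 study settings)."""

    mode: str = "synthetic"  # synthetic | claims_csv | fixture
    claims_path: str | None = None
    mapping_path: str | None = None
    fixture_year: str = "2006"
    genders: tuple[str, ...] = ("F", "M")
    scale: int = 2000
    min_quarters: int = 3
    min_conditions: int = 3
    min_prev: float = 0.01
    min_oe: float = 2.0
    eigen_threshold: float = 1.0
    loading_threshold: float = 0.25
    cluster_source: str = "fit"  # fit | fixture
    seed: int = 20061
    outdir: str = "triadnet_out"

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("synthetic", "claims_csv", "fixture"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "claims_csv" and not self.claims_path:
            raise ValueError("claims_csv mode requires claims_path")
        if self.cluster_source not in ("fit", "fixture"):
            raise ValueError("cluster_source must be 'fit' or 'fixture'")
        for thr in (self.min_prev, self.min_oe, self.eigen_threshold, self.loading_threshold):
            if thr < 0:
                raise ValueError("thresholds must be non-negative")
        return self


#: the 2004 replication setting: lower the triad prevalence criterion to 0.85%
REPLICATION_2004 = {"min_prev": 0.0085}


@dataclass
class ReportBundle:
    outdir: Path
    manifest: dict = field(default_factory=dict)

    def record(self, key: str, path: Path) -> None:
        self.manifest.setdefault("files", {})[key] = str(path.relative_to(self.outdir))

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, default=str))
        return path

    def validate(self) -> bool:
        files = self.manifest.get("files", {})
        ok = all((self.outdir / rel).exists() for rel in files.values())
        for g in self.manifest.get("triad_counts", {}).values():
            ok = ok and g["selected"] <= g["prevalent"] <= g["all"]
        return ok


def _gender_selection(config: PipelineConfig, cohort: ConditionMatrix | None, gender: str):
    if config.mode == "fixture":
        which = ("female_" if gender == "F" else "male_") + config.fixture_year
        return load_fixture_triads(which), fixture_prevalence(gender), None
    sub = cohort.for_gender(gender)
    if sub.n_patients == 0:
        raise EmptyCohortError(f"no multimorbid patients of gender {gender}")
    prev = compute_prevalence(sub)
    screen = TriadScreen(min_prev=config.min_prev, min_oe=config.min_oe).fit(sub)
    return screen.selection_, prev, sub


def _cluster_assignments(config: PipelineConfig, sub: ConditionMatrix | None):
    if config.cluster_source == "fixture" or sub is None:
        return load_cluster_membership(), None
    model = TetrachoricFactorClusters(
        eigen_threshold=config.eigen_threshold, loading_threshold=config.loading_threshold
    ).fit(sub)
    return model.assignments_, model.solution_


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run all stages in order and persist the report bundle.

    Stage order: cohort → prevalence → triads → selection → clusters →
    network → layout → report; identical config + seed gives an identical
    bundle.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=outdir)
    bundle.manifest["config"] = asdict(config)
    bundle.manifest["version"] = __version__

    cohort = None
    if config.mode != "fixture":
        if config.mode == "synthetic":
            gen = build_default_config(config.scale, seed=config.seed)
            claims, truth = simulate_claims(gen)
            truth.data.to_csv(outdir / "truth_matrix.csv")
            bundle.record("truth_matrix", outdir / "truth_matrix.csv")
            claims.to_csv(outdir / "claims.csv", index=False)
            bundle.record("claims", outdir / "claims.csv")
        else:
            try:
                claims = pd.read_csv(config.claims_path)
            except OSError as exc:
                raise FileNotFoundError(f"cannot read claims file: {exc}") from exc
        groups = load_groups(config.mapping_path) if config.mapping_path else default_groups()
        builder = CohortBuilder(
            groups=groups,
            min_quarters=config.min_quarters,
            min_conditions=config.min_conditions,
        )
        cohort = builder.fit(claims).transform(claims)
        if cohort.n_patients == 0:
            raise EmptyCohortError("multimorbidity filter left an empty cohort")
        bundle.manifest["funnel"] = builder.funnel_
        summary = cohort.summary()
        (outdir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
        bundle.record("cohort_summary", outdir / "cohort_summary.json")
        cohort.data.to_csv(outdir / "condition_matrix.csv")
        bundle.record("condition_matrix", outdir / "condition_matrix.csv")

    bundle.manifest["triad_counts"] = {}
    for gender in config.genders:
        selection, prev, sub = _gender_selection(config, cohort, gender)
        tag = "female" if gender == "F" else "male"
        prev.to_csv(outdir / f"prevalence_{tag}.csv")
        bundle.record(f"prevalence_{tag}", outdir / f"prevalence_{tag}.csv")
        bundle.manifest["triad_counts"][gender] = selection.counts

        assignments, solution = _cluster_assignments(config, sub)
        if sub is not None:  # conditions beyond the assignment source are unassigned
            assignments = {**{g: frozenset() for g in sub.group_ids}, **assignments}
        if solution is not None:
            solution.membership_frame().to_csv(
                outdir / f"cluster_membership_{tag}.csv", index=False
            )
            bundle.record(f"cluster_membership_{tag}", outdir / f"cluster_membership_{tag}.csv")
            bundle.manifest.setdefault("n_factors", {})[gender] = solution.n_factors

        triads = selection.stats.copy()
        sel_triads = selection.selected
        if not len(sel_triads):
            raise NoTriadsError(f"no triads selected for gender {gender}")
        triads["cluster_label"] = [
            classify_triad((r.group_a, r.group_b, r.group_c), assignments)
            if r.selected else ""
            for r in triads.itertuples()
        ]
        triads.to_csv(outdir / f"triads_{tag}.csv", index=False)
        bundle.record(f"triads_{tag}", outdir / f"triads_{tag}.csv")

        G = extract_edgelist(selection.triples(), prevalence=prev)
        annotate_clusters(G, assignments)
        metrics = network_metrics(G)
        metrics.index.name = "condition"
        metrics.to_csv(outdir / f"network_metrics_{tag}.csv")
        bundle.record(f"network_metrics_{tag}", outdir / f"network_metrics_{tag}.csv")
        bundle.manifest.setdefault("network", {})[gender] = {
            "n_nodes": metrics.attrs["n_nodes"],
            "n_edges": metrics.attrs["n_edges"],
            "degree_sum": metrics.attrs["degree_sum"],
            "average_betweenness_pct": metrics.attrs["average_betweenness_pct"],
            "average_betweenness_norm_pct": metrics.attrs["average_betweenness_norm_pct"],
        }

        edges = pd.DataFrame(
            [(u, v, len(d["triads"])) for u, v, d in G.edges(data=True)],
            columns=["condition_a", "condition_b", "n_supporting_triads"],
        )
        edges.to_csv(outdir / f"edgelist_{tag}.csv", index=False)
        bundle.record(f"edgelist_{tag}", outdir / f"edgelist_{tag}.csv")

        pos = layout_mds(G, seed=config.seed)
        pd.DataFrame(pos, index=["x", "y"]).T.rename_axis("condition").to_csv(
            outdir / f"layout_{tag}.csv"
        )
        bundle.record(f"layout_{tag}", outdir / f"layout_{tag}.csv")
        for node, (x, y) in pos.items():
            G.nodes[node]["x"], G.nodes[node]["y"] = float(x), float(y)
        for _, _, d in G.edges(data=True):
            d["n_supporting_triads"] = len(d.pop("triads"))
        nx.write_graphml(G, outdir / f"network_{tag}.graphml")
        bundle.record(f"network_{tag}", outdir / f"network_{tag}.graphml")
        plot_network(G, pos, path=outdir / f"network_{tag}.png", seed=config.seed)
        bundle.record(f"plot_{tag}", outdir / f"network_{tag}.png")

    bundle.write_manifest()
    if not bundle.validate():
        raise RuntimeError("report bundle failed manifest validation")
    return bundle
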
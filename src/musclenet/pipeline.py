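"""Stage orchestration behind a single YAML configuration.

Stages (in dependency order): parse -> impact -> nulls -> communities /
ordering -> correlates.  Each stage writes its table(s) into the output
directory together with a small meta record holding the config hash and
seed; re-running a stage whose meta matches the current config is a
cache hit and is skipped.  The synthetic mode replaces the input files
with a seeded generated body, so the full pipeline runs end-to-end
without any external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import nulls as nulls_mod
from . import ordering as ord_mod
from . import springs, stats, synthetic
from .hypergraph import Hypergraph, parse_incidence, project, degree_profile

__all__ = ["RunConfig", "Pipeline", "run", "STAGES", "DependencyError"]

log = logging.getLogger("musclenet")

STAGES = ("parse", "impact", "nulls", "communities", "ordering", "correlates")


class DependencyError(RuntimeError):
    """A stage was requested before its upstream stage produced output."""


@dataclass
class RunConfig:
    """Validated run configuration (YAML-loadable).

    In synthetic mode the ``synthetic`` block parameterizes
    :class:`~musclenet.synthetic.BodySpec`; otherwise ``incidence``,
    ``coordinates`` and ``categories`` must point at existing CSV files.
    """

    output_dir: str = "musclenet_out"
    seed: int = 0
    # inputs
    synthetic: dict | None = None
    incidence: str | None = None
    coordinates: str | None = None
    categories: str | None = None
    recovery_table: str | None = None
    volume_table: str | None = None
    # solver
    impact_mode: str = "steady_state_4d"
    d: float = 1.0
    dt: float = 0.01
    # nulls
    null_variant: str = "triad_rewire"
    null_replicates: int = 100
    # communities
    gamma: float = 4.3
    community_runs: int = 100
    # ordering
    mds_threshold: float = 0.0
    mds_variant: str = "binary_bfs"
    # clinical simulation (synthetic mode)
    effect_size: float = 2.0
    noise_sd: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            for name in ("incidence", "coordinates", "categories"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config lacks input path {name!r} "
                                     "(and no synthetic block)")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} path does not exist: {p}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class Pipeline:
    """Executes stages in dependency order with file-level caching."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._mem: dict[str, object] = {}

    # -- caching helpers ----------------------------------------------
    def _meta_path(self, stage: str) -> Path:
        return self.out / f"{stage}.meta.json"

    def _cached(self, stage: str) -> bool:
        mp = self._meta_path(stage)
        if not mp.exists():
            return False
        meta = json.loads(mp.read_text())
        return meta.get("config_hash") == self.config.digest()

    def _mark(self, stage: str, **extra) -> None:
        meta = {"config_hash": self.config.digest(),
                "seed": self.config.seed, **extra}
        self._meta_path(stage).write_text(json.dumps(meta, indent=2))

    # -- inputs --------------------------------------------------------
    def _load_inputs(self):
        if "hypergraph" in self._mem:
            return
        cfg = self.config
        if cfg.synthetic is not None:
            spec = synthetic.BodySpec(seed=cfg.seed, **cfg.synthetic)
            h, emb, cats = synthetic.generate_body(spec)
        else:
            h = parse_incidence(cfg.incidence)
            emb = springs.load_embedding(cfg.coordinates)
            cats = pd.read_csv(cfg.categories)
        self._mem["hypergraph"] = h
        self._mem["embedding"] = emb
        self._mem["categories"] = cats

    def _settings(self) -> springs.ImpactSettings:
        return springs.ImpactSettings(d=self.config.d, dt=self.config.dt)

    def _require(self, stage: str, artifact: Path):
        if not artifact.exists():
            raise DependencyError(
                f"stage {stage!r} must run before this one "
                f"(missing {artifact.name})")

    # -- stages --------------------------------------------------------
    def stage_parse(self):
        self._load_inputs()
        if self._cached("parse"):
            log.info("parse: cache hit")
            return
        h: Hypergraph = self._mem["hypergraph"]
        h.write_edges(self.out / "edges.csv")
        degree_profile(h).to_frame().to_csv(self.out / "degrees.csv",
                                            index=False)
        self._mark("parse", n_bones=h.n_bones, n_muscles=h.n_muscles)
        log.info("parse: %d bones, %d muscles", h.n_bones, h.n_muscles)

    def stage_impact(self):
        self._load_inputs()
        if self._cached("impact"):
            log.info("impact: cache hit")
            self._mem["impact"] = pd.read_csv(self.out / "impact.csv")
            return
        table = springs.impact_all(self._mem["hypergraph"],
                                   self._mem["embedding"],
                                   self.config.impact_mode, self._settings())
        table.to_csv(self.out / "impact.csv", index=False)
        self._mem["impact"] = table
        self._mark("impact", mode=self.config.impact_mode)
        log.info("impact: %d muscles scored", len(table))

    def stage_nulls(self):
        self._load_inputs()
        self._require("impact", self.out / "impact.csv")
        if self._cached("nulls"):
            log.info("nulls: cache hit")
            self._mem["deviation"] = pd.read_csv(self.out / "deviation.csv")
            return
        h = self._mem["hypergraph"]
        cfg = self.config
        grouping = None
        if cfg.null_variant == "category_rewire":
            cats = self._mem["categories"]
            grouping = dict(zip(cats["muscle"], cats["category_id"]))
        ens = nulls_mod.NullEnsemble.generate(
            h, cfg.null_variant, cfg.null_replicates, seed=cfg.seed,
            grouping=grouping)
        ens.compute_impacts(self._mem["embedding"], cfg.impact_mode,
                            self._settings())
        impact = self._mem.get("impact")
        if impact is None:
            impact = pd.read_csv(self.out / "impact.csv")
        dev = nulls_mod.impact_deviation(impact, ens)
        dev.to_csv(self.out / "deviation.csv", index=False)
        self._mem["deviation"] = dev
        self._mark("nulls", variant=cfg.null_variant,
                   replicates=cfg.null_replicates)
        log.info("nulls: %s x%d", cfg.null_variant, cfg.null_replicates)

    def stage_communities(self):
        self._load_inputs()
        if self._cached("communities"):
            log.info("communities: cache hit")
            self._mem["partition"] = pd.read_csv(self.out / "partition.csv")
            return
        h = self._mem["hypergraph"]
        B = project(h, "muscle_centric")
        est = comm.ConsensusClustering(
            gamma=self.config.gamma, n_runs=self.config.community_runs,
            random_state=self.config.seed).fit(B)
        part = pd.DataFrame({"muscle": h.muscle_labels,
                             "community": est.labels_ + 1})
        part.to_csv(self.out / "partition.csv", index=False)
        cats = self._mem["categories"]
        zr = float("nan")
        if set(cats["muscle"]) >= set(h.muscle_labels):
            cat_map = dict(zip(cats["muscle"], cats["category_id"]))
            cat_labels = np.array([cat_map[m] for m in h.muscle_labels])
            zr = comm.z_rand(est.labels_, cat_labels)
        sizes = np.bincount(est.labels_).tolist()
        (self.out / "communities.json").write_text(json.dumps({
            "n_communities": est.n_communities_, "gamma": self.config.gamma,
            "z_rand_vs_categories": zr, "sizes": sizes}, indent=2))
        self._mem["partition"] = part
        self._mem["z_rand"] = zr
        self._mark("communities", n_communities=est.n_communities_)
        log.info("communities: %d (z_rand vs categories %.2f)",
                 est.n_communities_, zr)

    def stage_ordering(self):
        self._load_inputs()
        if self._cached("ordering"):
            log.info("ordering: cache hit")
            self._mem["ordering"] = pd.read_csv(self.out / "ordering.csv")
            return
        h = self._mem["hypergraph"]
        B = project(h, "muscle_centric")
        est = ord_mod.ShortestPathMDS(threshold=self.config.mds_threshold,
                                      variant=self.config.mds_variant).fit(B)
        frame = est.to_ordering().to_frame(self.config.mds_variant,
                                           self.config.mds_threshold)
        frame.to_csv(self.out / "ordering.csv", index=False)
        self._mem["ordering"] = frame
        self._mark("ordering")
        log.info("ordering: %d coordinates", len(frame))

    def stage_correlates(self):
        self._load_inputs()
        self._require("nulls", self.out / "deviation.csv")
        self._require("ordering", self.out / "ordering.csv")
        if self._cached("correlates"):
            log.info("correlates: cache hit")
            return
        cfg = self.config
        h = self._mem["hypergraph"]
        dev = self._mem.get("deviation")
        if dev is None:
            dev = pd.read_csv(self.out / "deviation.csv")
        ordering = self._mem.get("ordering")
        if ordering is None:
            ordering = pd.read_csv(self.out / "ordering.csv")
        cats = self._mem["categories"]
        cat_map = dict(zip(cats["muscle"], cats["category_id"]))

        if cfg.synthetic is not None:
            deviations = dict(zip(dev["muscle"], dev["deviation"]))
            recovery, volumes, groups = synthetic.generate_clinical_tables(
                h, deviations, effect_size=cfg.effect_size,
                noise_sd=cfg.noise_sd, seed=cfg.seed)
        else:
            recovery = pd.read_csv(cfg.recovery_table)
            volumes = pd.read_csv(cfg.volume_table)
            groups = {g: [m for m in h.muscle_labels
                          if cat_map.get(m) == g] for g in
                      recovery["group"].unique()}

        ratios = nulls_mod.deviation_ratio(dev, cat_map)
        results = {
            "degree_impact": stats.robust_weighted_fit(
                dev["degree"], dev["impact"]),
            "recovery": stats.recovery_regression(dev, recovery, groups),
            "volume": stats.volume_regression(dev, volumes, groups),
            "homunculus": stats.homunculus_regression(ratios),
            "ordering": stats.ordering_regression(
                ordering.rename(columns={"coordinate": "coordinate"}),
                cat_map),
        }
        report = stats.regression_report(
            results, inputs={"deviation": dev, "ordering": ordering,
                             "recovery": recovery, "volumes": volumes})
        report["seed"] = cfg.seed
        report["config_hash"] = cfg.digest()
        (self.out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        self._mark("correlates")
        log.info("correlates: %d regressions", len(results))

    def run(self, stages: Sequence[str] | None = None) -> dict:
        requested = list(stages) if stages else list(STAGES)
        unknown = set(requested) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage in requested:
                getattr(self, f"stage_{stage}")()
        report_path = self.out / "report.json"
        if report_path.exists():
            return json.loads(report_path.read_text())
        return {"stages_run": requested}


def run(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (default: all) and return the report."""
    return Pipeline(config).run(stages)
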
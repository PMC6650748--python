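"""End-to-end replication of the synthetic dissimilarity study.

Stages: synthesize stimuli -> standardize -> extract features ->
simulate raters and identifiers -> build dissimilarity matrices ->
RSA + ordinal MDS + identification/reliability analyses.  Every
stochastic stage draws its stream from the master seed, so a run is
fully determined by its configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior as bhv
from . import dissimilarity as dsm
from . import features as ftr
from . import io as sio
from . import mds as mdsmod
from . import raters
from . import rsa as rsamod
from .preprocess import PreprocessConfig, standardize_clip
from .stimuli import SynthConfig, build_stimulus_set

log = logging.getLogger("sounddissim")

ALL_STAGES = ("synth", "preprocess", "features", "simulate", "rsa", "mds", "behavior")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    stages: tuple = ALL_STAGES
    n_rating_participants: int = 50
    n_identification_participants: int = 21
    n_identification_blocks: int = 10
    n_permutations: int = 10_000
    mds_dimensions: int = 3
    mds_starts: int = 8
    pair_mode: str = "unordered"
    n_reliability_splits: int = 100
    rater: dict = field(default_factory=dict)       # RaterModel overrides
    identifier: dict = field(default_factory=dict)  # IdentifierModel overrides
    write_wavs: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_file(self, path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        Path(path).write_text(json.dumps(data, indent=2))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the in-memory artifacts.

    Writes all tables as CSV under ``config.out_dir`` along with the
    echoed configuration and a per-stage timing log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "run_config.json")
    artifacts: dict = {}
    timings: dict[str, float] = {}
    stage_set = set(config.stages)

    def _stage(name: str):
        return name in stage_set

    def _run(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception:
            log.error("stage %r failed", name)
            raise
        timings[name] = time.time() - t0
        log.info("stage %s done in %.2fs", name, timings[name])
        return result

    if _stage("synth"):
        artifacts["stimulus_set"] = _run(
            "synth", lambda: build_stimulus_set(SynthConfig(), seed=config.seed))
        if config.write_wavs:
            sio.write_stimulus_set(artifacts["stimulus_set"], out / "stimuli")

    if _stage("preprocess"):
        def _pre():
            ss = artifacts["stimulus_set"]
            pc = PreprocessConfig()
            ss.clips = [standardize_clip(c, pc) for c in ss.clips]
            ss.renderings = {k: standardize_clip(c, pc)
                             for k, c in ss.renderings.items()}
            return ss
        artifacts["stimulus_set"] = _run("preprocess", _pre)

    if _stage("features"):
        def _feat():
            ss = artifacts["stimulus_set"]
            table = ftr.extract_features(ss.clips, ss.categories)
            table.scalars.to_csv(out / "features.csv", index_label="item")
            for name, V in table.vectors.items():
                np.savetxt(out / f"feature_{name}.csv", V, delimiter=",")
            return table
        artifacts["features"] = _run("features", _feat)

    if _stage("simulate"):
        def _sim():
            feats = artifacts["features"]
            rater_model = raters.RaterModel(**config.rater)
            ratings = raters.simulate_ratings(
                feats, rater_model, config.n_rating_participants,
                seed=config.seed)
            sio.write_rating_table(ratings, out / "ratings.csv")
            ident_model = raters.IdentifierModel(**config.identifier)
            confusions = raters.simulate_identification(
                feats, ident_model, config.n_identification_participants,
                n_blocks=config.n_identification_blocks, seed=config.seed)
            confusions.to_csv(out / "identification.csv", index=False)
            return ratings, confusions
        artifacts["ratings"], artifacts["confusions"] = _run("simulate", _sim)

    if {"rsa", "mds", "behavior"} & stage_set:
        feats = artifacts["features"]
        ratings = artifacts["ratings"]
        group = dsm.aggregate_ratings(ratings, feats.items)
        group.categories = dict(feats.categories)
        group.value_range = (1.0, 9.0)
        sio.write_dissim_matrix(group, out / "dissimilarity_ratings.csv")
        artifacts["group_matrix"] = group

    if _stage("rsa"):
        def _rsa():
            report = rsamod.rsa_report(
                artifacts["group_matrix"], feats,
                n=config.n_permutations, seed=config.seed,
                pair_mode=config.pair_mode)
            report.table.to_csv(out / "rsa_report.csv", index=False)
            return report
        artifacts["rsa"] = _run("rsa", _rsa)

    if _stage("mds"):
        def _mds():
            sol = mdsmod.ordinal_mds(
                artifacts["group_matrix"], config.mds_dimensions,
                n_starts=config.mds_starts, seed=config.seed)
            corr = mdsmod.dimension_feature_correlations(sol, feats)
            sol.dimension_correlations = corr
            sol.coordinates.to_csv(out / "mds_coordinates.csv", index_label="item")
            corr.to_csv(out / "mds_dimension_correlations.csv", index=False)
            return sol
        artifacts["mds"] = _run("mds", _mds)

    if _stage("behavior"):
        def _bhv():
            ss_sub = artifacts["stimulus_set"].subcategories
            conf = bhv.ConfusionTable(artifacts["confusions"], feats.items, ss_sub)
            acc = bhv.item_accuracy(conf)
            acc.to_csv(out / "item_accuracy.csv", index=False)
            recoded = bhv.recode_subcategory(conf)
            recoded.to_csv(out / "subcategory_accuracy.csv", index=False)
            tests = bhv.accuracy_vs_chance(acc, 1.0 / len(feats.items))
            tests.to_csv(out / "accuracy_vs_chance.csv", index=False)
            tau_full = bhv.confusion_dissim_correlation(
                conf, artifacts["group_matrix"], mode="full")
            reliability = bhv.split_half_reliability(
                artifacts["ratings"], n_splits=config.n_reliability_splits,
                seed=config.seed)
            summary = {"confusion_rating_tau": tau_full,
                       "split_half_reliability": reliability}
            (out / "behavior_summary.json").write_text(json.dumps(summary, indent=2))
            return {"confusions": conf, "accuracy": acc, "recoded": recoded,
                    "chance_tests": tests, **summary}
        artifacts["behavior"] = _run("behavior", _bhv)

    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    return artifacts
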
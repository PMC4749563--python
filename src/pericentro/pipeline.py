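"""Pipeline orchestration: config loading, stage execution, manifests.

A run config (YAML or dict) names the stages to execute and their
parameters.  Stages run in dependency order; every output file is hashed
into a manifest together with the parameters and seed that produced it,
so identical config + seed gives identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .errors import PipelineError
from .events import MeiosisEventCounts, call_events, classify_proximity, events_to_frame, summarize
from .fluor import perkins_map_distance
from .genome import SuppressionModel
from .landscape import distance_to_cen_profile, metaplot_median, rpm_normalize
from .simulate import (
    make_toy_genome,
    simulate_chip_coverage,
    simulate_interval_tetrads,
    simulate_meiosis,
    simulate_spo11_reads,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "log_level",
    "genome",
    "model",
    "tetrads",
    "meiosis",
    "spo11",
    "chip",
    "proximity",
    "profile",
    "metaplot",
}

_KNOWN_STAGES = [
    "simulate-tetrads",
    "mapdist",
    "simulate-meiosis",
    "call-events",
    "proximity",
    "simulate-spo11",
    "spo11-profile",
    "simulate-chip",
    "metaplot",
]

_STAGE_DEPS = {
    "mapdist": ["simulate-tetrads"],
    "call-events": ["simulate-meiosis"],
    "proximity": ["call-events"],
    "spo11-profile": ["simulate-spo11"],
    "metaplot": ["simulate-chip"],
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "pericentro_out"
    stages: list[str] = field(default_factory=list)
    log_level: str = "info"
    genome: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    tetrads: dict = field(default_factory=dict)
    meiosis: dict = field(default_factory=dict)
    spo11: dict = field(default_factory=dict)
    chip: dict = field(default_factory=dict)
    proximity: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    metaplot: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        for s in cfg.stages:
            if s not in _KNOWN_STAGES:
                raise PipelineError(f"unknown stage {s!r} (known: {_KNOWN_STAGES})")
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages) or ["simulate-tetrads", "mapdist"]

    # run requested stages in canonical (dependency) order; a stage whose
    # dependency was not requested fails with an orchestration error
    wanted = set(stages)
    for s in stages:
        missing = [d for d in _STAGE_DEPS.get(s, []) if d not in wanted]
        if missing:
            raise PipelineError(f"stage {s!r} needs output of stage(s) {missing}")
    ordered = [s for s in _KNOWN_STAGES if s in wanted]

    outputs: dict[str, str] = {}
    state: dict = {}
    model = SuppressionModel(**config.model)
    genome = make_toy_genome(seed=config.seed, **config.genome)

    for stage in ordered:
        try:
            if stage == "simulate-tetrads":
                counts = simulate_interval_tetrads(
                    d_cm=config.tetrads.get("d_cm", 7.5),
                    n_tetrads=config.tetrads.get("n_tetrads", 5000),
                    seed=config.seed,
                )
                state["tetrad_counts"] = counts
                path = out_dir / "tetrad_counts.tsv"
                pio.write_tetrad_counts(counts, path, seed=config.seed, d_cm=config.tetrads.get("d_cm", 7.5))
                outputs["tetrad_counts.tsv"] = _sha256(path)
            elif stage == "mapdist":
                counts = state.get("tetrad_counts")
                if counts is None:
                    raise PipelineError("stage 'mapdist' needs output of 'simulate-tetrads'")
                est = perkins_map_distance(counts)
                result = {
                    "pd": counts.pd,
                    "npd": counts.npd,
                    "tt": counts.tt,
                    "excluded": counts.excluded,
                    "cm": est.cm,
                    "se": est.se,
                    "n": est.n,
                    "seed": config.seed,
                }
                path = out_dir / "mapdist.json"
                pio.write_json(result, path)
                outputs["mapdist.json"] = _sha256(path)
            elif stage == "simulate-meiosis":
                products = simulate_meiosis(
                    genome, model, n_tetrads=config.meiosis.get("n_tetrads", 8), seed=config.seed,
                    **{k: v for k, v in config.meiosis.items() if k != "n_tetrads"},
                )
                state["meiosis"] = products
                path = out_dir / "truth_log.tsv"
                products.truth.to_csv(path, sep="\t", index=False)
                outputs["truth_log.tsv"] = _sha256(path)
                for i, gm in enumerate(products.genotypes):
                    gpath = out_dir / f"genotypes_tetrad{i:03d}.tsv"
                    pio.write_genotypes(gm, gpath)
                    outputs[gpath.name] = _sha256(gpath)
            elif stage == "call-events":
                products = state.get("meiosis")
                if products is None:
                    raise PipelineError("stage 'call-events' needs output of 'simulate-meiosis'")
                all_events = []
                for i, gm in enumerate(products.genotypes):
                    evts = call_events(gm)
                    all_events.append(evts)
                state["events"] = all_events
                frames = []
                for i, evts in enumerate(all_events):
                    df = events_to_frame(evts)
                    df.insert(0, "tetrad", i)
                    frames.append(df)
                import pandas as pd

                path = out_dir / "events.tsv"
                combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
                combined["start"] = combined["start"] + 1 if len(combined) else combined.get("start")
                with open(path, "w") as fh:
                    fh.write("# coordinates: 1-based, inclusive\n")
                    combined.to_csv(fh, sep="\t", index=False)
                outputs["events.tsv"] = _sha256(path)
            elif stage == "proximity":
                all_events = state.get("events")
                if all_events is None:
                    raise PipelineError("stage 'proximity' needs output of 'call-events'")
                window = config.proximity.get("window", 20_000)
                pooled = [e for evts in all_events for e in evts]
                summary = classify_proximity(pooled, genome.centromere_table(), window=window)
                per_tetrad = [
                    MeiosisEventCounts(
                        co_count=sum(e.type == "CO" for e in evts),
                        nco_count=sum(e.type == "NCO" for e in evts),
                    )
                    for evts in all_events
                ]
                result = {
                    "window": window,
                    "co_within": summary.co_within,
                    "nco_within": summary.nco_within,
                    "co_total": summary.co_total,
                    "nco_total": summary.nco_total,
                    "pct_within": summary.pct_within,
                    "per_tetrad": summarize(per_tetrad),
                    "seed": config.seed,
                }
                path = out_dir / "proximity.json"
                pio.write_json(result, path)
                outputs["proximity.json"] = _sha256(path)
            elif stage == "simulate-spo11":
                track = simulate_spo11_reads(genome, model, seed=config.seed, **config.spo11)
                state["spo11"] = track
                path = out_dir / "spo11.bedgraph"
                pio.write_bedgraph(track, path)
                outputs["spo11.bedgraph"] = _sha256(path)
            elif stage == "spo11-profile":
                track = state.get("spo11")
                if track is None:
                    raise PipelineError("stage 'spo11-profile' needs output of 'simulate-spo11'")
                prof = distance_to_cen_profile(
                    rpm_normalize(track), genome.centromere_table(), seed=config.seed, **config.profile
                )
                path = out_dir / "spo11_profile.tsv"
                df = prof.to_frame()
                df["genome_average"] = prof.genome_average
                df.to_csv(path, sep="\t", index=False)
                outputs["spo11_profile.tsv"] = _sha256(path)
            elif stage == "simulate-chip":
                track = simulate_chip_coverage(genome, seed=config.seed, **config.chip)
                state["chip"] = track
                path = out_dir / "chip.bedgraph"
                pio.write_bedgraph(track, path)
                outputs["chip.bedgraph"] = _sha256(path)
            elif stage == "metaplot":
                track = state.get("chip")
                if track is None:
                    raise PipelineError("stage 'metaplot' needs output of 'simulate-chip'")
                meta = metaplot_median(rpm_normalize(track), genome.centromere_table(), **config.metaplot)
                path = out_dir / "metaplot.tsv"
                meta.to_csv(path, sep="\t", index=False)
                outputs["metaplot.tsv"] = _sha256(path)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"stage {stage!r} failed: {e}") from e

    manifest = {
        "seed": config.seed,
        "stages": ordered,
        "parameters": {
            "genome": config.genome,
            "model": config.model,
            "tetrads": config.tetrads,
            "meiosis": config.meiosis,
            "spo11": config.spo11,
            "chip": config.chip,
            "proximity": config.proximity,
            "profile": config.profile,
            "metaplot": config.metaplot,
        },
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
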
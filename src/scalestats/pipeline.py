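"""End-to-end pipeline orchestration with reproducible seeding.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
a master seed, an ordered list of stages, per-stage parameter blocks and
an output directory.  Each stage gets a deterministic sub-seed derived
from the master seed and its position, so stochastic outputs are exactly
reproducible and any stage can be re-run in isolation from the manifest.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .between import BetweenConfig, significance_profile
from .corpus import filter_corpus, read_corpus, write_corpus
from .diversity import (
    EmbeddingSpec,
    embed_and_cluster,
    equidistance_fraction,
    internal_deviations,
    note_index_entropy,
    note_index_histograms,
)
from .core import OctaveInferenceOptions, infer_octave_scale
from .corpus import Corpus
from .errors import ConfigError, ScaleStatsError
from .synthetic import GeneratorConfig, generate_corpus
from .within import WithinTestConfig, default_targets, interval_sweep, null_calibration

STAGES = ("generate", "between", "within", "diversity")


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    output_dir: str = "scalestats_run"
    generate: dict[str, Any] = field(default_factory=dict)
    between: dict[str, Any] = field(default_factory=dict)
    within: dict[str, Any] = field(default_factory=dict)
    diversity: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("run config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    # deterministic per-stage sub-seed, independent of stage order
    return int(
        np.random.SeedSequence([master, STAGES.index(stage)]).generate_state(1)[0]
        % (2**31 - 1)
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the configured stages; returns (and writes) the run manifest.

    The manifest records, per stage, the exact parameters, the derived
    seed, output paths with SHA-256 checksums, and wall time.  Re-running
    with the same config reproduces all outputs bit-exactly.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    corpus_path = out_dir / "corpus.csv"

    for stage in config.stages:
        t0 = time.time()
        seed = _stage_seed(config.seed, stage)
        params = dict(getattr(config, stage))
        outputs: list[Path] = []
        try:
            if stage == "generate":
                gcfg = GeneratorConfig(**params)
                corpus = generate_corpus(gcfg, seed=seed)
                write_corpus(corpus, corpus_path)
                outputs.append(corpus_path)
            elif stage == "between":
                corpus = read_corpus(corpus_path)
                model = params.pop("model", "lognorm")
                kind = params.pop("kind", "measured")
                bcfg = BetweenConfig(**params)
                sub = filter_corpus(corpus, kind=kind) if kind else corpus
                profile = significance_profile(sub, model, bcfg, seed=seed)
                path = out_dir / "between_profile.tsv"
                profile.to_frame().to_csv(path, sep="\t", index=False)
                outputs.append(path)
            elif stage == "within":
                corpus = read_corpus(corpus_path)
                kind = params.pop("kind", "measured")
                lo = params.pop("target_lo", 200.0)
                hi = params.pop("target_hi", 2600.0)
                step = params.pop("target_step", 20.0)
                n_null_sets = params.pop("n_null_sets", 0)
                wcfg = WithinTestConfig(**params)
                sub = filter_corpus(corpus, kind=kind) if kind else corpus
                targets = default_targets(lo, hi, step)
                sweep = interval_sweep(sub, targets, wcfg, seed)
                if n_null_sets:
                    cal = null_calibration(
                        sub, targets, wcfg, n_null_sets, seed=seed + 1
                    )
                    sweep.null_low = cal.null_low
                    sweep.null_high = cal.null_high
                path = out_dir / "within_sweep.tsv"
                sweep.to_frame().to_csv(path, sep="\t", index=False)
                outputs.append(path)
            elif stage == "diversity":
                corpus = read_corpus(corpus_path)
                n = params.pop("n_notes", 7)
                threshold = params.pop("threshold", 43.0)
                embed = params.pop("embed", True)
                records = []
                for r in corpus:
                    if r.n_steps != n:
                        continue
                    if r.kind == "octave":
                        records.append(r)
                    elif r.kind == "measured":
                        records.extend(infer_octave_scale(r, OctaveInferenceOptions()))
                    else:  # theory scales already span the octave exactly
                        if abs(r.span - 1200.0) < 1e-9:
                            records.append(r.with_notes(r.notes, kind="octave"))
                octaves = Corpus(records=records)
                octaves = Corpus(
                    records=[r for r in octaves if r.n_steps == n]
                )
                notes = np.vstack([r.notes for r in octaves])
                dev = internal_deviations(notes, n)
                frame = octaves.to_frame()
                frame["equidistance_deviation"] = dev
                path = out_dir / "diversity_deviations.tsv"
                frame.to_csv(path, sep="\t", index=False)
                outputs.append(path)
                hists = note_index_histograms(notes, n)
                ent = note_index_entropy(hists)
                epath = out_dir / "diversity_entropy.tsv"
                with open(epath, "w") as fh:
                    fh.write("note_number\tentropy_bits\n")
                    for num, e in zip(hists.note_numbers, ent):
                        fh.write(f"{num}\t{e:.6f}\n")
                outputs.append(epath)
                manifest.setdefault("diversity_summary", {})[
                    "equidistance_fraction"
                ] = float(np.mean(dev <= threshold))
                if embed and len(octaves) >= 10:
                    emb = embed_and_cluster(octaves, EmbeddingSpec(), seed=seed)
                    cpath = out_dir / "diversity_embedding.tsv"
                    emb.to_frame(octaves).to_csv(cpath, sep="\t", index=False)
                    outputs.append(cpath)
        except ScaleStatsError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ScaleStatsError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": seed,
            "params": dict(getattr(config, stage)),
            "outputs": {str(p): _sha256(p) for p in outputs},
            "wall_time_s": round(time.time() - t0, 3),
        }

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
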
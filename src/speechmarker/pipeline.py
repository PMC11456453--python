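"""End-to-end orchestration: simulate -> features -> compare -> classify -> regress.

Each stage reads and writes plain files (JSON transcripts, TSV lexicon, CSV
tables) under an output directory and records itself in ``manifest.json``:
input checksums, the master seed, package version and per-stage status.  The
manifest contains no timestamps, so identical configuration and seed produce
byte-identical outputs.  Warnings raised by missing-value policies are
captured into the manifest so silent data loss is impossible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .classify import ClassificationProtocol
from .corpus import (
    DEFAULT_TAG_MAPPING,
    cohort_to_frame,
    read_cohort,
    read_feature_table,
    read_lexicon,
    read_tag_mapping,
    read_transcript,
    write_cohort,
    write_feature_table,
    write_lexicon,
    write_transcript,
)
from .features import FeatureConfig, extract_cohort_features

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "run_stage", "STAGES"]

STAGES = ("simulate", "features", "compare", "classify", "regress")


@dataclass
class RunConfig:
    """Paths, thresholds, protocol knobs and the master seed for a run."""

    out_dir: str = "speechmarker_out"
    transcripts_dir: str | None = None
    lexicon_path: str | None = None
    tagmap_path: str | None = None
    cohort_path: str | None = None
    min_pause_s: float = 0.12
    long_pause_s: float = 2.0
    vif_threshold: float = 5.0
    oov_policy: str = "skip"
    protocol: ClassificationProtocol = field(default_factory=ClassificationProtocol)
    n_per_group: dict = field(default_factory=lambda: {"NC": 32, "early_AD": 48})
    seed: int = 0
    stages: tuple = STAGES

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        protocol = ClassificationProtocol(**data.pop("protocol", {}))
        return cls(protocol=protocol, **data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(config: RunConfig, out: Path, manifest: dict) -> None:
    from .synthetic import default_config, generate_cohort

    cohort = generate_cohort(default_config(seed=config.seed, n_per_group=config.n_per_group))
    tdir = out / "transcripts"
    tdir.mkdir(parents=True, exist_ok=True)
    for t in cohort.transcripts:
        write_transcript(t, tdir / f"{t.participant_id}.json")
    write_cohort(cohort.rows, out / "cohort.csv")
    write_lexicon(cohort.lexicon, out / "lexicon.tsv")
    (out / "truth.json").write_text(json.dumps(_jsonable(cohort.truth), indent=1))
    config.transcripts_dir = str(tdir)
    config.lexicon_path = str(out / "lexicon.tsv")
    config.cohort_path = str(out / "cohort.csv")
    manifest["stages"]["simulate"] = {
        "status": "ok",
        "n_transcripts": len(cohort.transcripts),
        "outputs": {p.name: _sha256(p) for p in (out / "cohort.csv", out / "lexicon.tsv")},
    }


def _require(config: RunConfig, attr: str, stage: str, needed_stage: str):
    value = getattr(config, attr)
    if value is None or not Path(value).exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {attr.replace('_path', '').replace('_dir', '')}; "
            f"run {needed_stage!r} first or point the config at existing files"
        )
    return Path(value)


def _stage_features(config: RunConfig, out: Path, manifest: dict) -> None:
    tdir = _require(config, "transcripts_dir", "features", "simulate")
    lex_path = _require(config, "lexicon_path", "features", "simulate")
    mapping = DEFAULT_TAG_MAPPING
    if config.tagmap_path:
        mapping = read_tag_mapping(config.tagmap_path)
    lexicon = read_lexicon(lex_path, oov_policy=config.oov_policy)
    transcripts = [read_transcript(p, mapping) for p in sorted(tdir.glob("*.json"))]
    fc = FeatureConfig(long_pause_threshold_s=config.long_pause_s, min_pause_s=config.min_pause_s)
    rows = extract_cohort_features(transcripts, lexicon, fc)
    path = out / "features.csv"
    write_feature_table(rows, path)
    manifest["stages"]["features"] = {
        "status": "ok",
        "n_participants": len(rows),
        "outputs": {path.name: _sha256(path)},
    }


def _merged_frame(config: RunConfig, stage: str):
    import pandas as pd

    cohort_path = _require(config, "cohort_path", stage, "simulate")
    feat_path = Path(config.out_dir) / "features.csv"
    if not feat_path.exists():
        raise FileNotFoundError(f"stage {stage!r} needs features.csv; run 'features' first")
    cohort = cohort_to_frame(read_cohort(cohort_path))
    feats = pd.DataFrame.from_dict(read_feature_table(feat_path), orient="index")
    feats.index.name = "participant_id"
    return cohort.merge(feats.reset_index(), on="participant_id", how="inner")


def _stage_compare(config: RunConfig, out: Path, manifest: dict) -> None:
    from .stats import compare_groups

    table = compare_groups(_merged_frame(config, "compare"))
    path = out / "group_comparison.csv"
    table.to_csv(path, index=False)
    manifest["stages"]["compare"] = {"status": "ok", "outputs": {path.name: _sha256(path)}}


def _stage_classify(config: RunConfig, out: Path, manifest: dict) -> None:
    from .classify import run_classification

    report = run_classification(
        _merged_frame(config, "classify"), protocol=config.protocol, seed=config.seed
    )
    rdir = out / "classification"
    report.to_csv(rdir)
    manifest["stages"]["classify"] = {
        "status": "ok",
        "outputs": {p.name: _sha256(p) for p in sorted(rdir.glob("*.csv"))},
    }


def _stage_regress(config: RunConfig, out: Path, manifest: dict) -> None:
    from .regress import regression_table, run_regression

    results = run_regression(
        _merged_frame(config, "regress"),
        vif_threshold=config.vif_threshold, seed=config.seed,
    )
    path = out / "regression.csv"
    regression_table(results).to_csv(path)
    manifest["stages"]["regress"] = {
        "status": "ok",
        "outcomes": sorted(results),
        "outputs": {path.name: _sha256(path)},
    }


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "compare": _stage_compare,
    "classify": _stage_classify,
    "regress": _stage_regress,
}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_stage(name: str, config: RunConfig, manifest: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _STAGE_FNS[name](config, out, manifest)


def run_all(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Any stage failure is recorded in the manifest and re-raised, so a partial
    run leaves a readable account of what completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "speechmarker",
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(
            {k: v for k, v in dataclasses.asdict(config).items() if k != "protocol"}
        ),
        "protocol": dataclasses.asdict(config.protocol),
        "stages": {},
    }
    try:
        for name in STAGES:
            if name in config.stages:
                logger.info("running stage %s", name)
                run_stage(name, config, manifest)
    except Exception as exc:
        manifest["stages"][name] = {"status": "error", "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
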
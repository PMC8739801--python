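"""Structured run configuration, YAML parsing and provenance records.

A :class:`RunConfig` fully determines a run: data source, extractor,
selection and loop settings, output directory and master seed.  Unknown
keys are rejected (with a closest-match suggestion) so typos never silently
fall back to defaults.  The master seed fans out to named sub-seeds; no
component touches global random state.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DataConfig(_Strict):
    folder: Optional[str] = None          # class-per-directory image folder
    embeddings: Optional[str] = None      # embedding table (.csv/.tsv/.npz)
    fixture: Optional[dict] = None        # FixtureSpec fields for synthetic data
    resize_to: tuple[int, int] = (32, 32)
    train_fraction: float = Field(0.8, gt=0, lt=1)
    base_fraction_of_train: float = Field(0.1, gt=0, lt=1)


class ExtractorConfig(_Strict):
    preset: Literal["tiny", "shallow", "middle", "deep"] = "tiny"
    base_width: Optional[int] = None
    input_shape: tuple[int, int, int] = (32, 32, 3)


class SelectionConfigModel(_Strict):
    strategy: Literal["hard_first", "easy_first", "bad_data", "random"] = (
        "hard_first"
    )
    quota: int = Field(40, ge=1)          # per-class picks per round
    class_balanced: bool = True


class LoopConfigModel(_Strict):
    rounds_max: int = Field(6, ge=1)
    target_accuracy: Optional[float] = Field(None, gt=0, le=1)
    retrain_mode: Literal["warm", "cold"] = "warm"
    epochs_per_round: int = Field(20, ge=0)
    learning_rate: float = Field(0.01, gt=0)
    batch_size: int = Field(32, ge=1)
    per_class_range: bool = False


class RunConfig(_Strict):
    data: DataConfig = DataConfig()
    extractor: ExtractorConfig = ExtractorConfig()
    selection: SelectionConfigModel = SelectionConfigModel()
    loop: LoopConfigModel = LoopConfigModel()
    out_dir: str = "erj_out"
    log_level: str = "INFO"
    seed: int = 0


def _suggest(unknown: str, model: type[BaseModel]) -> str:
    close = difflib.get_close_matches(unknown, model.model_fields.keys(), n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def parse_config(path: str | Path) -> RunConfig:
    """Parse a YAML config file; unknown keys raise with a suggestion."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return parse_config_dict(raw)


def parse_config_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        messages = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            msg = err["msg"]
            if err["type"] == "extra_forbidden":
                section = RunConfig
                if len(err["loc"]) > 1:
                    section = type(getattr(RunConfig(), str(err["loc"][0])))
                msg = f"unknown key{_suggest(str(err['loc'][-1]), section)}"
            messages.append(f"{loc}: {msg}")
        raise ValueError("invalid config: " + "; ".join(messages)) from exc


def emit_config(config: RunConfig) -> str:
    """Serialize a config to YAML; ``parse`` of the output round-trips."""
    return yaml.safe_dump(config.model_dump(), sort_keys=True)


def membership_hash(ids: list[str]) -> str:
    """Order-insensitive digest of a set of sample ids."""
    h = hashlib.sha256()
    for s in sorted(ids):
        h.update(s.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


def provenance_record(
    config: RunConfig,
    rounds,
    base_history: list[list[str]],
    path: str | Path | None = None,
) -> dict:
    """Provenance of a run: config, version, seeds and per-round base hashes."""
    record = {
        "erj_version": __version__,
        "config": config.model_dump(),
        "rounds": [
            {
                "round_index": r.round_index,
                "seeds_used": r.seeds_used,
                "test_accuracy": r.test_accuracy,
                "base_membership_hash": membership_hash(ids),
            }
            for r, ids in zip(rounds, base_history)
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(record, indent=1, sort_keys=True))
    return record
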
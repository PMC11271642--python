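"""End-to-end experiment orchestration.

Runs the full generate → label onsets → train → evaluate loop for a sweep
of (condition, montage) cells and writes per-cell fold tables, a summary
table, and a manifest from which the whole report bundle is reproducible.
A single global seed expands deterministically into per-subject, per-fold
substreams, so cells can run in any order with identical results.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import StudyConfig
from .evaluate import CONDITIONS, run_condition
from .montage import parse_montage_spec
from .synthetic import generate_dataset

DEFAULT_MONTAGES = ("custom:32", "custom:21", "custom:16", "custom:8",
                    "custom:4", "standard:32", "standard:21", "standard:16")


@dataclass
class ExperimentConfig:
    """A sweep of transfer conditions and montages on one synthetic study."""

    study: StudyConfig = field(default_factory=StudyConfig)
    montages: tuple = DEFAULT_MONTAGES
    conditions: tuple = ("A", "B", "C")
    seed: int = 0
    onset_source: str = "estimated"

    def __post_init__(self) -> None:
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        for spec in self.montages:
            parse_montage_spec(spec)   # raises on an invalid spec

    def to_dict(self) -> dict:
        return dict(study=self.study.to_dict(),
                    montages=list(self.montages),
                    conditions=list(self.conditions), seed=self.seed,
                    onset_source=self.onset_source)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(study=StudyConfig.from_dict(d["study"]),
                   montages=tuple(d["montages"]),
                   conditions=tuple(d["conditions"]), seed=d["seed"],
                   onset_source=d.get("onset_source", "estimated"))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig,
                   out_dir=None) -> dict:
    """Run every (condition, montage) cell of the sweep.

    Returns ``{(condition, montage_spec): ConditionReport}``; cells that
    fail are recorded in the manifest without affecting the others.  With
    ``out_dir`` set, writes ``folds_<condition>_<montage>.tsv`` per cell,
    ``summary.tsv``, and ``manifest.json``.
    """
    dataset = generate_dataset(config.study)
    reports, errors = {}, {}
    for condition in config.conditions:
        for spec in config.montages:
            montage = parse_montage_spec(spec)
            try:
                reports[(condition, spec)] = run_condition(
                    dataset, condition, montage, seed=config.seed,
                    onset_source=config.onset_source)
            except Exception:
                errors[f"{condition}/{spec}"] = traceback.format_exc()
    if out_dir is not None:
        _write_bundle(config, reports, errors, Path(out_dir))
    return reports


def summarize(reports: dict) -> pd.DataFrame:
    """Mean ± SD balanced accuracy per (condition, montage) cell."""
    return pd.DataFrame([r.summary() for r in reports.values()])


def _write_bundle(config, reports, errors, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for (condition, spec), report in reports.items():
        name = f"folds_{condition}_{spec.replace(':', '-')}.tsv"
        report.to_frame().to_csv(out / name, sep="\t", index=False)
    summarize(reports).to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest = dict(config=config.to_dict(), config_digest=config.digest(),
                    version=__version__, errors=errors,
                    cells=[f"{c}/{m}" for c, m in reports])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def rerun_from_manifest(manifest_path, out_dir=None) -> dict:
    """Re-run an experiment exactly as recorded in its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = ExperimentConfig.from_dict(manifest["config"])
    return run_experiment(config, out_dir=out_dir)
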
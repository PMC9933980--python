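"""End-to-end pipeline: simulate → preprocess → index → select → fit → grid → report.

A single :class:`RunConfig` drives every stage; one global seed
deterministically derives per-stage seeds so each stage is independently
reproducible. Every artifact is written to the output directory and listed,
with its SHA-256 digest, in a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .design import COMPONENTS, generate_design, records_to_frame
from .evaluation import ModelGrid, derive_seed, make_cv_plan
from .ltri import LTRIModel
from .preprocess import PreprocessConfig, preprocess_chain
from .selection import CARSConfig, SPAConfig, UVEConfig
from .simulate import GeneratorConfig, simulate_biochemistry, simulate_spectra


class PipelineError(RuntimeError):
    pass


_KNOWN_KEYS = {
    "seed", "out_dir", "n_plants_per_cell", "n_bands", "sg_window", "sg_polyorder",
    "selection_mode", "indices", "band_methods", "families", "cv_folds",
    "max_repeats", "model_params", "selection_params", "verbosity",
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "frostspec_run"
    n_plants_per_cell: int = 16
    n_bands: int = 176
    sg_window: int = 11
    sg_polyorder: int = 2
    selection_mode: str = "per_fold"
    indices: list[str] = field(default_factory=lambda: list(COMPONENTS) + ["LTRI"])
    band_methods: list[str] = field(default_factory=lambda: ["CARS", "SPA", "UVE", "NONE"])
    families: list[str] = field(default_factory=lambda: ["PLS", "SVM", "RF", "BP", "CNN", "LSTM"])
    cv_folds: int = 5
    max_repeats: int | None = None
    model_params: dict = field(default_factory=dict)
    selection_params: dict = field(default_factory=dict)
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(obj) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**obj)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _selection_configs(params: dict) -> dict:
    out = {}
    classes = {"SPA": SPAConfig, "CARS": CARSConfig, "UVE": UVEConfig}
    for method, overrides in params.items():
        out[method.upper()] = classes[method.upper()](**overrides)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, returning the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record(stage: str, path: Path) -> None:
        manifest["stages"].setdefault(stage, []).append(
            {"path": str(path), "sha256": _digest(path)}
        )

    stage = "simulate"
    try:
        gen = GeneratorConfig(seed=derive_seed(config.seed, "simulate"),
                              n_bands=config.n_bands)
        records = simulate_biochemistry(generate_design(config.n_plants_per_cell), gen)
        spectra = simulate_spectra(records, gen)
        panel = records_to_frame(records)
        fio.write_panel(panel, out / "biochem.csv")
        record(stage, out / "biochem.csv")
        fio.write_spectra(spectra, out / "spectra_raw.csv")
        record(stage, out / "spectra_raw.csv")

        stage = "preprocess"
        pre = preprocess_chain(
            spectra, PreprocessConfig(config.sg_window, config.sg_polyorder)
        )
        fio.write_spectra(pre, out / "spectra_preprocessed.csv")
        record(stage, out / "spectra_preprocessed.csv")

        stage = "ltri"
        fit = LTRIModel(panel).fit()
        panel["LTRI"] = fit.scores
        fio.write_panel(panel, out / "biochem_with_ltri.csv")
        record(stage, out / "biochem_with_ltri.csv")
        fit.coefficient_table().to_csv(out / "ltri_coefficients.csv")
        record(stage, out / "ltri_coefficients.csv")
        (out / "ltri_summary.txt").write_text(fit.summary() + "\n")
        record(stage, out / "ltri_summary.txt")

        stage = "grid"
        cv = make_cv_plan(pre.n_samples, config.cv_folds,
                          derive_seed(config.seed, "cv"))
        grid = ModelGrid(
            pre,
            panel[config.indices],
            indices=config.indices,
            band_methods=config.band_methods,
            families=config.families,
            cv=cv,
            selection_mode=config.selection_mode,
            selection_configs=_selection_configs(config.selection_params),
            model_params=config.model_params,
            max_repeats=config.max_repeats,
            seed=derive_seed(config.seed, "grid"),
        ).fit()
        grid.table.to_csv(out / "grid_results.csv", index=False)
        record(stage, out / "grid_results.csv")

        stage = "report"
        report = grid.summary()
        (out / "report.txt").write_text(report + "\n")
        record(stage, out / "report.txt")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
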
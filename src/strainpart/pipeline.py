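"""End-to-end orchestration: simulate → measure → stats → cca.

A single YAML-configurable entry point runs the synthetic-monolayer
generator, the strain/morphology measurement, the correlation statistics and
the canonical correlation analysis in dependency order, writing CSV/JSON
artifacts plus a run manifest. All randomness derives from one master seed,
so a rerun with the same config reproduces every deterministic output
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import build_multicellular_features, fit_cca, predict_strain_correlations
from .measure import measure_pair, read_label_frame
from .stats import correlation_report, strain_bin_test
from .synthetic import (
    RatioDistribution,
    StretchParams,
    apply_stretch,
    generate_geometry,
    render_frame,
    write_frames,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "configure_logging", "default_config"]

STAGES = ("simulate", "measure", "stats", "cca")


def configure_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Structured logging to console and, optionally, a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunConfig:
    """Pipeline configuration; per-stage parameter blocks, one master seed."""

    outdir: str = "strainpart_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"

    # simulate
    n_cells: int = 150
    field_size: tuple[float, float] | None = None
    nucleus_area_fraction: float = 0.2
    pixel_size: float = 0.25
    intensity_cv: float = 0.15
    mean_strain: float = 0.25
    sigma_cell_strain: float = 0.05
    ratio_dist: str = "lognormal:0.5,1.5"
    length_fractions: tuple[float, float] | None = (0.5, 0.5)
    global_offset: tuple[float, float] = (2.0, 0.5)

    # measure (used instead of simulate outputs when mask paths are given)
    pre_cells: str | None = None
    pre_nuclei: str | None = None
    pre_intensity: str | None = None
    post_cells: str | None = None
    post_nuclei: str | None = None
    post_intensity: str | None = None
    strain_guess: float | None = None
    register: bool = True

    # stats
    stats_x: str = "eps_c"
    stats_y: str = "eps_n"
    n_boot: int = 10_000
    n_perm: int = 10_000

    # cca
    cca_mode: str = "unicellular"
    cca_neighbours: int = 3

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("field_size", "length_fractions", "global_offset", "stages"):
            val = getattr(cfg, key)
            if isinstance(val, list):
                setattr(cfg, key, tuple(val))
        return cfg

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, val in out.items():
            if isinstance(val, tuple):
                out[key] = list(val)
        return out


def default_config(**overrides) -> RunConfig:
    """The demo configuration: a heterogeneous synthetic monolayer end to end."""
    return dataclasses.replace(RunConfig(), **overrides)


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("geometry", "stretch", "render_pre", "render_post", "stats", "cca")
    state = np.random.SeedSequence(seed).generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in state)))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; returns the manifest.

    The manifest lists every produced file, the full parameter set and the
    derived per-stage seeds. A missing upstream product (e.g. ``stats``
    without ``measure``) raises an error naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    outputs: list[Path] = []
    stages_run: list[str] = []

    pre = post = None
    truth = None
    strain_table = morph_table = None

    if "simulate" in config.stages:
        logger.info("stage simulate: %d cells", config.n_cells)
        geom = generate_geometry(
            config.n_cells,
            field_size=config.field_size,
            seed=seeds["geometry"],
            nucleus_area_fraction=config.nucleus_area_fraction,
        )
        params = StretchParams(
            mean_strain=config.mean_strain,
            sigma_cell_strain=config.sigma_cell_strain,
            partition_ratio_dist=RatioDistribution.from_string(config.ratio_dist),
            length_fractions=config.length_fractions,
            global_offset=config.global_offset,
            seed=seeds["stretch"],
        )
        post_geom = apply_stretch(geom, params)
        truth = post_geom.true_strain
        pre = render_frame(geom, config.pixel_size, config.intensity_cv, seeds["render_pre"])
        post = render_frame(post_geom, config.pixel_size, config.intensity_cv, seeds["render_post"])
        outputs += write_frames(pre, post, outdir, truth)
        stages_run.append("simulate")

    if "measure" in config.stages:
        if pre is None:
            if not (config.pre_cells and config.pre_nuclei and config.post_cells and config.post_nuclei):
                raise RuntimeError("stage 'measure' needs simulate outputs or mask paths")
            pre = read_label_frame(config.pre_cells, config.pre_nuclei,
                                   config.pre_intensity, config.pixel_size)
            post = read_label_frame(config.post_cells, config.post_nuclei,
                                    config.post_intensity, config.pixel_size)
        guess = config.strain_guess if config.strain_guess is not None else config.mean_strain
        strain_table, morph_table, diag = measure_pair(
            pre, post, strain_guess=guess, register=config.register
        )
        strain_path = outdir / "strains.csv"
        morph_path = outdir / "morphology.csv"
        strain_table.to_csv(strain_path, index=False)
        morph_table.to_csv(morph_path, index=False)
        diag_path = outdir / "measure_diagnostics.json"
        diag_path.write_text(json.dumps(_jsonable(diag), indent=2))
        outputs += [strain_path, morph_path, diag_path]
        stages_run.append("measure")

    if "stats" in config.stages:
        if strain_table is None:
            raise RuntimeError("stage 'stats' needs the 'measure' stage output")
        report = correlation_report(
            strain_table[config.stats_x],
            strain_table[config.stats_y],
            n_boot=config.n_boot,
            n_perm=config.n_perm,
            seed=seeds["stats"],
        ).to_dict()
        report["x"], report["y"] = config.stats_x, config.stats_y
        try:
            report["strain_bin_test"] = strain_bin_test(strain_table)
        except (ValueError, KeyError) as exc:
            report["strain_bin_test"] = {"error": str(exc)}
        stats_path = outdir / "stats_report.json"
        stats_path.write_text(json.dumps(report, indent=2))
        outputs.append(stats_path)
        stages_run.append("stats")

    if "cca" in config.stages:
        if strain_table is None or morph_table is None:
            raise RuntimeError("stage 'cca' needs the 'measure' stage output")
        cca_out = _run_cca(strain_table, morph_table, config, outdir)
        outputs += cca_out
        stages_run.append("cca")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": config.to_dict(),
        "stages_run": stages_run,
        "outputs": [str(p.relative_to(outdir)) for p in outputs],
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    for path in outputs:
        if not path.exists():  # pragma: no cover - manifest integrity guard
            raise RuntimeError(f"manifest lists missing output: {path}")
    return manifest


def _run_cca(strain_table: pd.DataFrame, morph_table: pd.DataFrame,
             config: RunConfig, outdir: Path) -> list[Path]:
    from .measure import MORPHOLOGY_FEATURES

    if config.cca_mode == "multicellular":
        cin = build_multicellular_features(
            morph_table, strain_table, k=config.cca_neighbours
        )
        X, Y, names = cin.X, cin.Y, cin.feature_names
    elif config.cca_mode == "unicellular":
        df = morph_table[~morph_table["touches_border"].astype(bool)]
        df = df.merge(strain_table, on="cell_id")
        names = tuple(c for c in MORPHOLOGY_FEATURES if c in df.columns)
        df = df.dropna(subset=list(names))
        X = df[list(names)].to_numpy(float)
        Y = df[["eps_n", "eps_c", "eps_cell"]].to_numpy(float)
    else:
        raise ValueError("cca_mode must be 'unicellular' or 'multicellular'")
    result = fit_cca(X, Y, n_components=3, feature_names=names,
                     strain_names=("eps_n", "eps_c", "eps_cell"))
    pred = predict_strain_correlations(result, Y)
    payload = {
        "mode": config.cca_mode,
        "n": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "canonical_correlations": result.correlations.tolist(),
        "strain_weights": result.weights_y.tolist(),
        "predicted_strain_correlations": pred.to_dict(orient="records"),
    }
    cca_path = outdir / "cca.json"
    cca_path.write_text(json.dumps(payload, indent=2))
    weights = pd.DataFrame(
        result.weights_x, index=list(names),
        columns=[f"u{i + 1}" for i in range(result.weights_x.shape[1])],
    )
    weights_path = outdir / "cca_morphology_weights.csv"
    weights.to_csv(weights_path, index_label="feature")
    return [cca_path, weights_path]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
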
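"""Table readers/writers, run manifests and the pipeline driver.

Tables are plain CSV/TSV with documented headers (delimiter inferred from
the file extension).  ``spots`` tables need cell_id, replicate_id, channel,
x, y, z, intensity, compartment; ``cells`` tables need cell_id,
replicate_id, length, width, n_nuclei plus nucleus-sphere columns
(nuc1_x/y/z/r, optionally nuc2_*).  Unknown columns pass through untouched.

Every pipeline run writes a manifest recording the config, the root seed
and its per-stage splits, output digests and stage timings, so a run can be
reproduced bit-identically for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .infer import PriorSpec, grid_posterior, select_model, summarize_dataset
from .model import ModelSpec
from .noise import cell_volume, size_corrected_fano
from .spots import CELL_COLUMNS, SPOT_COLUMNS, CountingConfig, build_count_table
from .ssa import ssa_sample
from .synthetic import PopulationConfig, SpotNoiseConfig, generate_population, generate_spot_table


class SchemaError(ValueError):
    """A table is missing required columns or contains invalid values."""


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_delimiter(path))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name} table {path} is missing required column(s): {', '.join(missing)}"
        )
    return df


def read_spots(path) -> pd.DataFrame:
    df = _read_table(path, SPOT_COLUMNS, "spots")
    bad = df.index[~(df["intensity"] > 0)].tolist()
    if bad:
        raise SchemaError(f"spots table {path}: non-positive intensity in rows {bad}")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy(float)).all():
        raise SchemaError(f"spots table {path}: non-finite coordinates")
    return df


def read_cells(path) -> pd.DataFrame:
    df = _read_table(path, CELL_COLUMNS, "cells")
    if ((df["width"] <= 0) | (df["length"] < df["width"])).any():
        raise SchemaError(f"cells table {path}: need length >= width > 0")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path), index=False)
    return path


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    root_seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # name -> sha256
    timings: dict = field(default_factory=dict)  # name -> seconds
    version: str = __version__

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def stage_seeds(root_seed: int, names) -> dict:
    """Independent per-stage seeds split from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def run_pipeline(config: dict, out_dir, seed: int = 0) -> RunManifest:
    """Execute simulate -> count -> fano -> (infer/select) per config switches.

    ``config`` keys (all optional): ``population`` (PopulationConfig fields,
    with ``model`` as a ModelSpec dict), ``spot_noise`` (SpotNoiseConfig
    fields), ``counting`` (method, percentile), ``ts_mode``, ``size_variable``
    (length|volume), ``infer`` ({n_txn, n_deg}), ``select`` (bool),
    ``prior`` (bounds, resolution).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, root_seed=int(seed))
    seeds = stage_seeds(seed, ["simulate", "spots", "fano", "summary"])
    manifest.stage_seeds = seeds

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        pop_cfg = dict(config.get("population", {}))
        if "model" in pop_cfg:
            pop_cfg["model"] = ModelSpec.from_dict(pop_cfg["model"])
        pop = PopulationConfig(**pop_cfg)
        cells, truth = generate_population(pop, seed=seeds["simulate"])
        noise_cfg = SpotNoiseConfig(**config.get("spot_noise", {}))
        spots = generate_spot_table(cells, truth, noise_cfg, seed=seeds["spots"])
        for name, df in (("cells", cells), ("spots", spots), ("truth", truth)):
            p = write_table(df, out / f"{name}.csv")
            manifest.outputs[name] = file_digest(p)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "count"
        t0 = time.perf_counter()
        counting = config.get("counting", {})
        cc = CountingConfig(
            method=counting.get("method", "hybrid"),
            single_molecule_percentile=counting.get("percentile", 95.0),
        )
        counts = build_count_table(
            cells, spots.drop(columns=["true_label"]), cc,
            ts_mode=config.get("ts_mode", "expand"),
        )
        p = write_table(counts, out / "counts.csv")
        manifest.outputs["counts"] = file_digest(p)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "fano"
        t0 = time.perf_counter()
        merged = counts.merge(cells[["cell_id", "length", "width"]], on="cell_id")
        if config.get("size_variable", "length") == "volume":
            sizes = cell_volume(merged["length"], merged["width"])
            size_var = "volume"
        else:
            sizes = merged["length"].to_numpy(float)
            size_var = "length"
        fano = size_corrected_fano(
            merged["total"].to_numpy(float), sizes,
            seed=seeds["fano"], size_variable=size_var,
        )
        (out / "fano.json").write_text(json.dumps(asdict(fano), indent=2))
        manifest.outputs["fano"] = file_digest(out / "fano.json")
        manifest.timings[stage] = time.perf_counter() - t0

        if config.get("infer") or config.get("select"):
            stage = "summary"
            t0 = time.perf_counter()
            stats = summarize_dataset(merged, sizes, seed=seeds["summary"])
            manifest.timings[stage] = time.perf_counter() - t0
            prior = PriorSpec(**config.get("prior", {}))
            if config.get("infer"):
                stage = "infer"
                t0 = time.perf_counter()
                inf = config["infer"]
                post = grid_posterior(stats, inf["n_txn"], inf["n_deg"], prior)
                payload = {
                    "axes": {k: v.tolist() for k, v in post.axes.items()},
                    "log_evidence": post.log_evidence,
                    "boundary_mass": post.boundary_mass,
                    "mode": post.mode(),
                }
                (out / "posterior.json").write_text(json.dumps(payload, indent=2))
                np.savetxt(out / "posterior_mass.csv",
                           post.mass.reshape(post.mass.shape[0], -1), delimiter=",")
                manifest.outputs["posterior"] = file_digest(out / "posterior.json")
                manifest.timings[stage] = time.perf_counter() - t0
            if config.get("select"):
                stage = "select"
                t0 = time.perf_counter()
                table = select_model(stats, config.get("candidates"), prior)
                p = write_table(table, out / "evidence.csv")
                manifest.outputs["evidence"] = file_digest(p)
                manifest.timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.save(out / "manifest.json")
    return manifest
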
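"""Synthetic smFISH populations with known ground truth.

Emulates the statistical structure of fission-yeast smFISH tables: cell
lengths 7–16 μm (lognormal around a 10 μm median), widths near 3.5 μm, a
mono/binucleated split, low mRNA means (2–5) that increase with cell size,
single-molecule spot intensities clustered at 1 with occasional bright
transcription-site spots, and bimodal spot-to-TS distance distributions.

Counts are drawn from the stationary distribution of the expression model
conditioned on each cell's size (quasi-static size coupling: transcription
rates scale as (length/median)^exponent while export and degradation stay
fixed, so mean mRNA number grows with size but concentration is roughly
constant).  Every downstream quantity (per-cell counts, spot labels) is
recorded as ground truth, making the generator the oracle for the counting
and classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelSpec
from .ssa import ssa_sample

DEFAULT_MODEL = ModelSpec(3, (10.0, 10.0), 5.0, 3)


@dataclass(frozen=True)
class PopulationConfig:
    n_cells: int = 1000
    length_median: float = 10.0  # μm
    length_sigma: float = 0.15  # sd of log length
    length_bounds: tuple[float, float] = (7.0, 16.0)
    width_mean: float = 3.5  # μm
    width_sd: float = 0.1
    binucleated_fraction: float = 0.2
    size_exponent: float = 1.0  # transcription rates ∝ (length/median)^exponent
    binucleate_multiplier: float = 1.0  # optional txn-rate factor for bi cells
    nucleus_radius: float = 1.2  # μm
    model: ModelSpec = DEFAULT_MODEL

    def __post_init__(self):
        if not 0 <= self.binucleated_fraction <= 1:
            raise ValueError("binucleated_fraction must be in [0, 1]")
        if self.length_bounds[0] >= self.length_bounds[1]:
            raise ValueError("invalid length bounds")


@dataclass(frozen=True)
class SpotNoiseConfig:
    intensity_median: float = 1.0
    intensity_cv: float = 0.25  # lognormal CV of single-molecule intensities
    nascent_radius: float = 0.3  # μm around the TS
    nascent_fraction: float = 0.6  # of nuclear mRNA
    ts_intensity: float = 5.0
    chromatic_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _truncated_lognormal(rng, median, sigma, bounds, size):
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = np.exp(np.log(median) + sigma * rng.standard_normal(need.size))
        ok = (draw >= bounds[0]) & (draw <= bounds[1])
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def generate_population(
    pop: PopulationConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw cells and their true compartment counts.

    Returns (cells, truth): ``cells`` has the documented cell-table schema
    (sizes, nuclei as spheres); ``truth`` holds the generating (nuclear,
    cytoplasmic) counts per cell.
    """
    rng = np.random.default_rng(seed)
    n = pop.n_cells
    lengths = _truncated_lognormal(
        rng, pop.length_median, pop.length_sigma, pop.length_bounds, n
    )
    widths = np.clip(pop.width_mean + pop.width_sd * rng.standard_normal(n), 1.5, None)
    widths = np.minimum(widths, lengths)  # degenerate safety, essentially never hit
    binuc = rng.random(n) < pop.binucleated_fraction
    cell_seeds = rng.integers(0, 2**31 - 1, size=n)

    cells = []
    truths = []
    for i in range(n):
        factor = (lengths[i] / pop.length_median) ** pop.size_exponent
        if binuc[i]:
            factor *= pop.binucleate_multiplier
        spec = replace(
            pop.model,
            txn_rates=tuple(r * factor for r in pop.model.txn_rates),
        )
        m, c = ssa_sample(spec, 1, seed=int(cell_seeds[i]))[0]
        r = pop.nucleus_radius
        rec = {
            "cell_id": f"cell{i:05d}",
            "replicate_id": "rep1",
            "length": lengths[i],
            "width": widths[i],
            "n_nuclei": 2 if binuc[i] else 1,
            "nuc1_x": -lengths[i] / 4 if binuc[i] else 0.0,
            "nuc1_y": 0.0,
            "nuc1_z": 0.0,
            "nuc1_r": r,
            "nuc2_x": lengths[i] / 4 if binuc[i] else np.nan,
            "nuc2_y": 0.0 if binuc[i] else np.nan,
            "nuc2_z": 0.0 if binuc[i] else np.nan,
            "nuc2_r": r if binuc[i] else np.nan,
        }
        cells.append(rec)
        truths.append(
            {
                "cell_id": rec["cell_id"],
                "nuclear": int(m),
                "cytoplasmic": int(c),
                "length": lengths[i],
                "n_nuclei": rec["n_nuclei"],
            }
        )
    return pd.DataFrame(cells), pd.DataFrame(truths)


def _uniform_in_ball(rng, center, radius, size):
    pts = rng.standard_normal((size, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    rad = radius * rng.random(size) ** (1 / 3)
    return center + pts * rad[:, None]


def _uniform_in_cell(rng, length, width, nuclei, n):
    """Uniform points in the spherocylinder (axis along x) outside nuclei."""
    out = np.empty((n, 3))
    got = 0
    r = width / 2
    half = length / 2 - r  # cylinder half-length
    while got < n:
        k = max(4 * (n - got), 16)
        x = (rng.random(k) * length) - length / 2
        yz = (rng.random((k, 2)) * width) - r
        pts = np.column_stack([x, yz])
        # inside spherocylinder?
        ax = np.clip(np.abs(pts[:, 0]) - half, 0, None)
        inside = ax**2 + pts[:, 1] ** 2 + pts[:, 2] ** 2 <= r**2
        for c, rad in nuclei:
            inside &= ((pts - c) ** 2).sum(axis=1) > rad**2
        pts = pts[inside]
        take = min(len(pts), n - got)
        out[got : got + take] = pts[:take]
        got += take
    return out


def generate_spot_table(
    cells: pd.DataFrame,
    truth: pd.DataFrame,
    noise: SpotNoiseConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Render per-cell counts into a spot table with known labels.

    One TS spot per nucleus; each nuclear mRNA is nascent with the
    configured probability (placed within ``nascent_radius`` of its TS) or
    mature (uniform in the nucleus sphere, outside that radius); cytoplasmic
    mRNA is uniform in the cell body outside nuclei.  The hidden
    ``true_label`` column carries the generating compartment of every spot.
    """
    noise = noise or SpotNoiseConfig()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + noise.intensity_cv**2))
    truth = truth.set_index("cell_id")
    rows = []

    def emit(cid, rep, channel, xyz, intensity, compartment, label):
        rows.append(
            {
                "cell_id": cid,
                "replicate_id": rep,
                "channel": channel,
                "x": xyz[0],
                "y": xyz[1],
                "z": xyz[2],
                "intensity": intensity,
                "compartment": compartment,
                "true_label": label,
            }
        )

    def intensities(k):
        return np.exp(np.log(noise.intensity_median) + sigma * rng.standard_normal(k))

    for _, cell in cells.iterrows():
        cid = cell["cell_id"]
        rep = cell["replicate_id"]
        nuclei = []
        ts_pos = []
        for i in (1, 2):
            if pd.notna(cell.get(f"nuc{i}_x", np.nan)):
                c = np.array([cell[f"nuc{i}_x"], cell[f"nuc{i}_y"], cell[f"nuc{i}_z"]])
                rad = cell[f"nuc{i}_r"]
                nuclei.append((c, rad))
                ts = _uniform_in_ball(rng, c, 0.5 * rad, 1)[0]
                ts_pos.append(ts)
                emit(cid, rep, "TS", ts + np.asarray(noise.chromatic_offset),
                     noise.ts_intensity, "nuclear", "TS")
        t = truth.loc[cid]
        n_nuc, n_cyt = int(t["nuclear"]), int(t["cytoplasmic"])
        if n_nuc and nuclei:
            which_nuc = rng.integers(0, len(nuclei), n_nuc)
            nascent = rng.random(n_nuc) < noise.nascent_fraction
            ints = intensities(n_nuc)
            for j in range(n_nuc):
                c, rad = nuclei[which_nuc[j]]
                ts = ts_pos[which_nuc[j]]
                if nascent[j]:
                    xyz = _uniform_in_ball(rng, ts, noise.nascent_radius, 1)[0]
                    label = "nascent"
                else:
                    # uniform in nucleus, rejected out of the nascent shell
                    while True:
                        xyz = _uniform_in_ball(rng, c, rad, 1)[0]
                        if np.linalg.norm(xyz - ts) > noise.nascent_radius * 2:
                            break
                    label = "mature_nuclear"
                emit(cid, rep, "mRNA", xyz, ints[j], "nuclear", label)
        if n_cyt:
            pts = _uniform_in_cell(rng, cell["length"], cell["width"], nuclei, n_cyt)
            ints = intensities(n_cyt)
            for j in range(n_cyt):
                emit(cid, rep, "mRNA", pts[j], ints[j], "cytoplasmic", "cytoplasmic")
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "replicate_id", "channel", "x", "y", "z",
                 "intensity", "compartment", "true_label"],
    )
    return df
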
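"""Per-cell mRNA counting from smFISH spot tables.

Input is tabular: one row per detected spot (mRNA probe channel or
GFP-marked transcription-site channel) with 3D position, intensity and a
nuclear/cytoplasmic compartment label, plus one row per cell with its size
and nucleus geometry (spheres).  This module implements the counting rules
downstream of spot detection:

* intensity normalization by the median cytoplasmic spot of each replicate,
* spot / intensity / hybrid counting (hybrid: spots dimmer than the
  replicate's cytoplasmic 95th percentile count as one molecule, brighter
  spots as their normalized intensity),
* nascent vs mature classification of nuclear spots by a per-replicate
  distance cutoff at the minimum between the two modes of the
  spot-to-transcription-site distance distribution,
* transcription-site (TS) cell filters and nucleus-expansion handling of TS
  spots that fall just outside the segmented nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

MRNA = "mRNA"
TS = "TS"

SPOT_COLUMNS = [
    "cell_id",
    "replicate_id",
    "channel",
    "x",
    "y",
    "z",
    "intensity",
    "compartment",
]
CELL_COLUMNS = ["cell_id", "replicate_id", "length", "width", "n_nuclei"]


@dataclass(frozen=True)
class CountingConfig:
    """How spots become molecule counts.

    ``single_molecule_percentile`` is the percentile (linear-interpolation
    quantile) of normalized cytoplasmic intensities below which a spot is
    taken to contain exactly one molecule under the hybrid rule.
    """

    method: str = "hybrid"  # {spot, intensity, hybrid}
    single_molecule_percentile: float = 95.0

    def __post_init__(self):
        if self.method not in ("spot", "intensity", "hybrid"):
            raise ValueError(f"unknown counting method {self.method!r}")
        if not 0 < self.single_molecule_percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


def normalize_intensities(spots: pd.DataFrame) -> pd.DataFrame:
    """Divide each mRNA spot's intensity by the median cytoplasmic mRNA
    intensity of its replicate; TS-channel rows pass through untouched."""
    spots = spots.copy()
    is_mrna = spots["channel"] == MRNA
    for rep, grp in spots[is_mrna].groupby("replicate_id"):
        cyt = grp.loc[grp["compartment"] == "cytoplasmic", "intensity"]
        if cyt.empty:
            raise ValueError(
                f"replicate {rep!r} has no cytoplasmic mRNA spots to normalize by"
            )
        med = float(cyt.median())
        sel = is_mrna & (spots["replicate_id"] == rep)
        spots.loc[sel, "intensity"] = spots.loc[sel, "intensity"] / med
    return spots


def single_molecule_threshold(
    spots: pd.DataFrame, percentile: float = 95.0
) -> dict:
    """Per-replicate percentile of normalized cytoplasmic mRNA intensities."""
    out = {}
    sel = (spots["channel"] == MRNA) & (spots["compartment"] == "cytoplasmic")
    for rep, grp in spots[sel].groupby("replicate_id"):
        out[rep] = float(np.percentile(grp["intensity"].to_numpy(), percentile))
    return out


def count_spots(intensities: np.ndarray, threshold: float, method: str) -> float:
    """Molecule count of one set of spots under one counting rule."""
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        return 0.0
    if method == "spot":
        return float(x.size)
    if method == "intensity":
        return float(x.sum())
    # hybrid: dim spots are single molecules, bright ones their intensity
    return float(np.where(x < threshold, 1.0, x).sum())


def count_cell(
    cell_spots: pd.DataFrame,
    cytoplasmic_reference: np.ndarray,
    config: CountingConfig,
) -> float:
    """Count one cell's mRNA spots against a replicate reference set."""
    thr = float(
        np.percentile(np.asarray(cytoplasmic_reference, dtype=float),
                      config.single_molecule_percentile)
    ) if len(cytoplasmic_reference) else np.inf
    sel = cell_spots["channel"] == MRNA
    return count_spots(cell_spots.loc[sel, "intensity"].to_numpy(), thr, config.method)


def _nucleus_arrays(cells: pd.DataFrame):
    """Nucleus sphere parameters as dict cell_id -> (centers (k,3), radii (k,))."""
    out = {}
    for _, row in cells.iterrows():
        centers, radii = [], []
        for i in (1, 2):
            cx = row.get(f"nuc{i}_x", np.nan)
            if pd.notna(cx):
                centers.append([row[f"nuc{i}_x"], row[f"nuc{i}_y"], row[f"nuc{i}_z"]])
                radii.append(row[f"nuc{i}_r"])
        out[row["cell_id"]] = (np.asarray(centers, float), np.asarray(radii, float))
    return out


def _nearest_ts_distances(mrna: pd.DataFrame, ts: pd.DataFrame) -> pd.Series:
    """3D distance of each nuclear mRNA spot to the nearest TS spot of its
    cell; NaN for cells without any TS spot."""
    dists = pd.Series(np.nan, index=mrna.index)
    ts_by_cell = {cid: g[["x", "y", "z"]].to_numpy() for cid, g in ts.groupby("cell_id")}
    for cid, grp in mrna.groupby("cell_id"):
        pts = ts_by_cell.get(cid)
        if pts is None or len(pts) == 0:
            continue
        xyz = grp[["x", "y", "z"]].to_numpy()
        d = np.sqrt(((xyz[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        dists.loc[grp.index] = d
    return dists


def _kde_valley(distances: np.ndarray) -> float | None:
    """Location of the KDE minimum between the two largest modes, or None
    when the density is effectively unimodal."""
    d = np.asarray(distances, float)
    if d.size < 2 or np.ptp(d) == 0:
        return None
    kde = gaussian_kde(d)
    grid = np.linspace(d.min(), d.max(), 512)
    y = kde(grid)
    # local maxima / minima of the density on the grid
    rising = np.diff(y) > 0
    maxima = np.where(~rising[1:] & rising[:-1])[0] + 1
    if grid.size and y[0] > y[1]:
        maxima = np.concatenate(([0], maxima))
    if y[-1] > y[-2]:
        maxima = np.concatenate((maxima, [y.size - 1]))
    if maxima.size < 2:
        return None
    top2 = maxima[np.argsort(y[maxima])][-2:]
    lo, hi = sorted(top2)
    valley = lo + int(np.argmin(y[lo : hi + 1]))
    return float(grid[valley])


def _two_cluster_split(distances: np.ndarray) -> float:
    """Midpoint between the two centers of a 1D two-cluster partition
    (exhaustive search over sorted split points, minimizing within-cluster
    sum of squares)."""
    d = np.sort(np.asarray(distances, float))
    if d.size < 2:
        return float(d[0]) if d.size else np.inf
    best = (np.inf, 1)
    for k in range(1, d.size):
        a, b = d[:k], d[k:]
        ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if ss < best[0]:
            best = (ss, k)
    k = best[1]
    return float((d[:k].mean() + d[k:].mean()) / 2.0)


def classify_nascent(
    spots: pd.DataFrame, min_distances: int = 10
) -> tuple[pd.Series, dict]:
    """Label nuclear mRNA spots nascent or mature.

    For each replicate, the distances from nuclear mRNA spots to their
    nearest same-cell TS spot form a bimodal distribution; the cutoff is the
    KDE valley between the two largest modes (fallback: two-cluster split
    when unimodal or when fewer than ``min_distances`` distances exist).
    Spots at distance <= cutoff are nascent.  Cells without TS spots get all
    nuclear spots labelled mature.

    Returns (labels indexed like ``spots`` with values in
    {"nascent", "mature", ""}, per-replicate cutoffs).
    """
    labels = pd.Series("", index=spots.index, dtype=object)
    cutoffs: dict = {}
    mrna_nuc = spots[(spots["channel"] == MRNA) & (spots["compartment"] == "nuclear")]
    ts = spots[spots["channel"] == TS]
    if ts.empty:
        labels.loc[mrna_nuc.index] = "mature"
        return labels, cutoffs
    for rep, grp in mrna_nuc.groupby("replicate_id"):
        d = _nearest_ts_distances(grp, ts[ts["replicate_id"] == rep])
        have = d.notna()
        labels.loc[grp.index[~have]] = "mature"
        dv = d[have].to_numpy()
        if dv.size == 0:
            continue
        if dv.size < min_distances:
            warnings.warn(
                f"replicate {rep!r}: only {dv.size} spot-TS distances; "
                "using two-cluster fallback cutoff"
            )
            cut = _two_cluster_split(dv)
        else:
            cut = _kde_valley(dv)
            if cut is None:
                cut = _two_cluster_split(dv)
        cutoffs[rep] = cut
        idx = grp.index[have]
        labels.loc[idx] = np.where(d[have] <= cut, "nascent", "mature")
    return labels, cutoffs


def filter_ts_cells(cells: pd.DataFrame, spots: pd.DataFrame) -> pd.DataFrame:
    """Flag cells unusable for TS-based compartment analysis.

    A cell is excluded when it has any cytoplasmic TS spot, or any nucleus
    with zero or more than two TS spots (each nuclear TS spot is assigned to
    its nearest nucleus).
    """
    cells = cells.copy()
    if "excluded" not in cells:
        cells["excluded"] = False
        cells["exclusion_reason"] = ""
    nuc_geo = _nucleus_arrays(cells)
    ts = spots[spots["channel"] == TS]
    for i, row in cells.iterrows():
        if row["excluded"]:
            continue
        cid = row["cell_id"]
        cell_ts = ts[ts["cell_id"] == cid]
        if (cell_ts["compartment"] == "cytoplasmic").any():
            cells.loc[i, ["excluded", "exclusion_reason"]] = True, "cytoplasmic TS"
            continue
        centers, radii = nuc_geo[cid]
        n_nuc = len(radii)
        per_nucleus = np.zeros(n_nuc, dtype=int)
        if not cell_ts.empty and n_nuc:
            xyz = cell_ts[["x", "y", "z"]].to_numpy()
            nearest = np.argmin(
                ((xyz[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
            )
            per_nucleus = np.bincount(nearest, minlength=n_nuc)
        if (per_nucleus == 0).any():
            cells.loc[i, ["excluded", "exclusion_reason"]] = True, "no TS"
        elif (per_nucleus > 2).any():
            cells.loc[i, ["excluded", "exclusion_reason"]] = True, "too many TS"
    return cells


def resolve_ts_compartment(
    cells: pd.DataFrame, spots: pd.DataFrame, mode: str = "expand"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Handle TS spots falling just outside their segmented nucleus.

    expand mode: the nearest nucleus sphere is isotropically grown by the
    minimal factor that puts the TS on its boundary, and mRNA spots inside
    the grown sphere are reassigned nuclear.  filter mode: such cells are
    excluded.  TS spots already inside a nucleus change nothing.
    """
    if mode not in ("expand", "filter"):
        raise ValueError(f"unknown TS mode {mode!r}")
    cells = cells.copy()
    spots = spots.copy()
    if "excluded" not in cells:
        cells["excluded"] = False
        cells["exclusion_reason"] = ""
    ts = spots[spots["channel"] == TS]
    for i, row in cells.iterrows():
        if row["excluded"]:
            continue
        cid = row["cell_id"]
        cell_ts = ts[(ts["cell_id"] == cid) & (ts["compartment"] != "cytoplasmic")]
        if cell_ts.empty:
            continue
        centers = []
        radii = []
        nuc_idx = []
        for k in (1, 2):
            if pd.notna(row.get(f"nuc{k}_x", np.nan)):
                centers.append([row[f"nuc{k}_x"], row[f"nuc{k}_y"], row[f"nuc{k}_z"]])
                radii.append(row[f"nuc{k}_r"])
                nuc_idx.append(k)
        if not centers:
            continue
        centers = np.asarray(centers, float)
        radii = np.asarray(radii, float)
        xyz = cell_ts[["x", "y", "z"]].to_numpy()
        d = np.sqrt(((xyz[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
        nearest = d.argmin(axis=1)
        outside = d[np.arange(len(xyz)), nearest] > radii[nearest]
        if not outside.any():
            continue
        if mode == "filter":
            cells.loc[i, ["excluded", "exclusion_reason"]] = True, "TS outside nucleus"
            continue
        for j in np.where(outside)[0]:
            k = nearest[j]
            new_r = d[j, k]
            cells.loc[i, f"nuc{nuc_idx[k]}_r"] = max(
                cells.loc[i, f"nuc{nuc_idx[k]}_r"], new_r
            )
            radii[k] = max(radii[k], new_r)
        # reassign mRNA spots now inside an expanded nucleus
        sel = (spots["cell_id"] == cid) & (spots["channel"] == MRNA)
        if sel.any():
            sxyz = spots.loc[sel, ["x", "y", "z"]].to_numpy()
            dm = np.sqrt(((sxyz[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
            inside = (dm <= radii[None, :]).any(axis=1)
            idx = spots.index[sel][inside]
            spots.loc[idx, "compartment"] = "nuclear"
    return cells, spots


def build_count_table(
    cells: pd.DataFrame,
    spots: pd.DataFrame,
    config: CountingConfig | None = None,
    ts_mode: str = "none",
    chromatic_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> pd.DataFrame:
    """One row of per-compartment counts per retained cell.

    Pipeline: intensity normalization -> optional chromatic shift of the TS
    channel -> TS cell filters and nucleus expansion/filtering (when
    ``ts_mode`` is ``expand`` or ``filter``) -> nascent classification ->
    counting with the configured method.  Returns columns
    cell_id, nascent, mature_nuclear, cytoplasmic, total, method.
    """
    config = config or CountingConfig()
    spots = normalize_intensities(spots)
    if any(chromatic_offset):
        ts_sel = spots["channel"] == TS
        for ax, off in zip("xyz", chromatic_offset):
            spots.loc[ts_sel, ax] = spots.loc[ts_sel, ax] + off
    use_ts = ts_mode != "none" and (spots["channel"] == TS).any()
    if use_ts:
        cells = filter_ts_cells(cells, spots)
        cells, spots = resolve_ts_compartment(cells, spots, mode=ts_mode)
    if "excluded" in cells:
        retained = cells[~cells["excluded"]]
    else:
        retained = cells
    if (spots["channel"] == TS).any():
        labels, _ = classify_nascent(spots)
    else:
        labels = pd.Series("", index=spots.index, dtype=object)
        labels[(spots["channel"] == MRNA) & (spots["compartment"] == "nuclear")] = "mature"
    thresholds = single_molecule_threshold(spots, config.single_molecule_percentile)
    rows = []
    mrna = spots[spots["channel"] == MRNA]
    for _, cell in retained.iterrows():
        cid = cell["cell_id"]
        thr = thresholds.get(cell["replicate_id"], np.inf)
        grp = mrna[mrna["cell_id"] == cid]
        lab = labels.loc[grp.index]
        nuc = grp["compartment"] == "nuclear"
        parts = {
            "nascent": grp.loc[nuc & (lab == "nascent"), "intensity"],
            "mature_nuclear": grp.loc[nuc & (lab != "nascent"), "intensity"],
            "cytoplasmic": grp.loc[~nuc, "intensity"],
        }
        row = {"cell_id": cid, "replicate_id": cell["replicate_id"]}
        for name, ints in parts.items():
            row[name] = count_spots(ints.to_numpy(), thr, config.method)
        row["total"] = row["nascent"] + row["mature_nuclear"] + row["cytoplasmic"]
        row["method"] = config.method
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["cell_id", "replicate_id", "nascent", "mature_nuclear",
                 "cytoplasmic", "total", "method"],
    )
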
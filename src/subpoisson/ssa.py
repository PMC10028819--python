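"""Exact stochastic simulation (direct-method Gillespie) of the expression model.

Samples are independent stationary draws: one trajectory per cell, started
empty and burned in for at least ten times the slowest timescale of the
network, so consecutive cells share no autocorrelation.  All randomness is
seeded explicitly; identical seeds give bitwise-identical samples.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import ModelSpec


@njit(cache=True)
def _ssa_population(txn_rates, k_c, k_d, n_deg, burn_in, n_cells, seed, out):
    np.random.seed(seed)
    n_txn = txn_rates.shape[0]
    c = np.zeros(n_deg, dtype=np.int64)
    for cell in range(n_cells):
        pos = 0
        m = 0
        for j in range(n_deg):
            c[j] = 0
        ctot = 0
        t = 0.0
        while True:
            a_txn = txn_rates[pos]
            a_exp = k_c * m
            a_deg = k_d * ctot
            a_tot = a_txn + a_exp + a_deg
            t += np.random.exponential(1.0 / a_tot)
            if t >= burn_in:
                break
            u = np.random.random() * a_tot
            if u < a_txn:
                pos += 1
                if pos == n_txn:
                    pos = 0
                    m += 1
            elif u < a_txn + a_exp:
                m -= 1
                c[0] += 1
                ctot += 1
            else:
                u -= a_txn + a_exp
                acc = 0.0
                for j in range(n_deg):
                    acc += k_d * c[j]
                    if u < acc or j == n_deg - 1:
                        c[j] -= 1
                        if j + 1 < n_deg:
                            c[j + 1] += 1
                        else:
                            ctot -= 1
                        break
        ctot2 = 0
        for j in range(n_deg):
            ctot2 += c[j]
        out[cell, 0] = m
        out[cell, 1] = ctot2


def default_burn_in(spec: ModelSpec) -> float:
    """Ten times the slowest mean timescale (cycle, nuclear, cytoplasmic)."""
    cycle = sum(1.0 / r for r in spec.txn_rates)
    return 10.0 * max(cycle, 1.0 / spec.export_rate, spec.n_deg_steps / spec.deg_step_rate)


def ssa_sample(
    spec: ModelSpec,
    n_cells: int,
    burn_in: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Stationary (nuclear, cytoplasmic) count pairs, shape ``(n_cells, 2)``.

    Sampling metadata: independent trajectories, one per cell, direct-method
    Gillespie, reflecting nothing (exact dynamics), burn-in as given or
    :func:`default_burn_in`.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    b = default_burn_in(spec) if burn_in is None else float(burn_in)
    out = np.empty((n_cells, 2), dtype=np.int64)
    _ssa_population(
        np.asarray(spec.txn_rates, dtype=np.float64),
        float(spec.export_rate),
        float(spec.deg_step_rate),
        spec.n_deg_steps,
        b,
        n_cells,
        int(seed) % 2**32,
        out,
    )
    return out


def sample_moments(sample: np.ndarray) -> dict:
    """Means, variances and Fano factors of an SSA sample with their
    Monte-Carlo standard errors (delta method for the Fano factor)."""
    res = {}
    n = sample.shape[0]
    for name, col in (("nuc", 0), ("cyt", 1)):
        x = sample[:, col].astype(float)
        m = x.mean()
        v = x.var(ddof=1)
        res[f"mean_{name}"] = m
        res[f"var_{name}"] = v
        res[f"se_mean_{name}"] = np.sqrt(v / n)
        res[f"fano_{name}"] = v / m if m > 0 else np.nan
        # delta-method SE of var/mean from the joint CLT of (mean, var)
        mu2 = ((x - m) ** 2).mean()
        mu3 = ((x - m) ** 3).mean()
        mu4 = ((x - m) ** 4).mean()
        g = np.array([-mu2 / m**2, 1.0 / m])
        cov = np.array([[mu2, mu3], [mu3, mu4 - mu2**2]]) / n
        res[f"se_fano_{name}"] = float(np.sqrt(g @ cov @ g)) if m > 0 else np.nan
    return res
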
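"""Constitutive multi-step gene-expression model.

A single gene copy cycles irreversibly through ``n_txn_steps`` exponential
promoter steps (rates ``k_A``, ``k_B``, ... in units of the effective
cytoplasmic degradation rate).  Completion of the last step emits one
nuclear mRNA and returns the promoter to the first step, so inter-synthesis
times are hypoexponential — narrower than exponential — which is what
permits sub-Poissonian steady states.  Nuclear mRNA is exported in a single
exponential step (rate ``k_C``) and then traverses ``n_deg_steps`` equal-rate
cytoplasmic degradation stages (per-step rate ``k_D``), giving an Erlang
residence time with mean ``n_deg_steps / k_D``.

All propensities are linear in the state, so first and second moments close
exactly: the stationary mean is one linear solve and the stationary
covariance one Lyapunov solve (:func:`solve_steady_state_moments`).  Full
joint distributions come from a finite state projection
(:func:`steady_state_distribution`) and exact Gillespie sampling lives in
:mod:`subpoisson.ssa`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg


class ResourceCapError(RuntimeError):
    """State space exceeded the configured cap; carries the attempted dims."""

    def __init__(self, message: str, dims: tuple[int, ...]):
        super().__init__(message)
        self.dims = dims


@dataclass(frozen=True)
class ModelSpec:
    """Rate parameters of the multi-step expression model.

    Rates are dimensionless, expressed in units of the effective cytoplasmic
    degradation rate (the reciprocal of the mean cytoplasmic residence time).
    Under the default normalization ``k_D = n_deg_steps`` so that the
    effective degradation rate is exactly 1; pass ``deg_step_rate`` to
    override (the effective rate is then ``deg_step_rate / n_deg_steps``).

    ``txn_rates`` may be given as a full per-step list, as a single shared
    rate, or — for more than two steps — as ``(k_A, k_B)`` with steps three
    and beyond defaulting to ``k_B``.
    """

    n_txn_steps: int
    txn_rates: tuple[float, ...]
    export_rate: float
    n_deg_steps: int = 1
    deg_step_rate: float | None = None

    def __post_init__(self):
        if self.n_txn_steps < 1 or self.n_deg_steps < 1:
            raise ValueError("step counts must be >= 1")
        rates = tuple(float(r) for r in np.atleast_1d(self.txn_rates))
        if len(rates) == 1 and self.n_txn_steps > 1:
            rates = rates * self.n_txn_steps
        elif len(rates) == 2 and self.n_txn_steps > 2:
            # paper-style (k_A, k_B): later steps reuse k_B
            rates = rates + (rates[1],) * (self.n_txn_steps - 2)
        if len(rates) != self.n_txn_steps:
            raise ValueError(
                f"txn_rates has {len(rates)} entries for {self.n_txn_steps} steps"
            )
        object.__setattr__(self, "txn_rates", rates)
        kd = float(self.n_deg_steps if self.deg_step_rate is None else self.deg_step_rate)
        object.__setattr__(self, "deg_step_rate", kd)
        if any(r <= 0 for r in rates) or self.export_rate <= 0 or kd <= 0:
            raise ValueError("all rates must be strictly positive")

    @property
    def effective_degradation_rate(self) -> float:
        return self.deg_step_rate / self.n_deg_steps

    @property
    def arrival_rate(self) -> float:
        """Stationary mRNA synthesis rate: reciprocal mean promoter-cycle time."""
        return 1.0 / sum(1.0 / r for r in self.txn_rates)

    def scaled(self, factor: float) -> "ModelSpec":
        """All rates multiplied by ``factor`` (time-unit change)."""
        return ModelSpec(
            self.n_txn_steps,
            tuple(r * factor for r in self.txn_rates),
            self.export_rate * factor,
            self.n_deg_steps,
            self.deg_step_rate * factor,
        )

    def to_dict(self) -> dict:
        return {
            "n_txn_steps": self.n_txn_steps,
            "txn_rates": list(self.txn_rates),
            "export_rate": self.export_rate,
            "n_deg_steps": self.n_deg_steps,
            "deg_step_rate": self.deg_step_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            n_txn_steps=int(d["n_txn_steps"]),
            txn_rates=tuple(d["txn_rates"]),
            export_rate=float(d["export_rate"]),
            n_deg_steps=int(d["n_deg_steps"]),
            deg_step_rate=d.get("deg_step_rate"),
        )


def make_spec(n_txn=1, txn_rates=(10.0,), k_C=10.0, n_deg=1, k_D=None) -> ModelSpec:
    """Convenience constructor using the field's symbol names."""
    return ModelSpec(n_txn, tuple(np.atleast_1d(txn_rates)), k_C, n_deg, k_D)


@dataclass(frozen=True)
class SteadyStateMoments:
    mean_nuc: float
    mean_cyt: float
    var_nuc: float
    var_cyt: float
    cov_nuc_cyt: float
    fano_nuc: float
    fano_cyt: float


def _affine_network(spec: ModelSpec):
    """Reaction list (w, b, s) with the last promoter indicator eliminated.

    Propensity of reaction k is ``w_k . x + b_k``; ``s_k`` is its
    stoichiometry on the reduced state
    ``(p_1..p_{Nt-1}, nuclear, c_1..c_{Nd})``.
    """
    nt, nd = spec.n_txn_steps, spec.n_deg_steps
    npvar = nt - 1
    i_m = npvar
    i_c = npvar + 1
    n = npvar + 1 + nd
    reactions = []
    r = spec.txn_rates
    for i in range(npvar):  # promoter steps 1..Nt-1
        w = np.zeros(n)
        w[i] = r[i]
        s = np.zeros(n)
        s[i] = -1
        if i + 1 < npvar:
            s[i + 1] = 1
        reactions.append((w, 0.0, s))
    # completion of the last step: emit one mRNA, promoter back to step 1
    w = np.zeros(n)
    b = r[-1]
    if npvar:
        w[:npvar] = -r[-1]  # P_Nt = 1 - sum(P_i)
    s = np.zeros(n)
    if npvar:
        s[0] = 1
    s[i_m] = 1
    reactions.append((w, b, s))
    # export
    w = np.zeros(n)
    w[i_m] = spec.export_rate
    s = np.zeros(n)
    s[i_m] = -1
    s[i_c] = 1
    reactions.append((w, 0.0, s))
    # degradation stages
    for j in range(nd):
        w = np.zeros(n)
        w[i_c + j] = spec.deg_step_rate
        s = np.zeros(n)
        s[i_c + j] = -1
        if j + 1 < nd:
            s[i_c + j + 1] = 1
        reactions.append((w, 0.0, s))
    return reactions, n, i_m, i_c


def solve_steady_state_moments(spec: ModelSpec) -> SteadyStateMoments:
    """Exact stationary means, variances and Fano factors.

    The reaction network has purely linear propensities, so the moment
    hierarchy closes: the mean solves ``J m + h = 0`` and the covariance the
    continuous Lyapunov equation ``J C + C J' + B(m) = 0``.
    """
    reactions, n, i_m, i_c = _affine_network(spec)
    J = np.zeros((n, n))
    h = np.zeros(n)
    for w, b, s in reactions:
        J += np.outer(s, w)
        h += s * b
    try:
        mean = np.linalg.solve(J, -h)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - positive rates
        raise RuntimeError("singular moment system") from exc
    B = np.zeros((n, n))
    for w, b, s in reactions:
        a = float(w @ mean + b)
        B += np.outer(s, s) * a
    C = scipy.linalg.solve_continuous_lyapunov(J, -B)
    nd = spec.n_deg_steps
    mean_nuc = float(mean[i_m])
    mean_cyt = float(mean[i_c : i_c + nd].sum())
    var_nuc = float(C[i_m, i_m])
    var_cyt = float(C[i_c : i_c + nd, i_c : i_c + nd].sum())
    cov = float(C[i_m, i_c : i_c + nd].sum())
    return SteadyStateMoments(
        mean_nuc=mean_nuc,
        mean_cyt=mean_cyt,
        var_nuc=var_nuc,
        var_cyt=var_cyt,
        cov_nuc_cyt=cov,
        fano_nuc=var_nuc / mean_nuc if mean_nuc > 0 else np.nan,
        fano_cyt=var_cyt / mean_cyt if mean_cyt > 0 else np.nan,
    )


@dataclass
class JointDistribution:
    """Stationary joint pmf over (nuclear count, total cytoplasmic count)."""

    pmf: np.ndarray  # shape (nuc_max+1, cyt_max+1)
    captured_mass: float
    bounds: dict = field(default_factory=dict)
    warning: str | None = None

    @property
    def nuclear_marginal(self) -> np.ndarray:
        return self.pmf.sum(axis=1)

    @property
    def cytoplasmic_marginal(self) -> np.ndarray:
        return self.pmf.sum(axis=0)

    def moments(self) -> tuple[float, float, float, float]:
        """(mean_nuc, var_nuc, mean_cyt, var_cyt) of the truncated pmf."""
        out = []
        for marg in (self.nuclear_marginal, self.cytoplasmic_marginal):
            k = np.arange(marg.size)
            p = marg / marg.sum()
            m = float(k @ p)
            out += [m, float(((k - m) ** 2) @ p)]
        return tuple(out)


def _fsp_stationary(spec: ModelSpec, m_max: int, c_max: np.ndarray):
    """Stationary distribution of the truncated chain (reflecting truncation).

    States: promoter position x nuclear count x per-stage cytoplasmic counts.
    Transitions that would leave the box are dropped.
    """
    nt, nd = spec.n_txn_steps, spec.n_deg_steps
    dims = (nt, m_max + 1) + tuple(int(c) + 1 for c in c_max)
    nstates = int(np.prod([float(d) for d in dims]))
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    flat = [g.ravel() for g in grids]
    pos, m = flat[0], flat[1]
    cstages = flat[2:]
    strides = np.ones(len(dims), dtype=np.int64)
    for i in range(len(dims) - 2, -1, -1):
        strides[i] = strides[i + 1] * dims[i + 1]
    idx = np.zeros(nstates, dtype=np.int64)
    for g, st in zip(flat, strides):
        idx += g.astype(np.int64) * st

    rows, cols, vals = [], [], []
    rates = np.asarray(spec.txn_rates)

    def add(src_mask, dest_shift, rate):
        src = idx[src_mask]
        dst = src + dest_shift[src_mask] if np.ndim(dest_shift) else src + dest_shift
        r = rate[src_mask] if np.ndim(rate) else np.full(src.size, rate)
        rows.append(dst)
        cols.append(src)
        vals.append(r)
        rows.append(src)
        cols.append(src)
        vals.append(-r)

    # promoter steps without emission
    mask = pos < nt - 1
    add(mask, strides[0], rates[pos % nt])
    # completion: pos Nt-1 -> 0, m+1 (blocked at the m boundary)
    mask = (pos == nt - 1) & (m < m_max)
    add(mask, -(nt - 1) * strides[0] + strides[1], rates[nt - 1])
    # export: m-1, c1+1
    mask = (m > 0) & (cstages[0] < c_max[0])
    add(mask, -strides[1] + strides[2], spec.export_rate * m)
    # stage hops and final decay
    for j in range(nd):
        if j + 1 < nd:
            mask = (cstages[j] > 0) & (cstages[j + 1] < c_max[j + 1])
            shift = -strides[2 + j] + strides[3 + j]
        else:
            mask = cstages[j] > 0
            shift = -strides[2 + j]
        add(mask, shift, spec.deg_step_rate * cstages[j])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals).astype(float)
    Q = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(nstates, nstates))
    # stationary distribution by uniformized power iteration: the CME
    # generator on a multi-species box fills in badly under sparse LU, while
    # P = I + Q/Lambda keeps each step at O(nnz)
    lam = -Q.diagonal().min() * 1.001
    P = scipy.sparse.identity(nstates, format="csr") + Q * (1.0 / lam)
    p = np.full(nstates, 1.0 / nstates)
    for it in range(500_000):
        p_next = P @ p
        p_next /= p_next.sum()
        if it % 50 == 0 and np.abs(p_next - p).sum() < 1e-14:
            p = p_next
            break
        p = p_next
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    # mass on the outer shell measures the truncation quality
    shell = (m == m_max)
    for j in range(nd):
        shell |= cstages[j] == c_max[j]
    boundary_mass = float(p[shell].sum())
    return p.reshape(dims), boundary_mass


def steady_state_distribution(
    spec: ModelSpec,
    truncation: tuple[int, Sequence[int]] | None = None,
    mass_tol: float = 1e-8,
    max_states: int = 5_000_000,
) -> JointDistribution:
    """Joint stationary pmf of (nuclear, cytoplasmic) counts by finite state
    projection over promoter state x nuclear count x degradation stages.

    Truncation starts at mean + 8 sd per species (or the supplied bounds,
    auto-expanded to at least that) and doubles until the stationary mass on
    the truncation boundary is below ``mass_tol``.
    """
    mom = solve_steady_state_moments(spec)
    lam = spec.arrival_rate
    m0 = int(np.ceil(mom.mean_nuc + 8 * np.sqrt(max(mom.var_nuc, mom.mean_nuc)))) + 1
    stage_mean = lam / spec.deg_step_rate
    c0 = int(np.ceil(stage_mean + 8 * np.sqrt(max(stage_mean, 0.25)))) + 1
    m_max = m0
    c_max = np.full(spec.n_deg_steps, c0, dtype=int)
    if truncation is not None:
        tm, tc = truncation
        m_max = max(int(tm), m0)
        c_max = np.maximum(np.asarray(tc, dtype=int), c0)
    warning = None
    while True:
        dims = (spec.n_txn_steps, m_max + 1, *(c_max + 1))
        nstates = int(np.prod([float(d) for d in dims]))
        if nstates > max_states:
            raise ResourceCapError(
                f"finite state projection needs {nstates} states "
                f"(> cap {max_states}) at dims {dims}",
                dims,
            )
        p, boundary = _fsp_stationary(spec, m_max, c_max)
        if boundary <= mass_tol:
            break
        if nstates * 2 ** (1 + spec.n_deg_steps) > max_states:
            warning = (
                f"truncation boundary mass {boundary:.2e} above tolerance; "
                "state cap prevents further expansion"
            )
            warnings.warn(warning)
            break
        m_max *= 2
        c_max = c_max * 2
    # marginalize promoter, convert stage counts to their total
    nd = spec.n_deg_steps
    p_mc = p.sum(axis=0)  # (m, c_1..c_nd)
    cyt_tot_max = int(c_max.sum())
    joint = np.zeros((m_max + 1, cyt_tot_max + 1))
    stage_grids = np.meshgrid(*[np.arange(c + 1) for c in c_max], indexing="ij")
    ctot = np.zeros(stage_grids[0].shape, dtype=int)
    for g in stage_grids:
        ctot = ctot + g
    ctot_flat = ctot.ravel()
    for mi in range(m_max + 1):
        joint[mi] = np.bincount(
            ctot_flat, weights=p_mc[mi].ravel(), minlength=cyt_tot_max + 1
        )
    return JointDistribution(
        pmf=joint,
        captured_mass=1.0 - boundary,
        bounds={"nuclear": m_max, "stages": c_max.tolist()},
        warning=warning,
    )


def min_cytoplasmic_fano(
    n_txn: int,
    n_deg: int,
    rate_grid: np.ndarray | None = None,
    k_C_max: float = 1000.0,
) -> tuple[float, dict]:
    """Minimum stationary cytoplasmic Fano factor over a log-spaced rate grid.

    The search uses equal per-step transcription rates: among hypoexponential
    cycle-time distributions with fixed mean, the equal-rate profile has the
    smallest squared coefficient of variation, so it attains the noise floor.
    ``k_D`` stays at the default normalization (effective degradation rate 1).

    Returns ``(min_fano_cyt, argmin)`` where ``argmin`` records the
    transcription rate and export rate at the minimum.
    """
    if rate_grid is None:
        rate_grid = np.logspace(-1, 3, 17)
    rate_grid = np.asarray(rate_grid, dtype=float)
    kc_grid = rate_grid[rate_grid <= k_C_max]
    best = (np.inf, None)
    for k in rate_grid:
        for kc in kc_grid:
            spec = ModelSpec(n_txn, (k,) * n_txn, kc, n_deg)
            f = solve_steady_state_moments(spec).fano_cyt
            if f < best[0]:
                best = (f, {"txn_rate": float(k), "k_C": float(kc)})
    return best


def fano_export_curve(
    spec_template: ModelSpec, k_C_values: Sequence[float]
) -> np.ndarray:
    """Fano factors vs nuclear export rate.

    Returns an array of shape (len(k_C_values), 2) with columns
    (fano_nuc, fano_cyt), the template's other rates held fixed.
    """
    out = np.empty((len(k_C_values), 2))
    for i, kc in enumerate(k_C_values):
        spec = ModelSpec(
            spec_template.n_txn_steps,
            spec_template.txn_rates,
            float(kc),
            spec_template.n_deg_steps,
            spec_template.deg_step_rate,
        )
        mom = solve_steady_state_moments(spec)
        out[i] = (mom.fano_nuc, mom.fano_cyt)
    return out


def crossover_export_rate(
    spec_template: ModelSpec, bracket: tuple[float, float] = (1e-2, 1e3)
) -> float | None:
    """Export rate at which nuclear and cytoplasmic Fano factors are equal.

    Below the crossover the cytoplasmic Fano exceeds the nuclear one; above
    it the order flips.  Returns ``None`` when no sign change exists in the
    bracket (the one-step model never crosses: both Fano factors are 1).
    """

    def gap(kc: float) -> float:
        mom = solve_steady_state_moments(
            ModelSpec(
                spec_template.n_txn_steps,
                spec_template.txn_rates,
                kc,
                spec_template.n_deg_steps,
                spec_template.deg_step_rate,
            )
        )
        return mom.fano_cyt - mom.fano_nuc

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    tiny = 1e-12
    if abs(g_lo) < tiny and abs(g_hi) < tiny:
        return None  # curves coincide (one-step model): no crossover
    if abs(g_lo) < tiny:
        return float(lo)
    if abs(g_hi) < tiny:
        return float(hi)
    if np.sign(g_lo) == np.sign(g_hi):
        return None
    return float(scipy.optimize.brentq(gap, lo, hi, rtol=1e-6))
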
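"""First-level GLM machinery and group-level maps.

The main model has three groups of task regressors, all convolved with a
double-gamma HRF: four condition dummies (R, A, C, I boxcars over the 6.5 s
gamble period), four parametric uncertainty-level regressors (the same boxcars
scaled by the trial's level, mean-centered within each run), and one response
time regressor (an onset impulse with amplitude equal to the trial RT,
mean-centered within each run), plus one intercept per run.  Voxel time series
are converted to percent signal change per run before fitting.  Group maps are
voxelwise random-effects tests over per-subject parameter estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .choice import subjective_value
from .design import CONDITIONS, Session

TASK_REGRESSORS = ("R", "A", "C", "I", "R_level", "A_level", "C_level", "I_level", "RT")
_COND_KEY = {"risk": "R", "ambiguity": "A", "conflict": "C", "ignorance": "I"}


class GLMError(ValueError):
    pass


def double_gamma_hrf(
    t_grid,
    peak_shape: float = 6.0,
    peak_scale: float = 1.0,
    undershoot_shape: float = 16.0,
    undershoot_scale: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF on ``t_grid`` (s), peak normalized to 1.

    Defaults place the response peak at (shape-1)*scale = 5 s and the
    undershoot trough near 15 s.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise GLMError("t_grid must be nonnegative and increasing")
    for v in (peak_shape, peak_scale, undershoot_shape, undershoot_scale):
        if not np.isfinite(v) or v <= 0:
            raise GLMError("HRF shape/scale parameters must be positive")
    h = stats.gamma.pdf(t, peak_shape, scale=peak_scale) - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_shape, scale=undershoot_scale
    )
    peak = h.max()
    if peak <= 0:
        raise GLMError("degenerate HRF: nonpositive peak")
    return h / peak


@dataclass
class DesignMatrix:
    """Volumes x regressors, with names, TR and run boundaries."""

    frame: pd.DataFrame
    tr: float
    run_slices: list[slice]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def rank_deficient(self) -> bool:
        x = self.values
        return np.linalg.matrix_rank(x) < x.shape[1]


def _convolve_events(onsets, durations, amplitudes, n_vols, tr, hrf_kwargs, dt=0.1):
    """Discrete convolution of an amplitude-modulated boxcar with the HRF,
    sampled at volume acquisition times."""
    t_max = n_vols * tr
    n_fine = int(round(t_max / dt)) + 1
    x = np.zeros(n_fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        x[i0:min(i1, n_fine)] += amp
    h = double_gamma_hrf(np.arange(0, 32.0 + dt, dt), **(hrf_kwargs or {}))
    conv = np.convolve(x, h)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    return conv[vol_idx]


def build_design_matrix(
    session: Session,
    choices=None,
    hrf_kwargs: dict | None = None,
    dt: float = 0.1,
) -> DesignMatrix:
    """The main model's design matrix for one subject's whole session.

    ``choices`` (ChoiceRecords aligned with the session's gamble trials, in
    session order) supply the response times; without them the RT regressor is
    omitted.  Parametric level and RT amplitudes are mean-centered within each
    run before convolution.
    """
    n_vols, tr = session.volumes_per_run, session.tr
    rts = None
    if choices is not None:
        rts = [c.rt_s for c in choices]
        if len(rts) != len(session.gamble_trials()):
            raise GLMError("choices must align one-to-one with gamble trials")
    cols: dict[str, np.ndarray] = {}
    run_slices = [slice(r * n_vols, (r + 1) * n_vols) for r in range(session.n_runs)]
    total = session.n_runs * n_vols
    for name in TASK_REGRESSORS:
        if name == "RT" and rts is None:
            continue
        cols[name] = np.zeros(total)

    gamble_trials = session.gamble_trials()
    for run in range(session.n_runs):
        sl = run_slices[run]
        run_trials = [t for t in session.run_trials(run) if t.trial_type != "fixation"]
        for cond in CONDITIONS:
            key = _COND_KEY[cond]
            ct = [t for t in run_trials if t.trial_type == cond]
            if not ct:
                continue
            onsets = [t.onset for t in ct]
            durs = [t.duration for t in ct]
            cols[key][sl] = _convolve_events(
                onsets, durs, np.ones(len(ct)), n_vols, tr, hrf_kwargs, dt
            )
            levels = np.array([t.gamble.level for t in ct], dtype=float)
            cols[key + "_level"][sl] = _convolve_events(
                onsets, durs, levels - levels.mean(), n_vols, tr, hrf_kwargs, dt
            )
        if rts is not None:
            idx = [gamble_trials.index(t) for t in run_trials]
            rt_vals = np.array([rts[i] if rts[i] is not None else np.nan for i in idx])
            ok = np.isfinite(rt_vals)
            if ok.any():
                amps = rt_vals[ok] - rt_vals[ok].mean()
                onsets = [run_trials[i].onset for i in np.flatnonzero(ok)]
                cols["RT"][sl] = _convolve_events(
                    onsets, [dt] * len(onsets), amps / dt, n_vols, tr, hrf_kwargs, dt
                )
    # numerical orthogonalization to the run intercepts: truncation at the run
    # boundary leaves a small residual mean in the convolved parametric
    # columns; demeaning per run removes it without touching the task PEs
    for name in cols:
        if name.endswith("_level") or name == "RT":
            for sl in run_slices:
                cols[name][sl] -= cols[name][sl].mean()
    for run in range(session.n_runs):
        ic = np.zeros(total)
        ic[run_slices[run]] = 1.0
        cols[f"const_run{run + 1}"] = ic
    return DesignMatrix(pd.DataFrame(cols), tr, run_slices)


def build_sv_design_matrix(
    session: Session,
    choices,
    params,
    hrf_kwargs: dict | None = None,
    dt: float = 0.1,
) -> DesignMatrix:
    """The subjective-value confound model: 4 condition dummies + 4 regressors
    modulated by the weight W of the chosen option (mean-centered per run)."""
    n_vols, tr = session.volumes_per_run, session.tr
    gamble_trials = session.gamble_trials()
    if len(choices) != len(gamble_trials):
        raise GLMError("choices must align one-to-one with gamble trials")
    sv = [
        subjective_value(c.gamble, c.choice, params) if c.choice is not None else np.nan
        for c in choices
    ]
    cols: dict[str, np.ndarray] = {}
    total = session.n_runs * n_vols
    run_slices = [slice(r * n_vols, (r + 1) * n_vols) for r in range(session.n_runs)]
    for cond in CONDITIONS:
        key = _COND_KEY[cond]
        cols[key] = np.zeros(total)
        cols[key + "_sv"] = np.zeros(total)
    for run in range(session.n_runs):
        sl = run_slices[run]
        run_trials = [t for t in session.run_trials(run) if t.trial_type != "fixation"]
        for cond in CONDITIONS:
            key = _COND_KEY[cond]
            ct = [t for t in run_trials if t.trial_type == cond]
            if not ct:
                continue
            onsets = [t.onset for t in ct]
            durs = [t.duration for t in ct]
            vals = np.array([sv[gamble_trials.index(t)] for t in ct], dtype=float)
            ok = np.isfinite(vals)
            cols[key][sl] = _convolve_events(
                onsets, durs, np.ones(len(ct)), n_vols, tr, hrf_kwargs, dt
            )
            if ok.any():
                centered = np.where(ok, vals - vals[ok].mean(), 0.0)
                cols[key + "_sv"][sl] = _convolve_events(
                    onsets, durs, centered, n_vols, tr, hrf_kwargs, dt
                )
    for name in cols:
        if name.endswith("_sv"):
            for sl in run_slices:
                cols[name][sl] -= cols[name][sl].mean()
    for run in range(session.n_runs):
        ic = np.zeros(total)
        ic[run_slices[run]] = 1.0
        cols[f"const_run{run + 1}"] = ic
    return DesignMatrix(pd.DataFrame(cols), tr, run_slices)


def highpass_filter(ts: np.ndarray, cycles_per_run: float = 3.0) -> np.ndarray:
    """Remove slow drift below ``cycles_per_run`` from one run's time series.

    Projects out the discrete-cosine components whose frequency is below the
    cutoff (a DCT basis function with index k completes k/2 cycles over the
    run), plus the constant.  The synthetic generator injects no drift, so
    this is off by default throughout; it exists for data that need it.
    """
    y = np.asarray(ts, dtype=float)
    T = y.shape[-1]
    k_max = int(np.ceil(2 * cycles_per_run)) - 1
    if k_max < 1:
        return y - y.mean(axis=-1, keepdims=True)
    t = np.arange(T)
    basis = [np.ones(T) / math.sqrt(T)]
    for k in range(1, k_max + 1):
        b = np.cos(np.pi * k * (t + 0.5) / T)
        basis.append(b / np.linalg.norm(b))
    q = np.stack(basis, axis=1)                 # T x (k_max+1), orthonormal
    return y - (y @ q) @ q.T


def to_percent_signal_change(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """100 * (y - run mean) / run mean along the time axis of one run."""
    ts = np.asarray(ts, dtype=float)
    m = ts.mean(axis=axis, keepdims=True)
    if np.any(m <= 0):
        raise GLMError("run mean must be positive for PSC conversion")
    return 100.0 * (ts - m) / m


@dataclass
class GLMResult:
    pe: pd.DataFrame | pd.Series      # regressors x voxels (DataFrame) or Series
    resid_var: np.ndarray
    ar1: float
    names: list[str]

    def pe_for(self, name: str) -> np.ndarray:
        return np.asarray(self.pe.loc[name])


def fit_glm(ts: np.ndarray, design: DesignMatrix, ar1: bool = False) -> GLMResult:
    """OLS fit of the design to PSC time series (last axis = time).

    With ``ar1`` a single Cochrane-Orcutt prewhitening pass is applied: the
    lag-1 autocorrelation of the pooled OLS residuals is estimated, both sides
    are quasi-differenced within runs, and the model is refit.
    """
    y = np.asarray(ts, dtype=float)
    squeeze = y.ndim == 1
    y2 = np.atleast_2d(y)                       # voxels x time
    x = design.values
    if x.shape[0] != y2.shape[1]:
        raise GLMError(f"time axis mismatch: design {x.shape[0]}, data {y2.shape[1]}")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise GLMError("rank-deficient design matrix")

    beta, rho = _ols(y2, x)
    if ar1:
        yw = np.empty_like(y2)
        xw = np.empty_like(x)
        for sl in design.run_slices:
            ys, xs = y2[:, sl], x[sl]
            yw[:, sl] = ys - rho * np.roll(ys, 1, axis=1)
            xw[sl] = xs - rho * np.roll(xs, 1, axis=0)
            yw[:, sl.start] = ys[:, 0]
            xw[sl.start] = xs[0]
        beta, _ = _ols(yw, xw)
        resid = yw - beta @ xw.T
    else:
        resid = y2 - beta @ x.T
    dof = max(1, y2.shape[1] - x.shape[1])
    rvar = (resid**2).sum(axis=1) / dof
    pe = pd.DataFrame(beta.T, index=design.names)
    if squeeze:
        pe = pe[0]
        rvar = rvar[0]
    return GLMResult(pe, rvar, float(rho), design.names)


def _ols(y2: np.ndarray, x: np.ndarray):
    beta, *_ = np.linalg.lstsq(x, y2.T, rcond=None)
    resid = y2 - beta.T @ x.T
    num = (resid[:, 1:] * resid[:, :-1]).sum()
    den = (resid**2).sum()
    rho = num / den if den > 0 else 0.0
    return beta.T, float(rho)


# ---------------------------------------------------------------------------
# group-level maps (subjects x voxels arrays; any trailing spatial shape)

def group_ttest_map(pes: np.ndarray):
    """Voxelwise one-sample t of per-subject PEs against 0 (random effects).

    Returns (t_map, p_map); zero-variance voxels come back NaN.
    """
    pes = np.asarray(pes, dtype=float)
    if pes.shape[0] < 3:
        raise GLMError("need at least 3 subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_1samp(pes, 0.0, axis=0)
    return t, p


def brain_behavior_map(pes: np.ndarray, attitudes):
    """Voxelwise Pearson correlation of per-subject PEs with a behavioral score.

    Returns (r_map, p_map); constant-PE voxels come back NaN.
    """
    a = np.asarray(attitudes, dtype=float)
    pes = np.asarray(pes, dtype=float)
    if pes.shape[0] != a.size or a.size < 4:
        raise GLMError("need >= 4 subjects and matching attitude vector")
    if a.std() == 0:
        raise GLMError("zero-variance attitude vector")
    n = a.size
    az = (a - a.mean()) / a.std()
    pz = pes - pes.mean(axis=0)
    sd = pes.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.einsum("i,i...->...", az, pz) / (n * np.where(sd > 0, sd, np.nan))
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return r, p


def contrast_map(pes_a: np.ndarray, pes_c: np.ndarray):
    """Voxelwise paired t of (pes_c - pes_a) across subjects (e.g. C-level >
    A-level).  Returns (t_map, p_map)."""
    pes_a = np.asarray(pes_a, dtype=float)
    pes_c = np.asarray(pes_c, dtype=float)
    if pes_a.shape != pes_c.shape:
        raise GLMError("contrast inputs must share subjects and shape")
    return group_ttest_map(pes_c - pes_a)


def conjunction_map(tmap_a, pmap_a, tmap_c, pmap_c, alpha: float = 0.05) -> np.ndarray:
    """Minimum-statistic conjunction: both effects pass alpha with equal sign."""
    both = (np.asarray(pmap_a) < alpha) & (np.asarray(pmap_c) < alpha)
    same_sign = np.sign(tmap_a) == np.sign(tmap_c)
    return both & same_sign & (np.sign(tmap_a) != 0)


def cluster_threshold(
    shape,
    voxel_p: float = 0.005,
    n_sims: int = 500,
    smooth_sigma: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> int:
    """Monte-Carlo minimum cluster extent controlling family-wise error.

    Simulates smoothed Gaussian-noise maps on ``shape``, thresholds voxelwise
    at two-sided ``voxel_p``, records the largest suprathreshold cluster, and
    returns the smallest extent k whose exceedance rate is <= ``alpha``.
    """
    if n_sims < 100:
        raise GLMError("need at least 100 simulations")
    if not np.isfinite(smooth_sigma) or smooth_sigma < 0:
        raise GLMError("degenerate smoothness")
    rng = np.random.default_rng(seed)
    zcrit = stats.norm.isf(voxel_p / 2)
    maxima = np.empty(n_sims, dtype=int)
    for i in range(n_sims):
        z = rng.standard_normal(shape)
        if smooth_sigma > 0:
            z = ndimage.gaussian_filter(z, smooth_sigma)
            z /= z.std()
        lab, nlab = ndimage.label(np.abs(z) > zcrit)
        maxima[i] = 0 if nlab == 0 else np.bincount(lab.ravel())[1:].max()
    ks = np.sort(maxima)
    # smallest k with P(max cluster >= k) <= alpha
    k = int(ks[min(len(ks) - 1, int(np.ceil((1 - alpha) * n_sims)))]) + 1
    return k
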
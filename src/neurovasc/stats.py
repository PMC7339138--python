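"""Dual regression, the normalized-R² statistic, and group inference.

Stage-1 dual regression projects the group ICA spatial maps onto each
individual dataset: for every volume, the in-mask voxel values are
regressed (multiple least squares, all maps simultaneously plus an
intercept) onto the maps, and the per-volume coefficients form each
component's scan-specific timecourse.

The normalized R² of a component timecourse for one stimulus is the
variance explained by that stimulus alone (simple regression R²) divided by
the variance explained by the full stimulus model (multiple regression R²)
— the percentage of explained variance attributed to that stimulus.

Group inference compares the neural and vascular member of each pair with
paired two-tailed t-tests over scans, Bonferroni-corrected; normality of
the paired differences is assessed with a seeded Monte-Carlo Lilliefors
test (non-normal differences are flagged but still tested).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decompose import ICADecomposition
from .paradigm import Regressor, ValidationError
from .preprocess import BOLDDataset

__all__ = [
    "dual_regression_timeseries",
    "normalized_r2",
    "normalized_r2_table",
    "lilliefors",
    "paired_component_tests",
    "block_average",
    "cross_correlation_lag",
    "replication_analysis",
]

MEMBERS = ("neural", "vascular")


# -- dual regression ---------------------------------------------------------

def dual_regression_timeseries(
    ds: BOLDDataset, maps: np.ndarray
) -> np.ndarray:
    """Per-component timecourses of ``ds`` given group spatial ``maps``.

    ``maps`` is (n_comp, n_maskvoxels) on ``ds``'s mask.  Returns an
    (n_vols, n_comp) array of least-squares coefficients (intercept
    handled internally and dropped).
    """
    if ds.units != "percent_bold":
        raise ValidationError("dual regression expects percent_bold data")
    Y = ds.in_mask()                       # (V, T)
    if maps.shape[1] != Y.shape[0]:
        raise ValidationError(
            f"maps have {maps.shape[1]} voxels but dataset mask has {Y.shape[0]}"
        )
    G = np.column_stack([np.ones(Y.shape[0]), maps.T])   # (V, n_comp+1)
    coef, _, rank, _ = np.linalg.lstsq(G, Y, rcond=None)
    if rank < G.shape[1]:
        cc = np.corrcoef(maps)
        np.fill_diagonal(cc, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(cc)), cc.shape)
        raise ValidationError(
            f"rank-deficient map matrix (rank {rank} < {G.shape[1]}); most "
            f"collinear components: {i} and {j} (r={cc[i, j]:.4f})"
        )
    return coef[1:].T                      # (T, n_comp)


# -- normalized R² -----------------------------------------------------------

def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R² of y on columns of X plus an intercept."""
    G = np.column_stack([np.ones(y.size), X])
    coef, _, _, _ = np.linalg.lstsq(G, y, rcond=None)
    resid = y - G @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss <= 0:
        return 0.0
    return float(1.0 - (resid**2).sum() / tss)


def normalized_r2(ts: np.ndarray, single_reg, full_regs) -> float:
    """Single-stimulus R² over full-model R², clipped to [0, 1].

    ``single_reg`` must be one of ``full_regs``; each may be a Regressor or
    a plain array.  Returns 0 (flagged by convention) for a zero-variance
    timecourse or a vanishing full-model R².
    """
    def vals(r):
        return r.values if isinstance(r, Regressor) else np.asarray(r, float)

    y = np.asarray(ts, dtype=float)
    if y.std() == 0:
        return 0.0
    s = vals(single_reg)
    F = np.column_stack([vals(r) for r in full_regs])
    if not any(np.array_equal(s, F[:, j]) for j in range(F.shape[1])):
        raise ValidationError("single_reg must be one of full_regs")
    if s.size != y.size:
        raise ValidationError("regressor length does not match timeseries")
    r2_full = _r2(y, F)
    if r2_full < 1e-12:
        return 0.0
    r2_single = _r2(y, s[:, None])
    return float(np.clip(r2_single / r2_full, 0.0, 1.0))


def normalized_r2_table(
    scan_ts: dict,
    pair_index: dict,
    regressors_by_scan: dict,
) -> pd.DataFrame:
    """Tidy table of normalized R² per (scan, label, member, stimulus).

    ``scan_ts``: scan_id -> (n_vols, n_comp) dual-regression timeseries;
    ``pair_index``: label -> {"neural": idx, "vascular": idx};
    ``regressors_by_scan``: scan_id -> {stimulus_name: Regressor}.
    """
    rows = []
    for scan_id, ts in scan_ts.items():
        regs = regressors_by_scan[scan_id]
        full = list(regs.values())
        for label, members in pair_index.items():
            for member in MEMBERS:
                comp = members[member]
                for stim, reg in regs.items():
                    rows.append({
                        "scan_id": scan_id,
                        "label": label,
                        "member": member,
                        "stimulus": stim,
                        "normalized_r2": normalized_r2(ts[:, comp], reg, full),
                    })
    return pd.DataFrame(rows)


# -- Lilliefors (Monte-Carlo) and paired tests -------------------------------

def _ks_normal_stat(x: np.ndarray) -> float:
    """KS statistic of x against N(mean(x), sd(x))."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    lo = cdf - np.arange(0, n) / n
    return float(max(up.max(), lo.max()))


@lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((n_mc, n))
    m = samples.mean(axis=1, keepdims=True)
    s = samples.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((samples - m) / s, axis=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1) / n
    j = np.arange(0, n) / n
    stat = np.maximum((i - cdf).max(axis=1), (cdf - j).max(axis=1))
    return np.sort(stat)


def lilliefors(x: np.ndarray, n_mc: int = 10_000, seed: int = 0) -> tuple:
    """Lilliefors normality test by seeded Monte Carlo.

    KS statistic against a normal with sample-estimated mean/sd; the null
    distribution is simulated (``n_mc`` Gaussian replicates at the same n).
    Returns ``(statistic, p_value)``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValidationError("Lilliefors needs at least 4 observations")
    stat = _ks_normal_stat(x)
    null = _lilliefors_null(x.size, n_mc, seed)
    p = (1 + np.sum(null >= stat)) / (n_mc + 1)
    return stat, float(p)


@dataclass(frozen=True)
class StatsReport:
    """Per (label, stimulus) paired-test results."""

    table: pd.DataFrame
    alpha: float = 0.05
    m: int = 9


def paired_component_tests(
    table: pd.DataFrame,
    alpha: float = 0.05,
    m: int | None = None,
    lilliefors_mc: int = 10_000,
    seed: int = 0,
) -> StatsReport:
    """Paired t-tests of neural-vs-vascular normalized R² per (label, stimulus).

    Differences are neural minus vascular across scans.  Bonferroni
    correction over all tests performed (``m`` defaults to their count);
    non-normal differences (Lilliefors p < 0.05) are flagged, not dropped.
    Missing table cells raise with the offending keys.
    """
    combos = sorted(
        {(l, s) for l, s in zip(table["label"], table["stimulus"])}
    )
    if m is None:
        m = len(combos)
    rows = []
    for label, stim in combos:
        sub = table[(table["label"] == label) & (table["stimulus"] == stim)]
        piv = sub.pivot_table(index="scan_id", columns="member",
                              values="normalized_r2")
        missing = [c for c in MEMBERS if c not in piv.columns]
        if missing or piv.isna().any().any():
            raise ValidationError(
                f"incomplete table for ({label}, {stim}): missing "
                f"{missing or piv.index[piv.isna().any(axis=1)].tolist()}"
            )
        diff = (piv["neural"] - piv["vascular"]).to_numpy()
        n = diff.size
        if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0.0):
            t_stat, p_raw = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t_stat, p_raw = sps.ttest_1samp(diff, 0.0)
        _, lp = lilliefors(diff, n_mc=lilliefors_mc, seed=seed)
        rows.append({
            "label": label,
            "stimulus": stim,
            "n": n,
            "mean_diff": float(diff.mean()),
            "t": float(t_stat),
            "df": n - 1,
            "p_raw": float(p_raw),
            "p_bonferroni": float(min(1.0, m * p_raw)),
            "lilliefors_p": lp,
            "normal": lp >= 0.05,
            "significant": bool(min(1.0, m * p_raw) < alpha),
        })
    return StatsReport(table=pd.DataFrame(rows), alpha=alpha, m=m)


# -- epoch averaging and lags ------------------------------------------------

def block_average(
    ts: np.ndarray,
    onsets_s,
    window_s: float,
    tr_s: float,
    pre_s: float = 6.0,
):
    """Mean stimulus-locked epoch of ``ts`` across block onsets.

    Each epoch spans ``[onset - pre_s, onset + window_s)`` and is shifted by
    its pre-onset baseline (mean over ``[onset - pre_s, onset)``).  Epochs
    extending outside the scan are dropped with a warning.  Returns
    ``(rel_t_s, mean_curve, epochs)``.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.size
    pre = int(round(pre_s / tr_s))
    win = int(round(window_s / tr_s))
    epochs = []
    for onset in onsets_s:
        i0 = int(round(onset / tr_s)) - pre
        i1 = i0 + pre + win
        if i0 < 0 or i1 > n:
            warnings.warn(f"epoch at onset {onset}s out of range; dropped")
            continue
        seg = ts[i0:i1].copy()
        if pre > 0:
            seg -= seg[:pre].mean()
        epochs.append(seg)
    if not epochs:
        raise ValidationError("no epochs fall inside the scan")
    epochs = np.asarray(epochs)
    rel_t = (np.arange(pre + win) - pre) * tr_s
    return rel_t, epochs.mean(axis=0), epochs


def cross_correlation_lag(
    a: np.ndarray, b: np.ndarray, max_lag_s: float, tr_s: float
) -> tuple:
    """Lag (s) maximizing |Pearson r| over integer-TR shifts.

    Positive lag means ``a`` lags ``b`` (a(t) ≈ b(t - lag)).  Ties break to
    the smallest |lag|.  Returns ``(lag_s, r_at_lag)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ValidationError("timeseries lengths differ")
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("zero-variance timeseries")
    n = a.size
    max_shift = int(round(max_lag_s / tr_s))
    if max_lag_s >= n * tr_s / 4:
        raise ValidationError("max_lag_s must be < duration/4")
    best = None
    for shift in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        if shift >= 0:
            x, y = a[shift:], b[: n - shift]
        else:
            x, y = a[: n + shift], b[-shift:]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if best is None or abs(r) > abs(best[1]) + 1e-15:
            best = (shift, r)
    return best[0] * tr_s, best[1]


# -- replication-mode analysis ----------------------------------------------

def replication_analysis(
    study,
    original_decomp: ICADecomposition,
    original_pairs,
    wm_reg: Regressor,
    vis_reg: Regressor,
    level_alpha: float = 0.05,
    seed: int = 0,
    preprocessed: dict | None = None,
):
    """Apply the ORIGINAL network maps to a replication study.

    For every replication scan: stage-1 dual regression with the original
    ICA maps, normalized R² against working-memory, visual, and the scan's
    own natural PetCO2 regressor, then paired tests as in the original
    analysis.  The coupling report gives the Pearson correlation between
    the group-mean baseline-normalized PetCO2 grid trace and the
    working-memory stimulus timecourse, full-length and block-averaged.

    Returns ``(table, report, coupling)``.
    """
    from .physio import baseline_normalize, vascular_regressor
    from .preprocess import detrend_and_percent

    if study.mode != "replication":
        raise ValidationError("replication_analysis expects a replication study")
    hrf = study.hrf
    tr = study.config.tr_s
    n_vols = study.config.n_vols
    pair_index = {
        p.label: {"neural": p.neural_idx, "vascular": p.vascular_idx}
        for p in original_pairs
    }
    scan_ts, regs_by_scan = {}, {}
    petco2_grids = []
    for scan in study.scans:
        sid = (scan.subject_id, scan.scan_id)
        ds = (preprocessed[sid] if preprocessed is not None
              else detrend_and_percent(scan.bold))
        scan_ts[sid] = dual_regression_timeseries(ds, original_decomp.maps)
        trace = baseline_normalize(scan.petco2)
        regs_by_scan[sid] = {
            "working_memory": wm_reg,
            "visual": vis_reg,
            "co2": vascular_regressor(trace, hrf, tr, n_vols),
        }
        petco2_grids.append(trace.grid_values)

    table = normalized_r2_table(scan_ts, pair_index, regs_by_scan)
    report = paired_component_tests(table, alpha=level_alpha, seed=seed)

    wm_par = study.paradigms["working_memory"]
    tr_idx = np.round(np.arange(n_vols) * tr / wm_par.dt_s).astype(int)
    wm_tc = wm_par.timecourse[tr_idx]
    group_petco2 = np.mean(petco2_grids, axis=0)
    r_full = float(np.corrcoef(group_petco2, wm_tc)[0, 1])

    onsets = [o for o, _ in wm_par.blocks]
    window = 30.0  # the task block itself; later epochs would overlap the next block
    rel_t, co2_avg, _ = block_average(group_petco2, onsets, window, tr)
    _, wm_avg, _ = block_average(wm_tc, onsets, window, tr)
    r_block = float(np.corrcoef(co2_avg, wm_avg)[0, 1])

    # stimulus-locked mean response of each pair member (group-mean
    # dual-regression timecourse, averaged over working-memory blocks)
    group_ts = np.mean([scan_ts[k] for k in scan_ts], axis=0)
    block_curves = {}
    for label, members in pair_index.items():
        for member, comp in members.items():
            _, curve, _ = block_average(group_ts[:, comp], onsets, window, tr)
            block_curves[f"{label}_{member}"] = curve

    coupling = {
        "r_full": r_full,
        "r_block_average": r_block,
        "n_scans": len(study.scans),
        "block_rel_t_s": rel_t.tolist(),
        "block_averages": {k: v.tolist() for k, v in block_curves.items()},
    }
    return table, report, coupling
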
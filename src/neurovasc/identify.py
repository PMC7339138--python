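"""Component labeling, mixture-model thresholding, Dice overlap, pairing.

The three neuronal networks are labeled by signed temporal correlation with
the stimulus models: the component most *negatively* correlated with the
working-memory regressor is the Default Mode Network (which deactivates
during the task), the most positively correlated is the Task Positive
Network, and the component most positively correlated with the visual
regressor is the Visual Network.  Each labeled component is then paired
with the remaining component of greatest spatial overlap (Dice coefficient
of mixture-model-thresholded maps) — its putative "vascular" sibling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .decompose import ICADecomposition
from .paradigm import Regressor, ValidationError
from .preprocess import BOLDDataset

__all__ = [
    "ComponentPair",
    "BinaryMask",
    "find_neural_components",
    "mixture_model_threshold",
    "dice_coefficient",
    "pair_components",
    "partition_voxels",
]

log = logging.getLogger(__name__)

#: sign each label's defining correlation must have
LABEL_SIGNS = {"DMN": -1, "TPN": 1, "VN": 1}


@dataclass(frozen=True)
class BinaryMask:
    """A thresholded component map as a 3D boolean grid."""

    grid: np.ndarray = field(repr=False)

    @property
    def count(self) -> int:
        return int(self.grid.sum())

    @classmethod
    def from_flat(cls, flat: np.ndarray, brain_mask: np.ndarray) -> "BinaryMask":
        g = np.zeros(brain_mask.shape, dtype=bool)
        g[brain_mask] = flat
        return cls(grid=g)


@dataclass(frozen=True)
class ComponentPair:
    label: str
    neural_idx: int
    vascular_idx: int | None
    dice: float
    neural_corr: float
    matched: bool = True


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def find_neural_components(
    decomp: ICADecomposition, wm_reg: Regressor, vis_reg: Regressor
) -> dict:
    """Label DMN / TPN / VN by extreme signed stimulus correlations.

    Returns ``{label: (component_index, signed_r)}``.  The three winners
    must be distinct; a collision raises with the offending correlations.
    """
    ts = decomp.timeseries
    if ts.shape[0] != wm_reg.n_vols or ts.shape[0] != vis_reg.n_vols:
        raise ValidationError("regressor length does not match timeseries")
    r_wm = np.array([_corr(ts[:, k], wm_reg.values) for k in range(decomp.n_comp)])
    r_vis = np.array([_corr(ts[:, k], vis_reg.values) for k in range(decomp.n_comp)])
    # deterministic tie-break: argmin/argmax take the lowest index
    labels = {
        "DMN": (int(np.argmin(r_wm)), float(r_wm[np.argmin(r_wm)])),
        "TPN": (int(np.argmax(r_wm)), float(r_wm[np.argmax(r_wm)])),
        "VN": (int(np.argmax(r_vis)), float(r_vis[np.argmax(r_vis)])),
    }
    idxs = [v[0] for v in labels.values()]
    if len(set(idxs)) != 3:
        raise ValidationError(
            "component label collision: "
            + ", ".join(f"{k}->{v[0]} (r={v[1]:.3f})" for k, v in labels.items())
        )
    return labels


def mixture_model_threshold(
    map_values: np.ndarray,
    level: float = 0.5,
    max_iter: int = 200,
    tol: float = 1e-6,
    fallback_z: float = 2.3,
):
    """Threshold a component map via a Gaussian + Gamma mixture posterior.

    Fits, by expectation-maximization, a two-class mixture to the map
    values: a Gaussian null and a positive activation class modeled as a
    Gamma tail (density zero at and below the null mean).  Voxels whose
    posterior probability of activation exceeds ``level`` are included.  If
    EM degenerates (a vanishing class, or no positive tail) the threshold
    falls back to a fixed z > ``fallback_z`` cut with a logged warning.

    Returns ``(flat_bool, info)`` where ``flat_bool`` aligns with
    ``map_values``.
    """
    x = np.asarray(map_values, dtype=float)
    if x.size < 1000:
        raise ValidationError(f"map has {x.size} voxels; need >= 1000")
    if level >= 1.0:
        return np.zeros(x.size, dtype=bool), {"method": "mixture", "note": "level>=1"}

    mu0 = float(np.median(x))
    sd0 = float(1.4826 * np.median(np.abs(x - mu0))) or float(x.std())
    pi1 = 0.05
    hi = x > np.quantile(x, 0.95)
    shift = mu0
    pos = x[hi] - shift
    k_g = 2.0
    theta_g = max(pos.mean(), 1e-3) / k_g

    def gamma_pdf(v):
        out = np.zeros_like(v)
        m = v > shift
        out[m] = gamma_dist.pdf(v[m] - shift, k_g, scale=theta_g)
        return out

    ok = True
    for _ in range(max_iter):
        f0 = (1 - pi1) * norm.pdf(x, mu0, sd0)
        f1 = pi1 * gamma_pdf(x)
        tot = f0 + f1
        tot[tot <= 0] = 1e-300
        r1 = f1 / tot
        pi1_new = float(r1.mean())
        if pi1_new < 1e-4 or pi1_new > 0.999:
            ok = False
            break
        w0 = 1 - r1
        mu0_new = float((w0 * x).sum() / w0.sum())
        sd0_new = float(np.sqrt((w0 * (x - mu0_new) ** 2).sum() / w0.sum()))
        m = x > mu0_new
        w1 = r1[m]
        if w1.sum() < 1e-6 or sd0_new < 1e-8:
            ok = False
            break
        v = x[m] - mu0_new
        mean1 = (w1 * v).sum() / w1.sum()
        var1 = (w1 * (v - mean1) ** 2).sum() / w1.sum()
        if var1 <= 1e-10 or mean1 <= 0:
            ok = False
            break
        k_new = mean1**2 / var1
        theta_new = var1 / mean1
        delta = abs(pi1_new - pi1) + abs(mu0_new - mu0) + abs(sd0_new - sd0)
        pi1, mu0, sd0 = pi1_new, mu0_new, sd0_new
        k_g, theta_g, shift = k_new, theta_new, mu0_new
        if delta < tol:
            break

    # the activation class must sit clear of the null: without separation the
    # Gamma simply absorbs the positive half of a (sub)Gaussian map
    if ok and shift + k_g * theta_g < mu0 + 2.0 * sd0:
        ok = False
    if ok:
        f0 = (1 - pi1) * norm.pdf(x, mu0, sd0)
        f1 = pi1 * gamma_pdf(x)
        tot = f0 + f1
        tot[tot <= 0] = 1e-300
        post = f1 / tot
        sel = post > level
        info = {"method": "mixture", "pi1": pi1, "mu0": mu0, "sd0": sd0,
                "gamma_shape": k_g, "gamma_scale": theta_g}
        return sel, info

    log.warning("mixture EM degenerated; falling back to z > %.1f cut", fallback_z)
    z = (x - x.mean()) / (x.std() or 1.0)
    return z > fallback_z, {"method": "fallback_z", "z": fallback_z}


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 0 when both masks are empty."""
    if a.grid.shape != b.grid.shape:
        raise ValidationError(
            f"mask grids differ: {a.grid.shape} vs {b.grid.shape}"
        )
    denom = a.count + b.count
    if denom == 0:
        return 0.0
    inter = int(np.logical_and(a.grid, b.grid).sum())
    return 2.0 * inter / denom


def threshold_all_components(
    decomp: ICADecomposition, level: float = 0.5
) -> list:
    """Mixture-model threshold every component map; list of BinaryMask."""
    masks = []
    for k in range(decomp.n_comp):
        flat, _ = mixture_model_threshold(decomp.maps[k], level=level)
        masks.append(BinaryMask.from_flat(flat, decomp.mask))
    return masks


def pair_components(
    decomp: ICADecomposition,
    neural_labels: dict,
    level: float = 0.5,
    exclude_neural: bool = False,
    masks: list | None = None,
):
    """Pair each labeled neural component with its max-Dice partner.

    Candidates exclude the component itself and, optionally
    (``exclude_neural``), the other neural-labeled components.  Ties break
    to the lower component index (logged); a zero maximum Dice flags the
    pair as unmatched.

    Returns ``(pairs, masks)``.
    """
    if masks is None:
        masks = threshold_all_components(decomp, level=level)
    neural_idx = {v[0] for v in neural_labels.values()}
    pairs = []
    for label, (idx, r) in neural_labels.items():
        best_j, best_d = None, 0.0
        for j in range(decomp.n_comp):
            if j == idx:
                continue
            if exclude_neural and j in neural_idx and j != idx:
                continue
            d = dice_coefficient(masks[idx], masks[j])
            if d > best_d or (d == best_d and best_d > 0 and j < best_j):
                if d == best_d and best_j is not None:
                    log.info("Dice tie for %s between %d and %d; keeping %d",
                             label, best_j, j, min(best_j, j))
                best_j, best_d = j, d
        if best_j is None or best_d == 0.0:
            pairs.append(ComponentPair(label=label, neural_idx=idx,
                                       vascular_idx=None, dice=0.0,
                                       neural_corr=r, matched=False))
        else:
            pairs.append(ComponentPair(label=label, neural_idx=idx,
                                       vascular_idx=best_j, dice=best_d,
                                       neural_corr=r))
    return pairs, masks


def partition_voxels(
    pair: ComponentPair,
    masks: list,
    dataset: BOLDDataset | None = None,
):
    """Split a pair's voxels into unique-neural / unique-vascular / common.

    Returns ``(regions, timeseries)``: three BinaryMasks, plus the mean
    %BOLD timecourse of each nonempty region when ``dataset`` is given
    (empty regions are flagged by omission).
    """
    if pair.vascular_idx is None:
        raise ValidationError(f"pair {pair.label} is unmatched")
    a = masks[pair.neural_idx].grid
    b = masks[pair.vascular_idx].grid
    regions = {
        "unique_neural": BinaryMask(grid=a & ~b),
        "unique_vascular": BinaryMask(grid=b & ~a),
        "common": BinaryMask(grid=a & b),
    }
    timeseries = {}
    if dataset is not None:
        for name, bm in regions.items():
            if bm.count > 0:
                timeseries[name] = dataset.data[bm.grid].mean(axis=0)
    return regions, timeseries
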
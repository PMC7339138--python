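"""Spatial ICA of a group-average %BOLD dataset.

Voxels are treated as samples and timepoints as features, so independence is
maximized over space; each component is a spatial map with an associated
timecourse.  A fixed-point negentropy-maximizing ICA (FastICA) after PCA
whitening stands in for probabilistic ICA; the dimensionality is fixed
(default 30 components).  ICA sign is arbitrary, so a deterministic
convention is enforced: every map is flipped to non-negative skewness (with
its timecourse flipped in tandem) and scaled to unit variance over the mask.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.stats import kurtosis, skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .paradigm import ValidationError
from .preprocess import BOLDDataset

__all__ = ["ICADecomposition", "spatial_ica", "save_decomposition",
           "load_decomposition"]


@dataclass(frozen=True)
class ICADecomposition:
    """Spatial maps (n_comp x n_maskvoxels) and timeseries (n_vols x n_comp)."""

    maps: np.ndarray = field(repr=False)
    timeseries: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    tr_s: float = 2.0
    n_comp: int = 0
    seed: int = 0
    n_iter: int = 0

    def map_3d(self, idx: int) -> np.ndarray:
        out = np.zeros(self.mask.shape, dtype=float)
        out[self.mask] = self.maps[idx]
        return out


def spatial_ica(
    ds: BOLDDataset,
    n_comp: int = 30,
    seed: int = 0,
    n_restarts: int = 8,
    max_retries: int = 3,
    max_iter: int = 500,
    tol: float = 1e-4,
    algorithm: str = "deflation",
    fun: str = "cube",
) -> ICADecomposition:
    """Decompose a %BOLD dataset into spatially independent components.

    PCA-whitens to ``n_comp`` dimensions then runs fixed-point ICA with
    voxels as samples.  The kurtosis ("cube") contrast suits the sparse,
    heavy-tailed spatial maps of blob-like networks; the deflationary
    scheme estimates components one at a time, which is robust when many
    whitened dimensions carry only noise (the parallel scheme tends to
    oscillate there).  Deflation can land in run-dependent local optima, so
    ``n_restarts`` seeded runs are performed and the one with the greatest
    total spatial non-Gaussianity (summed |excess kurtosis|, the contrast
    the algorithm maximizes) is kept.  Non-convergence triggers retries
    with derived seeds, then an error.  Deterministic per seed.
    """
    if ds.units != "percent_bold":
        raise ValidationError("spatial_ica expects percent_bold units")
    if n_comp >= ds.n_vols:
        raise ValidationError(f"n_comp ({n_comp}) must be < n_vols ({ds.n_vols})")
    mask = ds.mask if ds.mask is not None else np.ones(ds.grid, bool)
    X = ds.data[mask].astype(np.float64)  # (n_voxels, n_vols); voxels = samples

    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(seed).spawn(n_restarts + max_retries)]
    last_err = None
    best = None
    n_done = 0
    for attempt_seed in seeds:
        if n_done >= n_restarts:
            break
        ica = FastICA(n_components=n_comp, random_state=attempt_seed,
                      whiten="unit-variance", max_iter=max_iter, tol=tol,
                      algorithm=algorithm, fun=fun)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                S = ica.fit_transform(X)  # (n_voxels, n_comp): spatial maps
            except ConvergenceWarning as exc:
                last_err = exc
                continue
        n_done += 1
        objective = float(np.abs(kurtosis(S, axis=0)).sum())
        if best is None or objective > best[0]:
            best = (objective, S, ica.mixing_, int(ica.n_iter_))
    if best is None:
        raise RuntimeError(
            f"FastICA failed to converge after {len(seeds)} seeded attempts: "
            f"{last_err}"
        )
    _, S, A, n_iter = best
    maps = S.T.copy()
    ts = A.copy()                        # (n_vols, n_comp): timecourses
    for k in range(n_comp):
        sd = maps[k].std()
        if sd > 0:
            maps[k] /= sd
            ts[:, k] *= sd
        if skew(maps[k]) < 0:
            maps[k] *= -1
            ts[:, k] *= -1
    return ICADecomposition(maps=maps, timeseries=ts, mask=mask,
                            tr_s=ds.tr_s, n_comp=n_comp, seed=seed,
                            n_iter=n_iter)


def save_decomposition(decomp: ICADecomposition, maps_path, ts_path,
                       sidecar_path) -> None:
    """Maps as 4D NIfTI (component = 4th axis), timeseries as text, JSON sidecar."""
    vol = np.zeros(decomp.mask.shape + (decomp.n_comp,), dtype=np.float32)
    for k in range(decomp.n_comp):
        vol[decomp.mask, k] = decomp.maps[k]
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(maps_path))
    np.savetxt(ts_path, decomp.timeseries, fmt="%.8g")
    with open(sidecar_path, "w") as fh:
        json.dump({"n_comp": decomp.n_comp, "seed": decomp.seed,
                   "n_iter": decomp.n_iter, "tr_s": decomp.tr_s}, fh, indent=2)


def load_decomposition(maps_path, ts_path, sidecar_path,
                       mask: np.ndarray) -> ICADecomposition:
    vol = np.asarray(nib.load(str(maps_path)).dataobj)
    ts = np.loadtxt(ts_path, ndmin=2)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    maps = np.stack([vol[..., k][mask] for k in range(vol.shape[-1])])
    return ICADecomposition(maps=maps, timeseries=ts, mask=mask,
                            tr_s=meta["tr_s"], n_comp=meta["n_comp"],
                            seed=meta["seed"], n_iter=meta["n_iter"])
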
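"""Stimulus paradigms, the canonical HRF, and TR-sampled regressors.

The study delivers three concurrent stimuli inside one 11-min (660 s) scan:
a 3-back working-memory task in 30-s blocks with an extended rest in the
middle, a flashing-checkerboard visual stimulus confined to the second half,
and four 1-min hypercapnia (CO2 inhalation) blocks.  The three designs are
mutually orthogonal: every pairwise Pearson correlation of the idealized
(unconvolved) binary timecourses is exactly zero.

Exact orthogonality of binary designs requires, for each pair, that the
on-overlap equals the product of the on-fractions times the scan length.
With a 660-s scan, 30-s WM blocks and four 60-s CO2 blocks this is only
integer-feasible with 11 WM blocks (330 s on, WM∩CO2 = 120 s) and 33-s
visual blocks (four blocks: WM∩VIS = 66 s, VIS∩CO2 = 48 s).  The default
onsets below were found by a seeded combinatorial search on a 1.5-s grid
(the granularity of the working-memory item presentation) and are frozen
here; they are a documented, overridable default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gamma as gamma_dist

__all__ = [
    "Paradigm",
    "HRFKernel",
    "Regressor",
    "build_block_paradigm",
    "default_paradigms",
    "canonical_hrf",
    "convolve_to_regressor",
    "orthogonality_matrix",
    "blocks_from_timecourse",
    "paradigm_to_yaml",
    "paradigm_from_yaml",
    "save_regressor",
    "load_regressor",
    "DEFAULT_TOTAL_DURATION_S",
    "DEFAULT_DT_S",
    "DEFAULT_BLOCKS",
]

DEFAULT_TOTAL_DURATION_S = 660.0
DEFAULT_DT_S = 0.1

#: Frozen default block schedules (onset_s, duration_s); pairwise Pearson
#: correlations of the binary timecourses are zero to machine precision.
DEFAULT_BLOCKS: dict[str, tuple[tuple[float, float], ...]] = {
    "working_memory": tuple(
        (o, 30.0)
        for o in (3.0, 49.5, 90.0, 130.5, 186.0, 229.5,
                  366.0, 417.0, 472.5, 523.5, 571.5)
    ),
    "visual": tuple((o, 33.0) for o in (400.5, 472.5, 534.0, 624.0)),
    "hypercapnia": tuple((o, 60.0) for o in (106.5, 256.5, 438.0, 544.5)),
}


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True)
class Paradigm:
    """A block stimulus design and its binary timecourse.

    ``timecourse[i]`` is 1 exactly when ``i * dt_s`` falls inside a block.
    """

    name: str
    blocks: tuple[tuple[float, float], ...]
    total_duration_s: float
    dt_s: float
    timecourse: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.timecourse.size


@dataclass(frozen=True)
class HRFKernel:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    ``params = (a1, a2, b1, b2, c)``: response gamma shape/undershoot gamma
    shape, the two rate parameters (1/s), and the undershoot ratio.
    """

    dt_s: float
    samples: np.ndarray = field(repr=False)
    params: tuple[float, float, float, float, float] = (6.0, 16.0, 1.0, 1.0, 1.0 / 6.0)

    @property
    def duration_s(self) -> float:
        return self.samples.size * self.dt_s


@dataclass(frozen=True)
class Regressor:
    """A model timecourse sampled on the volume (TR) grid."""

    name: str
    values: np.ndarray = field(repr=False)
    tr_s: float
    convolved: bool = True

    @property
    def n_vols(self) -> int:
        return self.values.size


def build_block_paradigm(
    name: str,
    blocks,
    total_duration_s: float = DEFAULT_TOTAL_DURATION_S,
    dt_s: float = DEFAULT_DT_S,
) -> Paradigm:
    """Build a binary block paradigm sampled at ``dt_s``.

    Blocks must be sorted, non-overlapping and lie within
    ``[0, total_duration_s)``.
    """
    if dt_s <= 0:
        raise ValidationError("dt_s must be positive")
    if total_duration_s <= 0:
        raise ValidationError("total_duration_s must be positive")
    blocks = tuple((float(o), float(d)) for o, d in blocks)
    prev_end = -np.inf
    for onset, dur in blocks:
        if dur <= 0:
            raise ValidationError(f"block duration must be positive, got {dur}")
        if onset < prev_end:
            raise ValidationError(
                f"blocks overlap or are unsorted at onset {onset} (previous "
                f"block ends at {prev_end})"
            )
        if onset < 0 or onset + dur > total_duration_s:
            raise ValidationError(
                f"block ({onset}, {dur}) exceeds [0, {total_duration_s})"
            )
        prev_end = onset + dur
    n = int(round(total_duration_s / dt_s))
    t = np.arange(n) * dt_s
    tc = np.zeros(n)
    for onset, dur in blocks:
        tc[(t >= onset) & (t < onset + dur)] = 1.0
    return Paradigm(name=name, blocks=blocks, total_duration_s=float(total_duration_s),
                    dt_s=float(dt_s), timecourse=tc)


def default_paradigms(
    include_hypercapnia: bool = True, dt_s: float = DEFAULT_DT_S
) -> dict[str, Paradigm]:
    """The frozen mutually-orthogonal three-paradigm preset.

    With ``include_hypercapnia=False`` (replication mode) only the two
    neuronal paradigms are returned; their timings are unchanged.
    """
    names = ["working_memory", "visual"]
    if include_hypercapnia:
        names.append("hypercapnia")
    return {
        nm: build_block_paradigm(nm, DEFAULT_BLOCKS[nm], DEFAULT_TOTAL_DURATION_S, dt_s)
        for nm in names
    }


def canonical_hrf(
    dt_s: float,
    params: tuple[float, float, float, float, float] = (6.0, 16.0, 1.0, 1.0, 1.0 / 6.0),
    duration_s: float = 32.0,
) -> HRFKernel:
    """Canonical double-gamma HRF on ``[0, duration_s]``, peak-normalized.

    h(t) = pdf_gamma(t; a1, b1) - c * pdf_gamma(t; a2, b2), the standard
    form with a ~5-s main lobe and a late undershoot.
    """
    if not (0 < dt_s <= 2):
        raise ValidationError(f"dt_s must be in (0, 2], got {dt_s}")
    a1, a2, b1, b2, c = params
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    h = gamma_dist.pdf(t, a1, scale=1.0 / b1) - c * gamma_dist.pdf(t, a2, scale=1.0 / b2)
    peak = h.max()
    if peak <= 0:
        raise ValidationError("HRF parameters produce no positive lobe")
    return HRFKernel(dt_s=float(dt_s), samples=h / peak, params=tuple(params))


def convolve_to_regressor(
    timecourse: np.ndarray,
    hrf: HRFKernel,
    tr_s: float,
    n_vols: int,
    dt_s: float | None = None,
    name: str = "regressor",
) -> Regressor:
    """Convolve a dt-sampled timecourse with the HRF; sample at the TR grid.

    Causal discrete convolution with zero-padded past (signal is zero before
    scan start).  Volume k is sampled at ``t = k * tr_s``.  ``dt_s`` defaults
    to the kernel's; when given it must match.
    """
    timecourse = np.asarray(timecourse, dtype=float)
    if dt_s is not None and not np.isclose(dt_s, hrf.dt_s):
        raise ValidationError(
            f"timecourse dt ({dt_s}) does not match HRF dt ({hrf.dt_s})"
        )
    dt = hrf.dt_s
    if n_vols * tr_s > timecourse.size * dt + dt / 2:
        raise ValidationError(
            f"{n_vols} volumes at TR {tr_s}s exceed the {timecourse.size * dt}s "
            "timecourse"
        )
    conv = np.convolve(timecourse, hrf.samples)[: timecourse.size]
    idx = np.round(np.arange(n_vols) * tr_s / dt).astype(int)
    return Regressor(name=name, values=conv[idx], tr_s=float(tr_s), convolved=True)


def orthogonality_matrix(items) -> pd.DataFrame:
    """Pairwise Pearson-correlation table of paradigms/regressors/arrays.

    Zero-variance inputs get NaN entries (flagged, not a crash).
    """
    vecs, names = [], []
    for i, it in enumerate(items):
        if isinstance(it, Paradigm):
            vecs.append(it.timecourse)
            names.append(it.name)
        elif isinstance(it, Regressor):
            vecs.append(it.values)
            names.append(it.name)
        else:
            vecs.append(np.asarray(it, dtype=float))
            names.append(f"x{i}")
    n = len(vecs)
    lengths = {v.size for v in vecs}
    if len(lengths) != 1:
        raise ValidationError(f"inputs have unequal lengths: {sorted(lengths)}")
    out = np.full((n, n), np.nan)
    sds = [v.std() for v in vecs]
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0 if sds[i] > 0 else np.nan
            elif sds[i] > 0 and sds[j] > 0:
                out[i, j] = np.corrcoef(vecs[i], vecs[j])[0, 1]
    return pd.DataFrame(out, index=names, columns=names)


def blocks_from_timecourse(tc: np.ndarray, dt_s: float) -> tuple[tuple[float, float], ...]:
    """Recover (onset_s, duration_s) blocks from a binary timecourse."""
    tc = np.asarray(tc)
    padded = np.concatenate([[0], (tc > 0.5).astype(int), [0]])
    d = np.diff(padded)
    onsets = np.where(d == 1)[0]
    offsets = np.where(d == -1)[0]
    return tuple((float(o * dt_s), float((f - o) * dt_s)) for o, f in zip(onsets, offsets))


# -- serialization -----------------------------------------------------------

def paradigm_to_yaml(paradigm: Paradigm, path) -> None:
    doc = {
        "name": paradigm.name,
        "blocks": [[float(o), float(d)] for o, d in paradigm.blocks],
        "total_duration": float(paradigm.total_duration_s),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def paradigm_from_yaml(path, dt_s: float = DEFAULT_DT_S) -> Paradigm:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return build_block_paradigm(
        doc["name"], [tuple(b) for b in doc["blocks"]], doc["total_duration"], dt_s
    )


def save_regressor(reg: Regressor, path) -> None:
    """One value per volume, plain text — the dialect of common GLM tools."""
    np.savetxt(path, reg.values, fmt="%.10g")


def load_regressor(path, tr_s: float, name: str = "regressor",
                   convolved: bool = True) -> Regressor:
    vals = np.loadtxt(path, ndmin=1)
    return Regressor(name=name, values=vals, tr_s=tr_s, convolved=convolved)
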
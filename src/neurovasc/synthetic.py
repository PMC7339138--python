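"""Ground-truthed synthetic BOLD studies with paired neural/vascular networks.

Each of three functional networks (DMN, TPN, VN) is represented by TWO
spatially overlapping sources: a "neural" map whose timecourse follows the
HRF-convolved task design (negative for the DMN, which deactivates during
working memory), and a "vascular" map whose timecourse follows the
HRF-convolved end-tidal CO2 excursion scaled by a cerebrovascular
reactivity (CVR, %BOLD per mmHg).  Maps are sums of 3D Gaussian blobs;
shared blobs give the pair its spatial overlap, unique blobs differentiate
the members.  A weak global CO2 response is added to every in-mask voxel,
and each voxel carries a random quadratic drift and white noise on top of a
raw baseline intensity.

Two modes:

* ``hypercapnia`` — four 1-min CO2-inhalation blocks raise PetCO2 by a
  target +5 mmHg above a per-subject baseline (10 subjects x 3 scans).
* ``replication`` — no gas challenge; PetCO2 fluctuates naturally but is
  negatively coupled to the working-memory task (task-correlated breathing),
  calibrated so the full-length PetCO2/WM correlation is about -0.68
  (8 subjects x 3 scans).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .paradigm import (
    DEFAULT_DT_S,
    HRFKernel,
    Paradigm,
    ValidationError,
    canonical_hrf,
    default_paradigms,
    paradigm_to_yaml,
)
from .physio import (
    PetCO2Trace,
    RawGasTrace,
    extract_end_tidal,
    simulate_capnograph,
    save_raw_trace,
)
from .preprocess import BOLDDataset, save_bold

__all__ = [
    "NetworkPairSpec",
    "GroundTruth",
    "Scan",
    "Study",
    "StudyConfig",
    "default_pair_specs",
    "ellipsoid_mask",
    "make_network_pair_maps",
    "simulate_scan",
    "simulate_study",
    "write_study",
]

LABELS = ("DMN", "TPN", "VN")

#: per-network vascular timing offsets (s) emulating non-zero transit lags
DEFAULT_VASCULAR_LAGS_S = {"DMN": 4.0, "TPN": 0.0, "VN": 0.0}

#: per-network vascular response dispersion (s): CO2 arrival is increasingly
#: smeared along longer vascular paths, a shape difference beyond a pure lag
DEFAULT_VASCULAR_DISP_S = {"DMN": 6.0, "TPN": 0.0, "VN": 0.0}

#: per-network adapting (transient-emphasis) fraction of the CO2 response
#: and its adaptation time constant: regional vascular responses differ in
#: sustained-vs-transient dynamics, not only in arrival time
DEFAULT_VASCULAR_TRANSIENT = {"DMN": 0.0, "TPN": 0.7, "VN": 0.0}
DEFAULT_VASCULAR_ADAPT_TAU_S = {"DMN": 15.0, "TPN": 15.0, "VN": 15.0}

#: per-network neural response latency/dispersion (s): deactivation (DMN)
#: is slower than activation — the dynamics are not exact temporal mirrors,
#: which is also what makes the two task-locked sources separable by ICA
#: (exactly collinear timecourses would collapse into a single component).
#: An optional adapting (onset-transient) neural response is available but
#: disabled by default.
DEFAULT_NEURAL_TRANSIENT = {"DMN": 0.0, "TPN": 0.0, "VN": 0.0}
DEFAULT_NEURAL_ADAPT_TAU_S = {"DMN": 8.0, "TPN": 8.0, "VN": 8.0}
DEFAULT_NEURAL_LAGS_S = {"DMN": 2.0, "TPN": 0.0, "VN": 0.5}
DEFAULT_NEURAL_DISP_S = {"DMN": 4.0, "TPN": 0.0, "VN": 1.0}


@dataclass(frozen=True)
class NetworkPairSpec:
    """Geometry and amplitude of one neural/vascular network pair."""

    label: str
    shared_nodes: int = 1
    neural_unique_nodes: int = 3
    vascular_unique_nodes: int = 3
    neural_amp: float = 1.0          # %BOLD at task plateau
    vascular_amp: float = 0.25       # CVR, %BOLD per mmHg PetCO2
    neural_sign: int = 1             # -1 for DMN deactivation
    shared_weight: float = 1.0       # relative amplitude of shared nodes

    def __post_init__(self):
        if self.shared_nodes < 1:
            raise ValidationError(
                f"{self.label}: pairs must overlap (shared_nodes >= 1)"
            )
        if self.neural_amp < 0 or self.vascular_amp < 0:
            raise ValidationError(f"{self.label}: amplitudes must be >= 0")
        if self.neural_sign not in (-1, 1):
            raise ValidationError(f"{self.label}: neural_sign must be +-1")


def default_pair_specs() -> tuple[NetworkPairSpec, ...]:
    return (
        NetworkPairSpec("DMN", neural_amp=1.0, vascular_amp=0.40, neural_sign=-1),
        NetworkPairSpec("TPN", neural_amp=1.2, vascular_amp=0.60, neural_sign=1),
        NetworkPairSpec("VN", neural_amp=1.8, vascular_amp=0.60, neural_sign=1),
    )


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    spatial_maps: dict                       # source name -> 3D map
    true_pairs: list                         # (neural_name, vascular_name, label)
    true_dice: dict                          # label -> dice of half-max masks
    node_centers: dict                       # source name -> list of centers
    noise_params: dict


@dataclass
class Scan:
    subject_id: int
    scan_id: int
    bold: BOLDDataset
    petco2: PetCO2Trace                      # extracted from the raw trace
    raw_gas: RawGasTrace
    source_ts: dict                          # source name -> TR-grid timecourse
    petco2_true: np.ndarray = field(repr=False, default=None)  # envelope, TR grid


@dataclass
class Study:
    mode: str
    scans: list
    paradigms: dict
    hrf: HRFKernel
    ground_truth: GroundTruth
    config: "StudyConfig"
    mask: np.ndarray = field(repr=False, default=None)


@dataclass
class StudyConfig:
    """Study-level generator settings; defaults are the emulated conditions."""

    mode: str = "hypercapnia"
    n_subjects: int | None = None            # 10 hypercapnia / 8 replication
    n_scans_per_subject: int = 3
    n_vols: int = 330
    tr_s: float = 2.0
    grid: tuple = (24, 24, 12)
    s0: float = 1000.0                       # raw in-mask baseline intensity
    noise_sd: float = 8.0                    # white noise, raw units
    drift_sd: float = 4.0                    # quadratic drift coef sd, raw units
    cvr_global: float = 0.05                 # global CO2 response, %BOLD/mmHg
    co2_target_mmHg: float = 5.0             # hypercapnia block rise
    co2_tau_s: float = 8.0                   # gas-equilibration time constant
    coupling_k_mmHg: float = 3.0             # replication: task-CO2 coupling
    coupling_tau_s: float = 8.0             # breathing-response smoothing
    ar_sd_mmHg: float | None = None          # natural PetCO2 AR(1) noise sd
    ar_phi: float = 0.9
    drift_co2_mmHg: float | None = None      # slow PetCO2 drift amplitude
    blob_sigma_vox: float = 1.6
    subject_amp_sd: float = 0.15             # between-subject amplitude spread
    scan_amp_sd: float = 0.10                # between-scan amplitude spread
    vascular_lags_s: dict = field(
        default_factory=lambda: dict(DEFAULT_VASCULAR_LAGS_S)
    )
    vascular_disp_s: dict = field(
        default_factory=lambda: dict(DEFAULT_VASCULAR_DISP_S)
    )
    vascular_transient: dict = field(
        default_factory=lambda: dict(DEFAULT_VASCULAR_TRANSIENT)
    )
    vascular_adapt_tau_s: dict = field(
        default_factory=lambda: dict(DEFAULT_VASCULAR_ADAPT_TAU_S)
    )
    neural_lags_s: dict = field(
        default_factory=lambda: dict(DEFAULT_NEURAL_LAGS_S)
    )
    neural_disp_s: dict = field(
        default_factory=lambda: dict(DEFAULT_NEURAL_DISP_S)
    )
    neural_transient: dict = field(
        default_factory=lambda: dict(DEFAULT_NEURAL_TRANSIENT)
    )
    neural_adapt_tau_s: dict = field(
        default_factory=lambda: dict(DEFAULT_NEURAL_ADAPT_TAU_S)
    )
    capnograph_rate_hz: float = 25.0
    breath_period_s: float = 3.5
    pair_specs: tuple = field(default_factory=default_pair_specs)

    def __post_init__(self):
        if self.mode not in ("hypercapnia", "replication"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        self.grid = tuple(self.grid)
        self.pair_specs = tuple(
            NetworkPairSpec(**p) if isinstance(p, dict) else p
            for p in self.pair_specs
        )
        if self.n_subjects is None:
            self.n_subjects = 10 if self.mode == "hypercapnia" else 8
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be positive")
        if self.n_vols < 10:
            raise ValidationError("n_vols must be >= 10")
        # natural breathing variability is much larger without a gas challenge
        if self.ar_sd_mmHg is None:
            self.ar_sd_mmHg = 0.25 if self.mode == "hypercapnia" else 1.2
        if self.drift_co2_mmHg is None:
            self.drift_co2_mmHg = 0.3 if self.mode == "hypercapnia" else 0.9

    @property
    def duration_s(self) -> float:
        return self.n_vols * self.tr_s


def ellipsoid_mask(grid, margin: float = 0.95) -> np.ndarray:
    """Ellipsoidal 'brain' mask filling ``margin`` of each half-axis."""
    nx, ny, nz = grid
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = margin * nx / 2, margin * ny / 2, margin * nz / 2
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _gaussian_blob(grid, center, sigma) -> np.ndarray:
    nx, ny, nz = grid
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _place_centers(n, grid, mask, region_x, rng, sigma, existing,
                   min_sep_factor: float = 2.0, max_tries: int = 2000,
                   avoid=(), avoid_sep_factor: float = 3.0):
    """Random blob centers inside ``mask`` and the x-slab ``region_x``.

    ``avoid`` holds other networks' centers, kept at a wider separation so
    blobs of different pairs stay spatially disjoint even near slab edges.
    """
    nx, ny, nz = grid
    centers = []
    min_sep = min_sep_factor * sigma
    avoid_sep = avoid_sep_factor * sigma
    margin = max(int(round(sigma)), 1)   # keep blobs clear of the mask edge
    for _ in range(n):
        for attempt in range(max_tries):
            c = np.array([
                rng.uniform(region_x[0] + 1, region_x[1] - 1),
                rng.uniform(1, ny - 2),
                rng.uniform(1, nz - 2),
            ])
            ci = np.clip(np.round(c).astype(int), 0, [nx - 1, ny - 1, nz - 1])
            probes = [ci]
            for ax in range(3):
                for d in (-margin, margin):
                    p = ci.copy()
                    p[ax] = np.clip(p[ax] + d, 0, grid[ax] - 1)
                    probes.append(p)
            if not all(mask[tuple(p)] for p in probes):
                continue
            if (all(np.linalg.norm(c - e) >= min_sep for e in existing + centers)
                    and all(np.linalg.norm(c - a) >= avoid_sep for a in avoid)):
                centers.append(c)
                break
        else:
            raise ValidationError(
                f"could not place {n} blob centers in x-slab {region_x} "
                f"after {max_tries} tries"
            )
    return centers


def make_network_pair_maps(
    spec: NetworkPairSpec,
    grid,
    seed: int,
    mask: np.ndarray | None = None,
    region_x: tuple | None = None,
    sigma_vox: float = 1.6,
    avoid_centers=(),
):
    """Build one pair of overlapping spatial maps from Gaussian blobs.

    ``avoid_centers`` are node centers of other network pairs; new nodes are
    kept well clear of them so different pairs occupy disjoint territory.
    Returns ``(neural_map, vascular_map, true_dice, centers)`` where
    ``true_dice`` is the Dice coefficient of the two half-maximum binarized
    maps.
    """
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = ellipsoid_mask(grid)
    if region_x is None:
        region_x = (0, grid[0])
    shared = _place_centers(spec.shared_nodes, grid, mask, region_x, rng,
                            sigma_vox, [], avoid=avoid_centers)
    nu = _place_centers(spec.neural_unique_nodes, grid, mask, region_x, rng,
                        sigma_vox, shared, avoid=avoid_centers)
    vu = _place_centers(spec.vascular_unique_nodes, grid, mask, region_x, rng,
                        sigma_vox, shared + nu, avoid=avoid_centers)
    w = spec.shared_weight
    shared_part = sum(w * _gaussian_blob(grid, c, sigma_vox) for c in shared)
    neural = shared_part + sum(_gaussian_blob(grid, c, sigma_vox) for c in nu)
    vascular = shared_part + sum(_gaussian_blob(grid, c, sigma_vox) for c in vu)
    neural *= mask
    vascular *= mask
    a = neural > 0.5 * neural.max()
    b = vascular > 0.5 * vascular.max()
    inter = np.logical_and(a, b).sum()
    true_dice = 2.0 * inter / (a.sum() + b.sum()) if (a.sum() + b.sum()) else 0.0
    centers = {"shared": shared, "neural_unique": nu, "vascular_unique": vu}
    return neural, vascular, float(true_dice), centers


def _smooth_exp(x: np.ndarray, tau_s: float, dt_s: float) -> np.ndarray:
    """Causal exponential smoothing (unit sustained response)."""
    t = np.arange(0.0, 6.0 * tau_s, dt_s)
    k = np.exp(-t / tau_s)
    k /= k.sum()
    return np.convolve(x, k)[: x.size]


def _ar1(n, phi, sd, rng) -> np.ndarray:
    innov_sd = sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = sd * rng.standard_normal()
    eps = innov_sd * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _petco2_envelope(cfg: StudyConfig, paradigms, baseline_mmHg, dt_s, rng):
    """Underlying (breath-free) PetCO2 curve on the fine dt grid, in mmHg."""
    n = int(round(cfg.duration_s / dt_s))
    t = np.arange(n) * dt_s
    drift = cfg.drift_co2_mmHg * np.sin(
        2 * np.pi * t / cfg.duration_s + rng.uniform(0, 2 * np.pi)
    )
    # AR(1) generated at 1-s resolution then interpolated (natural breathing
    # variation is slow relative to dt)
    n1 = int(np.ceil(cfg.duration_s)) + 1
    ar = np.interp(t, np.arange(n1), _ar1(n1, cfg.ar_phi, cfg.ar_sd_mmHg, rng))
    env = baseline_mmHg + drift + ar
    if cfg.mode == "hypercapnia":
        env += cfg.co2_target_mmHg * _smooth_exp(
            paradigms["hypercapnia"].timecourse, cfg.co2_tau_s, dt_s
        )
    else:
        env -= cfg.coupling_k_mmHg * _smooth_exp(
            paradigms["working_memory"].timecourse, cfg.coupling_tau_s, dt_s
        )
    return t, env


def _conv_sustained(x, hrf: HRFKernel, tr_s, n_vols):
    """HRF convolution normalized so a sustained unit input plateaus at 1."""
    conv = np.convolve(x, hrf.samples)[: x.size] / hrf.samples.sum()
    idx = np.round(np.arange(n_vols) * tr_s / hrf.dt_s).astype(int)
    return conv[idx]


def simulate_scan(
    cfg: StudyConfig,
    paradigms: dict,
    hrf: HRFKernel,
    maps: dict,
    subject_params: dict,
    seed,
) -> Scan:
    """Simulate one scan: 4D BOLD data plus its capnograph trace.

    ``maps`` holds the study-level source maps ("<label>_neural" /
    "<label>_vascular"); ``subject_params`` carries per-subject random
    effects (amplitude scale, CVR scale, CO2 baseline).  Deterministic per
    seed.
    """
    rng = np.random.default_rng(seed)
    dt = hrf.dt_s
    n_vols, tr = cfg.n_vols, cfg.tr_s
    mask = subject_params["mask"]

    t_fine, env = _petco2_envelope(
        cfg, paradigms, subject_params["co2_baseline_mmHg"], dt, rng
    )
    delta = env - subject_params["co2_baseline_mmHg"]
    tr_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)

    def shape(x, lag_s, disp_s):
        """Per-network response shaping: lag plus exponential dispersion."""
        y = np.interp(t_fine - lag_s, t_fine, x) if lag_s else x
        return _smooth_exp(y, disp_s, dt) if disp_s else y

    # source timecourses on the TR grid (%BOLD units via the spatial maps)
    source_ts = {}
    for spec in cfg.pair_specs:
        task = "visual" if spec.label == "VN" else "working_memory"
        amp = (spec.neural_amp * subject_params["amp_scale"]
               * (1 + cfg.scan_amp_sd * rng.standard_normal()))
        ntc = shape(paradigms[task].timecourse,
                    cfg.neural_lags_s.get(spec.label, 0.0),
                    cfg.neural_disp_s.get(spec.label, 0.0))
        nresp = np.convolve(ntc, hrf.samples)[: ntc.size] / hrf.samples.sum()
        nbeta = cfg.neural_transient.get(spec.label, 0.0)
        if nbeta:
            nadapt = _smooth_exp(
                nresp, cfg.neural_adapt_tau_s.get(spec.label, 10.0), dt)
            nresp = (1 - nbeta) * nresp + nbeta * (nresp - nadapt)
        source_ts[f"{spec.label}_neural"] = (
            spec.neural_sign * amp * nresp[tr_idx]
        )
        vtc = shape(delta,
                    cfg.vascular_lags_s.get(spec.label, 0.0),
                    cfg.vascular_disp_s.get(spec.label, 0.0))
        resp = np.convolve(vtc, hrf.samples)[: vtc.size] / hrf.samples.sum()
        beta = cfg.vascular_transient.get(spec.label, 0.0)
        if beta:
            adapt = _smooth_exp(resp, cfg.vascular_adapt_tau_s.get(spec.label, 15.0), dt)
            resp = (1 - beta) * resp + beta * (resp - adapt)
        cvr = (spec.vascular_amp * subject_params["cvr_scale"]
               * (1 + cfg.scan_amp_sd * rng.standard_normal()))
        source_ts[f"{spec.label}_vascular"] = cvr * resp[tr_idx]
    # weak brain-wide CO2 response: the aggregate of the per-network response
    # shapes, so it spans no temporal dimension beyond the network sources
    vasc = [source_ts[f"{s.label}_vascular"] / max(s.vascular_amp, 1e-12)
            for s in cfg.pair_specs]
    source_ts["global_co2"] = cfg.cvr_global * np.mean(vasc, axis=0)

    # mix into voxels (percent), then raw units + drift + noise
    vox_pct = np.zeros((int(mask.sum()), n_vols), dtype=np.float64)
    for name, ts in source_ts.items():
        if name == "global_co2":
            vox_pct += ts[None, :]
        else:
            vox_pct += np.outer(maps[name][mask], ts)

    tau = np.linspace(-1.0, 1.0, n_vols)
    nvox = vox_pct.shape[0]
    c1 = cfg.drift_sd * rng.standard_normal(nvox)
    c2 = cfg.drift_sd * rng.standard_normal(nvox)
    drift = np.outer(c1, tau) + np.outer(c2, tau**2)
    base = cfg.s0 * (1 + 0.05 * rng.standard_normal(nvox))
    raw = (base[:, None] * (1 + vox_pct / 100.0) + drift
           + cfg.noise_sd * rng.standard_normal((nvox, n_vols)))

    data = np.zeros(cfg.grid + (n_vols,), dtype=np.float32)
    data[mask] = raw.astype(np.float32)
    bold = BOLDDataset(data=data, tr_s=tr, units="raw", mask=mask.copy())

    raw_gas = simulate_capnograph(
        envelope=np.interp(
            np.arange(int(round(cfg.duration_s * cfg.capnograph_rate_hz)))
            / cfg.capnograph_rate_hz,
            t_fine, env,
        ),
        breath_period_s=cfg.breath_period_s,
        total_s=cfg.duration_s,
        rate_hz=cfg.capnograph_rate_hz,
        seed=int(rng.integers(2**31 - 1)),
    )
    petco2 = extract_end_tidal(
        raw_gas, grid_t_s=np.arange(n_vols) * tr
    )
    return Scan(
        subject_id=subject_params["subject_id"],
        scan_id=subject_params["scan_id"],
        bold=bold,
        petco2=petco2,
        raw_gas=raw_gas,
        source_ts=source_ts,
        petco2_true=env[tr_idx],
    )


def simulate_study(cfg: StudyConfig | None = None, master_seed: int = 0) -> Study:
    """Simulate a full multi-subject study with shared ground-truth maps.

    Per-subject random effects are drawn once per subject; per-scan seeds
    derive deterministically from ``master_seed``.  Network maps and subject
    effects depend only on ``master_seed`` (not on the mode), so a
    replication study simulated with the same seed re-scans the same
    subjects — same brains, same network geometry — with fresh scan noise,
    mirroring a follow-up session in the same cohort.
    """
    if cfg is None:
        cfg = StudyConfig()
    ss = np.random.SeedSequence(master_seed)
    maps_seed, effects_seed, _ = ss.spawn(3)
    scans_seed = np.random.SeedSequence(
        [master_seed, 101 if cfg.mode == "replication" else 100]
    )

    paradigms = default_paradigms(
        include_hypercapnia=(cfg.mode == "hypercapnia"), dt_s=DEFAULT_DT_S
    )
    hrf = canonical_hrf(DEFAULT_DT_S)
    mask = ellipsoid_mask(cfg.grid)

    # one x-slab per network pair keeps different pairs spatially disjoint;
    # boundaries chosen so each slab holds ~equal mask volume (the ellipsoid
    # caps are thin, so equal-width slabs would starve the outer networks)
    colvol = mask.sum(axis=(1, 2)).cumsum()
    total = colvol[-1]
    b1 = int(np.searchsorted(colvol, total / 3)) + 1
    b2 = int(np.searchsorted(colvol, 2 * total / 3)) + 1
    slabs = [(0, b1), (b1, b2), (b2, cfg.grid[0])]
    true_pairs = [(f"{s.label}_neural", f"{s.label}_vascular", s.label)
                  for s in cfg.pair_specs]
    # joint placement of all pairs can wedge for unlucky draws; retry the
    # whole layout with fresh derived seeds before giving up
    last_exc = None
    for attempt_seed in maps_seed.spawn(10):
        maps, true_dice, centers, placed = {}, {}, {}, []
        pair_seeds = attempt_seed.spawn(len(cfg.pair_specs))
        try:
            for spec, slab, pseed in zip(cfg.pair_specs, slabs, pair_seeds):
                n_map, v_map, dice, ctr = make_network_pair_maps(
                    spec, cfg.grid, pseed, mask=mask, region_x=slab,
                    sigma_vox=cfg.blob_sigma_vox, avoid_centers=tuple(placed),
                )
                placed.extend(ctr["shared"] + ctr["neural_unique"]
                              + ctr["vascular_unique"])
                maps[f"{spec.label}_neural"] = n_map
                maps[f"{spec.label}_vascular"] = v_map
                true_dice[spec.label] = dice
                centers[f"{spec.label}"] = ctr
        except ValidationError as exc:
            last_exc = exc
            continue
        break
    else:
        raise ValidationError(
            f"network node placement failed after 10 layout attempts: {last_exc}"
        )

    erng = np.random.default_rng(effects_seed)
    subject_effects = []
    for sid in range(cfg.n_subjects):
        subject_effects.append({
            "amp_scale": float(np.clip(1 + cfg.subject_amp_sd * erng.standard_normal(),
                                       0.3, None)),
            "cvr_scale": float(np.clip(1 + cfg.subject_amp_sd * erng.standard_normal(),
                                       0.3, None)),
            "co2_baseline_mmHg": float(40.0 + 3.0 * erng.standard_normal()),
        })

    scan_seeds = scans_seed.spawn(cfg.n_subjects * cfg.n_scans_per_subject)
    scans = []
    i = 0
    for sid in range(cfg.n_subjects):
        for scid in range(cfg.n_scans_per_subject):
            sp = dict(subject_effects[sid], subject_id=sid, scan_id=scid, mask=mask)
            scans.append(simulate_scan(cfg, paradigms, hrf, maps, sp,
                                       scan_seeds[i]))
            i += 1

    truth = GroundTruth(
        spatial_maps=maps,
        true_pairs=true_pairs,
        true_dice=true_dice,
        node_centers=centers,
        noise_params={"noise_sd": cfg.noise_sd, "drift_sd": cfg.drift_sd,
                      "s0": cfg.s0},
    )
    return Study(mode=cfg.mode, scans=scans, paradigms=paradigms, hrf=hrf,
                 ground_truth=truth, config=cfg, mask=mask)


def write_study(study: Study, outdir) -> dict:
    """Write scans as NIfTI, gas traces as text, paradigms as YAML + manifest."""
    from pathlib import Path

    import nibabel as nib

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"mode": study.mode, "n_scans": len(study.scans), "scans": []}
    nib.save(nib.Nifti1Image(study.mask.astype(np.uint8), np.eye(4)),
             str(out / "mask.nii.gz"))
    for nm, par in study.paradigms.items():
        paradigm_to_yaml(par, out / f"paradigm_{nm}.yaml")
    np.savez(out / "ground_truth_maps.npz",
             **{k: v for k, v in study.ground_truth.spatial_maps.items()})
    for scan in study.scans:
        stem = f"sub-{scan.subject_id:02d}_scan-{scan.scan_id}"
        try:
            save_bold(scan.bold, out / f"{stem}_bold.nii.gz")
            save_raw_trace(scan.raw_gas, out / f"{stem}_co2.tsv")
        except OSError as exc:
            raise OSError(f"failed writing scan files for {stem}: {exc}") from exc
        manifest["scans"].append({
            "subject_id": scan.subject_id,
            "scan_id": scan.scan_id,
            "bold": f"{stem}_bold.nii.gz",
            "co2_trace": f"{stem}_co2.tsv",
        })
    manifest["true_dice"] = study.ground_truth.true_dice
    cfg = asdict(study.config)
    cfg["pair_specs"] = [asdict(s) for s in study.config.pair_specs]
    manifest["config"] = cfg
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
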
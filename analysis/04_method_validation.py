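"""Method validation: oracles, statistical calibration, physio round-trip.

Checks the numerical core against independent references: dual regression
vs an explicit normal-equations solve, normalized R2 vs its closed form on
orthogonal designs, Dice identities, type-I error rates of the Monte-Carlo
Lilliefors and paired t tests, and recovery of the hypercapnia end-tidal
envelope from simulated capnograph traces.
"""

import json
from pathlib import Path

import numpy as np
from scipy import stats as sps

from neurovasc.identify import BinaryMask, dice_coefficient
from neurovasc.paradigm import default_paradigms
from neurovasc.physio import extract_end_tidal, simulate_capnograph
from neurovasc.preprocess import BOLDDataset
from neurovasc.stats import dual_regression_timeseries, lilliefors, normalized_r2
from neurovasc.synthetic import _smooth_exp

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    checks = {}

    grid = (8, 8, 5)
    nvox = int(np.prod(grid))
    worst = 0.0
    for s in range(50):
        rng = np.random.default_rng(s)
        maps = rng.standard_normal((4, nvox))
        X = rng.standard_normal((30, nvox))
        ds = BOLDDataset(data=X.T.reshape(grid + (30,)), tr_s=2.0,
                         units="percent_bold", mask=np.ones(grid, bool))
        ts = dual_regression_timeseries(ds, maps)
        G = np.column_stack([np.ones(nvox), maps.T])
        oracle = np.linalg.solve(G.T @ G, G.T @ X.T).T[:, 1:]
        worst = max(worst, float(np.max(np.abs(ts - oracle))))
    checks["dual_regression_vs_normal_equations_max_error"] = worst
    print(f"dual regression vs normal equations (50 draws): "
          f"max |error| = {worst:.2e}")

    rng = np.random.default_rng(0)
    raw = rng.standard_normal((150, 3))
    q, _ = np.linalg.qr(raw - raw.mean(0))
    x, y, z = q.T
    worst = 0.0
    for a, b in [(1.0, 2.0), (0.2, 0.9), (5.0, 0.1)]:
        ts = a * x + b * y
        expected = a**2 * x.var() / (a**2 * x.var() + b**2 * y.var())
        worst = max(worst, abs(normalized_r2(ts, x, [x, y, z]) - expected))
    checks["normalized_r2_vs_closed_form_max_error"] = worst
    print(f"normalized R2 vs closed form: max |error| = {worst:.2e}")

    g = np.ones((10, 10, 10), bool)
    c = np.zeros(1000, bool); c[[0, 1]] = True
    d = np.zeros(1000, bool); d[[1, 2]] = True
    checks["dice_2_2_1"] = dice_coefficient(BinaryMask.from_flat(c, g),
                                            BinaryMask.from_flat(d, g))
    print(f"Dice 2/2/1 identity: {checks['dice_2_2_1']}")

    rng = np.random.default_rng(123)
    rej = sum(lilliefors(rng.standard_normal(30), n_mc=10_000, seed=7)[1] < 0.05
              for _ in range(1000))
    checks["lilliefors_type1_rate"] = rej / 1000
    print(f"Lilliefors type-I rate at alpha 0.05: {rej / 1000:.3f}")

    diffs = np.random.default_rng(456).normal(0, 0.1, size=(2000, 30))
    _, p = sps.ttest_1samp(diffs, 0.0, axis=1)
    checks["paired_t_type1_rate"] = float(np.mean(p < 0.05))
    print(f"paired-t type-I rate at alpha 0.05: {checks['paired_t_type1_rate']:.3f}")

    par = default_paradigms()["hypercapnia"]
    fine = 40.0 + 5.0 * _smooth_exp(par.timecourse, 8.0, 0.1)
    t25 = np.arange(0, 660, 1 / 25.0)
    env = np.interp(t25, np.arange(6600) * 0.1, fine)
    errs = []
    for s in range(20):
        rawg = simulate_capnograph(env, seed=s)
        trace = extract_end_tidal(rawg, grid_t_s=np.arange(0, 660, 2.0))
        ref = np.interp(trace.grid_t_s, t25, env)
        errs.append(float(np.sqrt(np.mean((trace.grid_values - ref) ** 2))))
    checks["petco2_roundtrip_rmse_mmHg"] = float(np.mean(errs))
    print(f"end-tidal extraction round-trip RMSE (20 seeds): "
          f"{np.mean(errs):.3f} mmHg")

    with open(RESULTS / "method_checks.json", "w") as fh:
        json.dump(checks, fh, indent=2)
    print(f"wrote {RESULTS / 'method_checks.json'}")


if __name__ == "__main__":
    main()
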
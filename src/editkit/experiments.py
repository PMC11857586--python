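"""Benchmark experiments for the pipeline's statistical guarantees.

Each experiment fixes its own study conditions and returns measured
quantities; nothing here asserts, so the same code backs both the test
suite and the acceptance script.

Conditions:

* Null calibration: 2000 NB features, two conditions x 3 replicates,
  per-feature means lognormal(log 30, 0.6), dispersion alpha = 0.05,
  no condition effect.
* FDR control: 1000 NB features per seed, 10% alternates at
  |log2FC| = 1.5, pooled false discovery proportion across seeds.
* Power: 2000 editing sites at per-sample depth exactly 30, alt reads
  binomial; 15% of sites shift 0.2 <-> 0.5 between conditions, the
  rest sit at a Beta(2, 2) frequency truncated to the detection band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import diffstats

CONDITIONS = ["control"] * 3 + ["treated"] * 3


def null_calibration(seed: int, n_features: int = 2000) -> dict:
    """NB null: fraction of p below 0.05 and KS uniformity of p-values."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(30), 0.6, size=n_features)
    lam = rng.gamma(1 / 0.05, mu[:, None] * 0.05, size=(n_features, 6))
    counts = pd.DataFrame(rng.poisson(lam))
    res = diffstats.run_differential(counts, CONDITIONS, "control")
    ps = res["pvalue"].dropna().to_numpy()
    return {
        "n": len(ps),
        "frac_p_lt_05": float(np.mean(ps < 0.05)),
        "ks_pvalue": float(stats.kstest(ps, "uniform").pvalue),
    }


def fdr_control(seed: int, n_seeds: int = 20, n_features: int = 1000) -> dict:
    """Pooled empirical false discovery proportion at BH FDR 0.05."""
    false = discoveries = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 * (k + 1))
        alt = np.zeros(n_features, bool)
        alt[: n_features // 10] = True
        mu = rng.lognormal(np.log(30), 0.6, size=n_features)
        shift = np.where(rng.random(n_features) < 0.5, 1.5, -1.5)
        mult = np.where(alt, np.power(2.0, shift), 1.0)
        mu2 = np.column_stack(
            [np.repeat(mu[:, None], 3, 1), np.repeat((mu * mult)[:, None], 3, 1)]
        )
        counts = pd.DataFrame(rng.poisson(rng.gamma(1 / 0.05, mu2 * 0.05)))
        res = diffstats.run_differential(counts, CONDITIONS, "control")
        called = (res["call"] != "ns").to_numpy()
        false += int((called & ~alt).sum())
        discoveries += int(called.sum())
    return {
        "n": n_seeds * n_features,
        "false_discoveries": false,
        "discoveries": discoveries,
        "fdp": false / discoveries if discoveries else 0.0,
    }


def power_planted_shifts(
    seed: int,
    n_sites: int = 2000,
    depth: int = 30,
    frac_shifted: float = 0.15,
    freq_low: float = 0.2,
    freq_high: float = 0.5,
) -> dict:
    """Detection rate of frequency shifts 0.2 <-> 0.5 at site depth 30, 3v3."""
    rng = np.random.default_rng(seed)
    n_shift = int(round(frac_shifted * n_sites))
    shifted = np.zeros(n_sites, bool)
    shifted[:n_shift] = True
    base = np.clip(rng.beta(2, 2, n_sites), 0.10, 1.0)
    up = rng.random(n_sites) < 0.5
    f_ctrl = np.where(shifted, np.where(up, freq_low, freq_high), base)
    f_trt = np.where(shifted, np.where(up, freq_high, freq_low), base)
    f = np.column_stack(
        [np.repeat(f_ctrl[:, None], 3, 1), np.repeat(f_trt[:, None], 3, 1)]
    )
    counts = pd.DataFrame(rng.binomial(depth, f))
    res = diffstats.run_differential(counts, CONDITIONS, "control")
    detected = (res.loc[shifted.nonzero()[0], "call"] != "ns").mean()
    return {"n": n_shift, "power": float(detected)}


def caller_recovery(truth_sites: pd.DataFrame, called_sites: pd.DataFrame) -> dict:
    """Sensitivity (planted frequency >= 0.2) and precision vs the truth."""
    called = set(
        zip(called_sites["chrom"], called_sites["pos"], called_sites["alt"])
    )
    planted = set(
        zip(truth_sites["chrom"], truth_sites["pos"], truth_sites["alt"])
    )
    high = truth_sites[
        truth_sites[["freq_control", "freq_treated"]].max(axis=1) >= 0.2
    ]
    high_keys = set(zip(high["chrom"], high["pos"], high["alt"]))
    tp_high = len(called & high_keys)
    tp = len(called & planted)
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "n_planted_high": len(high_keys),
        "sensitivity_high": tp_high / len(high_keys) if high_keys else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
    }
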
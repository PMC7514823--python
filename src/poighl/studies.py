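"""Packaged application datasets, synthetic-data generation, and the
Monte-Carlo studies assessing estimator quality at configurable scale.

Replicate streams are spawned deterministically from a study seed with the
replicate index mixed into the seed sequence, so partial reruns are stable.
Default replication is 1000 (full-scale 10,000-replicate runs are available
by passing ``reps``); inside replicates the fits are warm-started at the
generating parameters, which is the standard device for keeping large
recovery studies affordable without changing the estimator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import fit_mle
from .params import PoiGHLParams
from .stress_strength import fit_ss, reliability_integral

__all__ = [
    "Dataset",
    "DATASET_NAMES",
    "load_dataset",
    "generate_synthetic",
    "MLESimConfig",
    "SSSimConfig",
    "SimulationReport",
    "mle_simulation",
    "ss_simulation",
]

DATASET_NAMES = (
    "bladder_cancer_128",
    "mechanical_20",
    "software_34",
    "fibers_20mm",
    "fibers_50mm",
)


@dataclass(frozen=True)
class Dataset:
    name: str
    values: np.ndarray
    expected_n: int
    units: str
    source: str
    checksum: str


def load_dataset(name: str) -> Dataset:
    """Load one of the packaged application datasets, verifying its count
    and checksum against the manifest."""
    if name not in DATASET_NAMES:
        raise ValueError(f"unknown dataset {name!r}; available: {DATASET_NAMES}")
    pkg = resources.files("poighl") / "data"
    manifest = json.loads((pkg / "manifest.json").read_text())
    meta = manifest[name]
    text = (pkg / f"{name}.txt").read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != meta["sha256"]:
        raise RuntimeError(f"dataset {name} failed its integrity check")
    values = np.array([float(line) for line in text.split()])
    if values.size != meta["n"]:
        raise RuntimeError(
            f"dataset {name}: {values.size} values but manifest says {meta['n']}"
        )
    if np.any(values <= 0):
        raise RuntimeError(f"dataset {name} contains nonpositive values")
    return Dataset(
        name=name, values=values, expected_n=meta["n"], units=meta["units"],
        source=meta["source"], checksum=digest,
    )


def _rep_seed(seed: int, rep: int) -> np.random.SeedSequence:
    # rep 0 reuses the bare seed so it reproduces the core sample() stream
    if rep == 0:
        return np.random.SeedSequence(seed)
    return np.random.SeedSequence(entropy=seed, spawn_key=(rep,))


def generate_synthetic(
    params,
    n,
    seed: int,
    rep: int = 0,
):
    """Draw synthetic PoiGHL data for study configurations.

    One-sample mode: ``params`` is a :class:`PoiGHLParams` and ``n`` an int.
    Two-sample (stress-strength) mode: ``params`` is ``(a1, a2, lam)`` and
    ``n`` is ``(n, m)``; the two streams are independent substreams of the
    replicate seed.  Returns the sample (or pair) together with the
    generating parameters.
    """
    ss = _rep_seed(seed, rep)
    if isinstance(params, PoiGHLParams):
        rng = np.random.Generator(np.random.Philox(ss))
        u = np.clip(rng.random(int(n)), 1e-300, 1 - 1e-16)
        from .distribution import quantile

        return np.asarray(quantile(u, params)), params
    a1, a2, lam = params
    n1, n2 = n
    child1, child2 = ss.spawn(2)
    from .distribution import quantile

    p1 = PoiGHLParams(1.0, lam, a1)
    p2 = PoiGHLParams(1.0, lam, a2)
    rng1 = np.random.Generator(np.random.Philox(child1))
    rng2 = np.random.Generator(np.random.Philox(child2))
    x = np.asarray(quantile(np.clip(rng1.random(int(n1)), 1e-300, 1 - 1e-16), p1))
    y = np.asarray(quantile(np.clip(rng2.random(int(n2)), 1e-300, 1 - 1e-16), p2))
    return (x, y), (a1, a2, lam)


@dataclass(frozen=True)
class MLESimConfig:
    """Parameter-recovery study design: true parameter triples crossed with
    sample sizes, ``reps`` replicates each."""

    thetas: Sequence[tuple[float, float, float]] = ((1.0, 1.0, 1.0),)
    n_grid: Sequence[int] = (30, 50, 100, 150, 200, 300)
    reps: int = 1000
    seed: int = 0


@dataclass(frozen=True)
class SSSimConfig:
    """Stress-strength recovery design over (n, m) pairs."""

    configs: Sequence[tuple[float, float, float]] = ((1.5, 0.5, 1.9),)
    nm_grid: Sequence[tuple[int, int]] = ((20, 20), (30, 20), (30, 40), (50, 50))
    reps: int = 1000
    seed: int = 0


@dataclass
class SimulationReport:
    config: object
    table: pd.DataFrame
    n_failures: int = 0

    def __post_init__(self) -> None:
        total = getattr(self.config, "reps", 0) * max(1, len(self.table))
        if total and self.n_failures / total > 0.02:
            raise RuntimeError(
                f"{self.n_failures} replicate fits failed (> 2% of {total})"
            )


def mle_simulation(config: MLESimConfig) -> SimulationReport:
    """Bias / sd / MSE of the PoiGHL MLEs over the configured grid."""
    if config.reps < 1:
        raise ValueError("reps must be positive")
    rows = []
    failures = 0
    rep_counter = 0
    for n in config.n_grid:
        for theta in config.thetas:
            p_true = PoiGHLParams(*theta)
            est = np.empty((config.reps, 3))
            got = 0
            for r in range(config.reps):
                data, _ = generate_synthetic(p_true, n, config.seed, rep_counter)
                rep_counter += 1
                try:
                    fit = fit_mle(data, "poighl", starts=[theta])
                    est[got] = fit.theta()
                    got += 1
                except Exception:
                    failures += 1
            e = est[:got]
            mean = e.mean(axis=0)
            sd = e.std(axis=0, ddof=1)
            bias = mean - np.asarray(theta)
            mse = np.mean((e - np.asarray(theta)) ** 2, axis=0)
            row = {"n": n, "alpha": theta[0], "lam": theta[1], "a": theta[2]}
            for i, name in enumerate(("alpha", "lam", "a")):
                row[f"mean_{name}"] = mean[i]
                row[f"sd_{name}"] = sd[i]
                row[f"bias_{name}"] = bias[i]
                row[f"mse_{name}"] = mse[i]
            rows.append(row)
    return SimulationReport(config=config, table=pd.DataFrame(rows), n_failures=failures)


def ss_simulation(config: SSSimConfig) -> SimulationReport:
    """R-hat recovery: bias, MSE, mean delta-method variance, and the average
    95% confidence-interval length (ALCI) over the (n, m) grid."""
    if config.reps < 1:
        raise ValueError("reps must be positive")
    rows = []
    failures = 0
    rep_counter = 0
    for (n, m) in config.nm_grid:
        for (a1, a2, lam) in config.configs:
            r_true = reliability_integral(a1, a2, lam)
            r_hats = np.empty(config.reps)
            alci = np.empty(config.reps)
            var_r = np.empty(config.reps)
            got = 0
            for r in range(config.reps):
                (x, y), _ = generate_synthetic((a1, a2, lam), (n, m), config.seed, rep_counter)
                rep_counter += 1
                try:
                    fit = fit_ss(x, y, starts=[(a1, a2, lam)])
                    r_hats[got] = fit.R_hat
                    var_r[got] = fit.var_R
                    alci[got] = 2.0 * 1.959963984540054 * np.sqrt(max(fit.var_R, 0.0))
                    got += 1
                except Exception:
                    failures += 1
            rh = r_hats[:got]
            rows.append(
                {
                    "n": n, "m": m, "a1": a1, "a2": a2, "lam": lam,
                    "R_true": r_true,
                    "R_hat_mean": rh.mean(),
                    "bias": rh.mean() - r_true,
                    "mse": np.mean((rh - r_true) ** 2),
                    "var_R_mean": var_r[:got].mean(),
                    "alci": alci[:got].mean(),
                }
            )
    return SimulationReport(config=config, table=pd.DataFrame(rows), n_failures=failures)
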
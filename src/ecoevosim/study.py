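"""Scaled-down replicate experiments.

The proof-of-concept scenario (1000x1000 regions, 5e6 iterations, 1000
surviving replicates) is far beyond a desktop budget; the packaged study
runs the same process on an 8x8 torus for 6e4 iterations and launches
replicates until a target number survive.  All replicate seeds derive from
one master seed, so the whole study is reproducible from a single integer.

The study reports the quantities the framework's headline analyses rest on:
the speciation-extinction balance (Pearson correlation, across surviving
replicates, of each replicate's mean per-iteration speciation and
extinction rates; a per-iteration pooled correlation is also exposed), the
pooled distribution of closed species lifetimes, and the fraction of
launched replicates in which life fails to establish early.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .config import SimulationConfig
from .engine import run

STUDY_GRID = 8
STUDY_ITERATIONS = 60_000


def study_config(seed: int, **overrides) -> SimulationConfig:
    """The scaled-down general-scenario configuration for one replicate."""
    base = dict(
        d1=STUDY_GRID, d2=STUDY_GRID,
        iterations=STUDY_ITERATIONS,
        seed=int(seed) & 0x7FFFFFFF,
        log_population_events=False,  # species-level bookkeeping suffices
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class ReplicateResult:
    seed: int
    survived: bool
    summary: dict
    rates: object | None = None        # rate-series DataFrame (survivors only)
    lifetimes: object | None = None    # lifetime table DataFrame


@dataclass
class StudyResult:
    replicates: list = field(default_factory=list)
    launched: int = 0
    survivors: int = 0

    @property
    def early_extinct_fraction(self) -> float:
        return 1.0 - self.survivors / max(self.launched, 1)

    def pooled_rates(self):
        spec, ext = [], []
        for rep in self.replicates:
            if rep.survived and rep.rates is not None:
                spec.append(rep.rates["speciation_rate"].to_numpy())
                ext.append(rep.rates["extinction_rate"].to_numpy())
        if not spec:
            return np.array([]), np.array([])
        return np.concatenate(spec), np.concatenate(ext)

    def pooled_rate_correlation(self) -> tuple:
        """Pearson r between speciation and extinction rates, pooled over all
        (replicate, iteration) points with a defined denominator."""
        s, e = self.pooled_rates()
        m = np.isfinite(s) & np.isfinite(e)
        return metrics.pearson(s[m], e[m]), int(m.sum())

    def replicate_mean_rates(self):
        """Per-replicate mean speciation and extinction rates (survivors)."""
        spec, ext = [], []
        for rep in self.replicates:
            if rep.survived and rep.rates is not None:
                spec.append(float(np.nanmean(rep.rates["speciation_rate"])))
                ext.append(float(np.nanmean(rep.rates["extinction_rate"])))
        return np.array(spec), np.array(ext)

    def rate_correlation_across_replicates(self) -> tuple:
        """Pearson r between per-simulation mean speciation and extinction
        rates, one point per surviving replicate — the balance statistic the
        full-scale analysis reports across simulations."""
        s, e = self.replicate_mean_rates()
        return metrics.pearson(s, e), int(s.size)

    def pooled_closed_lifetimes(self) -> np.ndarray:
        out = []
        for rep in self.replicates:
            if rep.survived and rep.lifetimes is not None:
                t = rep.lifetimes
                out.append(t.loc[~t["censored"], "lifetime"].to_numpy())
        return np.concatenate(out) if out else np.array([])


def run_replicate(seed: int, keep_series: bool = True, **overrides) -> ReplicateResult:
    cfg = study_config(seed, **overrides)
    result = run(cfg)
    survived = not result.summary["total_extinction"]
    rates = lifetimes = None
    if survived and keep_series:
        rates = metrics.rate_series(result.events, result.state.iteration)
        lifetimes = metrics.lifetime_table(result.events, result.state.iteration)
    return ReplicateResult(cfg.seed, survived, result.summary, rates, lifetimes)


def replicate_study(
    seed: int,
    target_survivors: int = 10,
    max_launches: int = 250,
    progress=None,
    **overrides,
) -> StudyResult:
    """Launch replicates (seeds spawned from ``seed``) until
    ``target_survivors`` complete their full run with extant life."""
    child_seeds = np.random.SeedSequence(seed).generate_state(max_launches)
    study = StudyResult()
    for s in child_seeds:
        rep = run_replicate(int(s), **overrides)
        study.replicates.append(rep)
        study.launched += 1
        if rep.survived:
            study.survivors += 1
        if progress is not None:
            progress(study, rep)
        if study.survivors >= target_survivors:
            break
    return study
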
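"""Post-hoc statistics over event logs and final states: richness and rate
series, correlations and correlograms, species lifetime distributions, niche
occupancy, allele-frequency drift tracks and Newick export of the emergent
species tree.

Rates are defined per iteration as event counts divided by the number of
extant species at the previous iteration (configurable denominator), so the
richness recurrence richness(t) = richness(t-1) + originations(t) -
extinctions(t) holds exactly against every engine log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import EXTINCTION, ORIGINATION


# ---------------------------------------------------------------------------
# Rate series
# ---------------------------------------------------------------------------

def _species_event_counts(events, total_iterations):
    orig = np.zeros(total_iterations + 1, dtype=np.int64)
    ext = np.zeros(total_iterations + 1, dtype=np.int64)
    for it, kind, _subject, info in events:
        if kind == ORIGINATION:
            orig[it] += 1
        elif kind == EXTINCTION and info[2]:  # a species lost its last member
            ext[it] += 1
    return orig, ext


def rate_series(
    events: list, total_iterations: int, denominator: str = "previous"
) -> pd.DataFrame:
    """Per-iteration richness and speciation / extinction rates.

    ``denominator`` selects the rate normalisation: ``previous`` (extant
    species at t-1, the default), ``current`` (at t) or ``events``
    (raw counts).  Rates are NaN where the denominator is zero.
    """
    orig, ext = _species_event_counts(events, total_iterations)
    richness = np.cumsum(orig - ext)
    t = np.arange(total_iterations + 1)
    if denominator == "previous":
        denom = np.concatenate([[np.nan], richness[:-1]]).astype(float)
    elif denominator == "current":
        denom = richness.astype(float)
    elif denominator == "events":
        denom = np.ones(total_iterations + 1)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    denom[denom == 0] = np.nan
    df = pd.DataFrame({
        "iteration": t,
        "richness": richness,
        "originations": orig,
        "extinctions": ext,
        "speciation_rate": orig / denom,
        "extinction_rate": ext / denom,
    })
    return df.iloc[1:].reset_index(drop=True)  # t = 0 is founding, not a rate


def smooth_rates(series: pd.DataFrame, window: int = 200) -> pd.DataFrame:
    """Moving average of the rate columns over ``window`` iterations."""
    out = series.copy()
    for col in ("speciation_rate", "extinction_rate"):
        out[col] = out[col].rolling(window, min_periods=1).mean()
    return out


def pearson(x, y) -> float:
    """Pearson correlation with pairwise deletion; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 3:
        return math.nan
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return math.nan
    return float(xc @ yc) / (sx * sy)


def autocorrelogram(x, max_lag: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.array([pearson(x[:-k], x[k:]) for k in range(1, max_lag + 1)])


def rate_statistics(series: pd.DataFrame, max_lag: int = 20) -> dict:
    """Speciation-extinction coupling and temporal-dependence diagnostics.

    Returns the Pearson correlation between the two rates, autocorrelograms
    for each rate at lags 1..max_lag, and the correlation of each rate with
    the per-iteration diversification change (d richness).
    """
    s = series["speciation_rate"].to_numpy()
    e = series["extinction_rate"].to_numpy()
    drich = np.diff(series["richness"].to_numpy(), prepend=np.nan)
    return {
        "speciation_extinction_r": pearson(s, e),
        "speciation_autocorr": autocorrelogram(s, max_lag),
        "extinction_autocorr": autocorrelogram(e, max_lag),
        "speciation_diversification_r": pearson(s, drich),
        "extinction_diversification_r": pearson(e, drich),
        "n_points": int(np.isfinite(s).sum()),
    }


# ---------------------------------------------------------------------------
# Lifetimes
# ---------------------------------------------------------------------------

def lifetime_table(events: list, run_length: int) -> pd.DataFrame:
    """Per-species birth, extinction (or censoring at run end) and lifetime."""
    birth, death = {}, {}
    for it, kind, subject, info in events:
        if kind == ORIGINATION:
            birth[subject] = it
        elif kind == EXTINCTION and info[2]:
            death[info[1]] = it
    rows = []
    for sid in sorted(birth):
        b = birth[sid]
        d = death.get(sid)
        rows.append({
            "species_id": sid,
            "birth": b,
            "extinction": d if d is not None else np.nan,
            "censored": d is None,
            "lifetime": (d - b) if d is not None else (run_length - b),
        })
    return pd.DataFrame(rows)


def lifetime_distribution(events: list, run_length: int, bins: int = 50):
    """Lifetime table plus a histogram of *closed* (uncensored) lifetimes.

    Extant species only bound their duration from below, so they are kept in
    the table (flagged) but excluded from the closed histogram.
    """
    table = lifetime_table(events, run_length)
    closed = table.loc[~table["censored"], "lifetime"].to_numpy()
    if closed.size:
        hist, edges = np.histogram(closed, bins=bins)
    else:
        hist, edges = np.zeros(bins, dtype=np.int64), np.linspace(0, 1, bins + 1)
    return table, (hist, edges)


# ---------------------------------------------------------------------------
# Niche occupancy
# ---------------------------------------------------------------------------

@dataclass
class OccupancySummary:
    per_region: dict          # region id -> frozenset of occupied positions
    position_fraction: np.ndarray  # fraction of regions occupying each position
    full_fraction: float      # fraction of regions with every position occupied
    vacancy_fraction: dict    # non-full regions -> fraction of positions vacant


def niche_occupancy(state, niche_bits: int = 8) -> OccupancySummary:
    """Occupied niche positions per region at the end of a run.

    A position p in [0, 2**niche_bits) counts as occupied in a region when at
    least one resident population sits at n = p.
    """
    n_positions = 1 << niche_bits
    per_region = {rid: set() for rid in state.grid.regions}
    for pop in state.populations.values():
        if 0 <= pop.niche.n < n_positions:
            per_region[pop.region_id].add(pop.niche.n)
    counts = np.zeros(n_positions, dtype=np.int64)
    full = 0
    vacancy = {}
    n_regions = len(per_region)
    for rid, occ in per_region.items():
        for p in occ:
            counts[p] += 1
        if len(occ) == n_positions:
            full += 1
        else:
            vacancy[rid] = 1.0 - len(occ) / n_positions
    return OccupancySummary(
        per_region={rid: frozenset(v) for rid, v in per_region.items()},
        position_fraction=counts / max(n_regions, 1),
        full_fraction=full / max(n_regions, 1),
        vacancy_fraction=vacancy,
    )


# ---------------------------------------------------------------------------
# Allele-frequency drift tracks
# ---------------------------------------------------------------------------

GENE_CLASSES = ("fitness_influencing", "expressed_non_fitness", "non_expressed")


def allele_frequency_tracks(genotype_samples: list, species_id: int) -> pd.DataFrame:
    """Modal-allele frequency per gene class over time for one species.

    ``genotype_samples`` is the engine's sampled record: tuples
    (iteration, species_id, gene classes, per-population packed allele
    bytes).  For every sampled iteration the modal 8-bit allele frequency is
    computed per phenotypic gene and averaged within each gene class; a
    class with no genes yields NaN.
    """
    rows = []
    for it, sid, classes, alleles in genotype_samples:
        if sid != species_id:
            continue
        npop = len(alleles)
        if npop == 0:
            continue
        mat = np.frombuffer(b"".join(alleles), dtype=np.uint8).reshape(npop, -1)
        row = {"iteration": it, "n_populations": npop}
        for cls in GENE_CLASSES:
            idx = [g for g, c in enumerate(classes) if c == cls]
            if not idx:
                row[cls] = np.nan
                continue
            freqs = []
            for g in idx:
                _vals, cnt = np.unique(mat[:, g], return_counts=True)
                freqs.append(cnt.max() / npop)
            row[cls] = float(np.mean(freqs))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def export_newick(species_rows: list, run_length: int) -> str:
    """Serialize the recorded species ancestry as a rooted Newick tree.

    Each speciation inserts an internal node on the parent's branch at the
    child's birth; branch lengths are iterations.  Extinct species carry an
    ``_x`` suffix; extant species are censored at ``run_length``.
    """
    info = {}
    children = {}
    roots = []
    for row in species_rows:
        sid = int(row["species_id"])
        parent = row["parent_id"]
        parent = None if parent in ("", None) else int(parent)
        ext = row["extinction"]
        ext = None if ext in ("", None) or (isinstance(ext, float) and math.isnan(ext)) else int(ext)
        info[sid] = (int(row["birth"]), ext, parent)
        children.setdefault(sid, [])
        if parent is None:
            roots.append(sid)
    for sid, (birth, _ext, parent) in info.items():
        if parent is not None:
            if parent not in info:
                raise ValueError(f"species {sid} has unknown parent {parent}")
            children[parent].append((birth, sid))
    if len(roots) != 1:
        raise ValueError(f"expected exactly one founder, found {len(roots)}")
    # cycle check: walk each lineage to the root
    for sid in info:
        seen = set()
        cur = sid
        while cur is not None:
            if cur in seen:
                raise ValueError("cyclic ancestry")
            seen.add(cur)
            cur = info[cur][2]
    for sid in children:
        children[sid].sort()

    def label(sid):
        return f"S{sid}_x" if info[sid][1] is not None else f"S{sid}"

    def end(sid):
        ext = info[sid][1]
        return run_length if ext is None else ext

    # children are strictly younger than their parents, so processing species
    # by descending birth guarantees every child's subtree exists already
    sub = {}
    for sid in sorted(info, key=lambda s: (-info[s][0], -s)):
        kids = children[sid]
        birth = info[sid][0]
        last = kids[-1][0] if kids else birth
        text = f"{label(sid)}:{end(sid) - last}"
        for i in range(len(kids) - 1, -1, -1):
            b, cid = kids[i]
            prev = kids[i - 1][0] if i > 0 else birth
            text = f"({text},{sub[cid]}):{b - prev}"
        sub[sid] = text
    root = roots[0]
    return sub[root] + ";\n"
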
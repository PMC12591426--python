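"""Toroidal grid of regions with bit-encoded environmental properties.

The world is a d1 x d2 grid of cells with periodic boundaries; cells are
partitioned into connected *regions*, each carrying ``nenv`` bit-encoded
environmental properties that act as abstract abiotic/biotic factors.
Properties drift stochastically (one random bit of one random property per
event, at a per-region rate drawn once at initialization); adjacent regions
can merge into macro-regions and macro-regions can split back, reshaping
habitat connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Region:
    id: int
    cells: set  # {(i, j), ...}
    properties: np.ndarray  # int64, values in [0, 2**size_property)
    pregionchange: float
    env_version: int = 0
    _neighbors: tuple | None = None  # cached adjacent region ids

    def normalized(self, size_property: int) -> np.ndarray:
        """Properties scaled to [0, 1] (value / (2**bits - 1))."""
        return self.properties / float((1 << size_property) - 1)


class EnvironmentGrid:
    """Cell -> region assignment plus the region registry.

    Adjacency is 4-neighbour (von Neumann) on the torus.  Region geometry is
    static while merge/split are disabled, so neighbour sets and the
    per-region drift-rate vector are cached and only invalidated by
    structural events.
    """

    def __init__(self, d1: int, d2: int, nenv: int, size_property: int):
        if d1 < 1 or d2 < 1:
            raise ValueError("grid dimensions must be positive")
        self.d1, self.d2 = d1, d2
        self.nenv, self.size_property = nenv, size_property
        self.cell_region = np.zeros((d1, d2), dtype=np.int64)
        self.regions: dict = {}
        self.next_region_id = 0
        self._cache = None  # (ids array, pregion vector)

    # -- bookkeeping ---------------------------------------------------------

    def _invalidate(self):
        self._cache = None
        for r in self.regions.values():
            r._neighbors = None

    def region_of(self, cell) -> Region:
        return self.regions[int(self.cell_region[cell])]

    def neighbor_cells(self, cell):
        i, j = cell
        return (
            ((i - 1) % self.d1, j),
            ((i + 1) % self.d1, j),
            (i, (j - 1) % self.d2),
            (i, (j + 1) % self.d2),
        )

    def adjacent_region_ids(self, region: Region) -> tuple:
        if region.id not in self.regions:
            raise KeyError(f"unknown region {region.id}")
        if region._neighbors is None:
            ids = set()
            for cell in region.cells:
                for nb in self.neighbor_cells(cell):
                    rid = int(self.cell_region[nb])
                    if rid != region.id:
                        ids.add(rid)
            region._neighbors = tuple(sorted(ids))
        return region._neighbors

    def _vectors(self):
        if self._cache is None:
            ids = sorted(self.regions)
            rates = np.array([self.regions[i].pregionchange for i in ids])
            self._cache = (ids, rates)
        return self._cache

    def set_pregionchange(self, values):
        """Override every region's drift rate (dict id->rate or scalar)."""
        for rid, region in self.regions.items():
            region.pregionchange = values[rid] if isinstance(values, dict) else values
        self._cache = None

    def snapshot(self) -> str:
        """JSON snapshot (region ids, cells, property integers)."""
        data = {
            "d1": self.d1, "d2": self.d2,
            "nenv": self.nenv, "size_property": self.size_property,
            "regions": [
                {
                    "id": r.id,
                    "cells": sorted(map(list, r.cells)),
                    "properties": [int(v) for v in r.properties],
                    "pregionchange": r.pregionchange,
                }
                for r in sorted(self.regions.values(), key=lambda r: r.id)
            ],
        }
        return json.dumps(data)


def init_environment(
    d1: int,
    d2: int,
    nenv: int,
    size_property: int,
    rng: np.random.Generator,
    pregion_low: float = 0.005,
    pregion_high: float = 0.025,
) -> EnvironmentGrid:
    """One single-cell region per cell; property bits i.i.d. uniform.

    Per-region drift rates are drawn once from U(pregion_low, pregion_high)
    and stay fixed for the run (shocks override them globally).
    """
    grid = EnvironmentGrid(d1, d2, nenv, size_property)
    top = 1 << size_property
    for i in range(d1):
        for j in range(d2):
            rid = grid.next_region_id
            grid.next_region_id += 1
            grid.cell_region[i, j] = rid
            grid.regions[rid] = Region(
                id=rid,
                cells={(i, j)},
                properties=rng.integers(0, top, nenv, dtype=np.int64),
                pregionchange=float(rng.uniform(pregion_low, pregion_high)),
            )
    return grid


def step_environment(
    grid: EnvironmentGrid,
    penvmerge: float,
    penvsplit: float,
    rng: np.random.Generator,
):
    """One environmental update pass; returns a list of structural events.

    (a) each region flips one uniformly chosen bit of one uniformly chosen
    property with its own ``pregionchange``; (b) with ``penvmerge`` per
    region, it absorbs one uniformly chosen adjacent region, each merged
    property taken uniformly from one of the two parents; (c) with
    ``penvsplit`` per macro-region, it splits into two connected cell subsets
    that both retain the parent's properties.  Returns (changed_region_ids,
    structural_events); structural events let the caller remap populations:
    ("merge", kept_id, removed_id) and ("split", parent_id, new_id, moved).
    """
    events = []
    changed = []
    ids, rates = grid._vectors()
    hit = np.flatnonzero(rng.random(len(ids)) < rates)
    for k in hit:
        rid = ids[k]
        region = grid.regions[rid]
        p = int(rng.integers(grid.nenv))
        b = int(rng.integers(grid.size_property))
        region.properties[p] ^= 1 << b
        region.env_version += 1
        changed.append(rid)
    if penvmerge > 0.0:
        for rid in sorted(grid.regions):
            if rid not in grid.regions:
                continue  # absorbed earlier this pass
            if rng.random() >= penvmerge:
                continue
            region = grid.regions[rid]
            nbrs = grid.adjacent_region_ids(region)
            if not nbrs:
                continue
            other = grid.regions[nbrs[int(rng.integers(len(nbrs)))]]
            pick = rng.integers(0, 2, grid.nenv).astype(bool)
            region.properties = np.where(pick, region.properties, other.properties)
            region.cells |= other.cells
            for cell in other.cells:
                grid.cell_region[cell] = region.id
            del grid.regions[other.id]
            region.env_version += 1
            changed.append(region.id)
            grid._invalidate()
            events.append(("merge", region.id, other.id))
    if penvsplit > 0.0:
        for rid in sorted(grid.regions):
            region = grid.regions[rid]
            if len(region.cells) < 2 or rng.random() >= penvsplit:
                continue
            part_a, part_b = _random_bipartition(grid, region, rng)
            new = Region(
                id=grid.next_region_id,
                cells=part_b,
                properties=region.properties.copy(),
                pregionchange=region.pregionchange,
            )
            grid.next_region_id += 1
            region.cells = part_a
            grid.regions[new.id] = new
            for cell in part_b:
                grid.cell_region[cell] = new.id
            grid._invalidate()
            events.append(("split", region.id, new.id, frozenset(part_b)))
    return changed, events


def _random_bipartition(grid, region, rng):
    """Random connected bipartition: cut one edge of a random spanning tree."""
    cells = sorted(region.cells)
    order = rng.permutation(len(cells))
    cellset = set(cells)
    start = cells[int(order[0])]
    # randomized BFS spanning tree
    parent = {start: None}
    frontier = [start]
    while frontier:
        nxt = []
        for cell in frontier:
            nbs = [c for c in grid.neighbor_cells(cell) if c in cellset and c not in parent]
            for c in (nbs[i] for i in rng.permutation(len(nbs))):
                if c not in parent:
                    parent[c] = cell
                    nxt.append(c)
        frontier = nxt
    non_root = [c for c in sorted(parent) if parent[c] is not None]
    cut = non_root[int(rng.integers(len(non_root)))]
    # subtree below the cut edge
    children = {}
    for c, p in parent.items():
        if p is not None:
            children.setdefault(p, []).append(c)
    sub = set()
    stack = [cut]
    while stack:
        c = stack.pop()
        sub.add(c)
        stack.extend(children.get(c, ()))
    return region.cells - sub, sub


def check_partition(grid: EnvironmentGrid) -> None:
    """Audit: regions exactly partition the cells and are torus-connected."""
    seen = {}
    for rid, region in grid.regions.items():
        if not region.cells:
            raise AssertionError(f"region {rid} is empty")
        for cell in region.cells:
            if cell in seen:
                raise AssertionError(f"cell {cell} in two regions")
            seen[cell] = rid
            if int(grid.cell_region[cell]) != rid:
                raise AssertionError(f"cell_region mismatch at {cell}")
        # connectivity
        start = next(iter(region.cells))
        visited = {start}
        stack = [start]
        while stack:
            c = stack.pop()
            for nb in grid.neighbor_cells(c):
                if nb in region.cells and nb not in visited:
                    visited.add(nb)
                    stack.append(nb)
        if visited != region.cells:
            raise AssertionError(f"region {rid} is disconnected")
    if len(seen) != grid.d1 * grid.d2:
        raise AssertionError("cells not fully covered")
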
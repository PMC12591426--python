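"""Population and species bookkeeping: lineage parameters, population
splitting and migration, the species partition (speciation) and the three
extinction routes.

Species are maintained as partitions of reproductively compatible
populations.  Compatibility is pairwise (reproductive distance at or below
the species' threshold) and extended transitively: the species splits into
the connected components of its compatibility graph.  Speciation is
irreversible — once two populations belong to different species they are
never re-merged, however close their genomes drift afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bitgenome import Genotype, hamming_bits, reproductive_distance
from .ecology import NicheState


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


@dataclass
class LineageParams:
    """Per-population rates.

    Mutation rates are re-drawn per population from their uniform ranges.
    The Normal-distributed parameters (gene flow, splitting, migration) carry
    both a lineage *mean*, inherited unchanged from the parent at formation,
    and a realized *value* drawn Normal(mean, sigma) for this population.
    """

    pmutp: float
    pmutr: float
    pmutn: float
    pflowp: float
    pflowr: float
    pflown: float
    ppopsplit: float
    ppopmig: float
    means: tuple = ()  # (pflowp, pflowr, pflown, ppopsplit, ppopmig) means

    @classmethod
    def _draw(cls, means, cfg, rng: np.random.Generator) -> "LineageParams":
        u = rng.random(3)
        z = rng.standard_normal(5)
        pflowp, pflowr, pflown, ppopsplit, ppopmig = means
        return cls(
            pmutp=float(u[0]) * cfg.pmutp_high,
            pmutr=float(u[1]) * cfg.pmutr_high,
            pmutn=float(u[2]) * cfg.pmutn_high,
            pflowp=_clip01(pflowp + float(z[0]) * cfg.pflow_sigma),
            pflowr=_clip01(pflowr + float(z[1]) * cfg.pflow_sigma),
            pflown=_clip01(pflown + float(z[2]) * cfg.pflow_sigma),
            ppopsplit=_clip01(ppopsplit + float(z[3]) * cfg.popsplit_sigma),
            ppopmig=_clip01(ppopmig + float(z[4]) * cfg.popmig_sigma),
            means=tuple(means),
        )

    @classmethod
    def founder(cls, cfg, rng: np.random.Generator) -> "LineageParams":
        means = (cfg.founder_pflowp, cfg.founder_pflowr, cfg.founder_pflown,
                 cfg.founder_ppopsplit, cfg.founder_ppopmig)
        return cls._draw(means, cfg, rng)

    def daughter(self, cfg, rng: np.random.Generator) -> "LineageParams":
        """Uniform-range rates are re-drawn per population; Normal-family
        rates are drawn around the inherited lineage mean."""
        return LineageParams._draw(self.means, cfg, rng)


@dataclass
class SpeciesParams:
    """Species-scope constants, drawn once when the species emerges."""

    th_speciation_bits: float  # reproductive divergence threshold, in bits
    thextrel: float            # NEI collapse threshold (negative)
    thextfit: float
    pexpp: float
    pexpr: float
    pexpn: float

    @classmethod
    def draw(cls, cfg, ngenr_bits: int, rng: np.random.Generator) -> "SpeciesParams":
        frac = float(rng.uniform(cfg.th_speciation_low, cfg.th_speciation_high))
        return cls(
            th_speciation_bits=ngenr_bits * frac,
            thextrel=float(rng.uniform(cfg.thextrel_low, cfg.thextrel_high)),
            thextfit=cfg.thextfit,
            pexpp=cfg.pexpp,
            pexpr=cfg.pexpr,
            pexpn=cfg.pexpn,
        )


@dataclass(slots=True)
class Population:
    id: int
    species_id: int
    region_id: int
    genotype: Genotype
    params: LineageParams
    fitness_fn: object          # grammar.FitnessFunction
    niche: NicheState
    birth: int
    profile: object = None      # grammar.PhenotypeProfile, rebuilt on demand
    trait_values: list | None = None
    fitness: float = 0.0
    nei: float = 0.0
    # cache keys: phenotype dirty flag and the environment version last seen
    phen_dirty: bool = True
    env_seen: int = -1
    region_seen: int = -1
    slot: int = -1  # row in the engine's vectorized per-population arrays
    _niche_mut: object = None  # cached mutable-bit indices of the niche segment


@dataclass
class Species:
    id: int
    parent_id: int | None
    birth: int
    params: SpeciesParams
    members: set = field(default_factory=set)
    extinction: int | None = None
    repro_dirty: bool = True  # re-check the compatibility partition
    repro_index: object = None  # ReproIndex, attached by the engine

    @property
    def extinct(self) -> bool:
        return self.extinction is not None


class ReproIndex:
    """Incremental pairwise reproductive-distance cache for one species.

    Rows hold members' reproductive bits padded with the sentinel 255 up to a
    common width, so a plain element-mismatch count equals aligned-prefix
    Hamming distance plus the surplus-length penalty.  The compatibility
    partition only needs re-checking when an edge of the threshold graph can
    have disappeared: a member left, or an update/lengthening pushed some
    pairwise distance above the threshold.  Births and edge-preserving
    mutations never split a connected graph.
    """

    PAD = 255

    def __init__(self, th_bits: float, rule: str = "pairwise_diameter"):
        self.th = th_bits
        self.rule = rule
        self.ids: list = []
        self.row: dict = {}      # pop id -> row index
        self.width = 0
        self.bits = np.zeros((0, 0), dtype=np.uint8)
        self.dist = np.zeros((0, 0), dtype=np.int32)
        self.need_check = False

    def _ensure_width(self, nbits: int):
        if nbits <= self.width:
            return
        m = len(self.ids)
        grown = np.full((max(m, 4), nbits), self.PAD, dtype=np.uint8)
        grown[:m, : self.width] = self.bits[:m, : self.width]
        self.bits = grown
        self.width = nbits

    def _row_distances(self, row_bits) -> np.ndarray:
        m = len(self.ids)
        if m == 0:
            return np.zeros(0, dtype=np.int32)
        return np.count_nonzero(
            self.bits[:m, : self.width] != row_bits[: self.width], axis=1
        ).astype(np.int32)

    def _padded(self, segment) -> np.ndarray:
        out = np.full(self.width, self.PAD, dtype=np.uint8)
        out[: segment.n_bits] = segment.bits
        return out

    def add(self, pid: int, segment) -> None:
        self._ensure_width(segment.n_bits)
        m = len(self.ids)
        row_bits = self._padded(segment)
        d = self._row_distances(row_bits)
        if m == self.bits.shape[0]:
            grown = np.full((max(2 * m, 4), self.width), self.PAD, dtype=np.uint8)
            grown[:m] = self.bits[:m]
            self.bits = grown
        if m >= self.dist.shape[0]:
            cap = max(2 * m, 4)
            grown = np.zeros((cap, cap), dtype=np.int32)
            grown[:m, :m] = self.dist[:m, :m]
            self.dist = grown
        self.bits[m] = row_bits
        self.dist[m, :m] = d
        self.dist[:m, m] = d
        self.dist[m, m] = 0
        self.ids.append(pid)
        self.row[pid] = m

    def add_clone(self, pid: int, parent_pid: int) -> None:
        """Register a newborn whose reproductive segment is a verbatim copy
        of an existing member's: distances are copied, not recomputed."""
        j = self.row[parent_pid]
        m = len(self.ids)
        if m == self.bits.shape[0]:
            grown = np.full((max(2 * m, 4), self.width), self.PAD, dtype=np.uint8)
            grown[:m] = self.bits[:m]
            self.bits = grown
        if m >= self.dist.shape[0]:
            cap = max(2 * m, 4)
            grown = np.zeros((cap, cap), dtype=np.int32)
            grown[:m, :m] = self.dist[:m, :m]
            self.dist = grown
        self.bits[m] = self.bits[j]
        self.dist[m, :m] = self.dist[j, :m]
        self.dist[:m, m] = self.dist[:m, j]
        self.dist[m, j] = self.dist[j, m] = 0
        self.dist[m, m] = 0
        self.ids.append(pid)
        self.row[pid] = m

    def remove(self, pid: int) -> None:
        i = self.row.pop(pid)
        m = len(self.ids) - 1
        last = self.ids.pop()
        if i != m:  # move the last row into the vacated slot
            self.ids[i] = last
            self.row[last] = i
            self.bits[i] = self.bits[m]
            self.dist[i, : m + 1] = self.dist[m, : m + 1]
            self.dist[: m + 1, i] = self.dist[: m + 1, m]
            self.dist[i, i] = 0
        if self.rule == "connected_components":
            # removals can disconnect the threshold graph; they can never
            # raise the diameter, so the pairwise rule needs no recheck
            self.need_check = True

    def update(self, pid: int, segment) -> None:
        self._ensure_width(segment.n_bits)
        i = self.row[pid]
        row_bits = self._padded(segment)
        self.bits[i] = row_bits
        d = self._row_distances(row_bits)
        m = len(self.ids)
        old = self.dist[i, :m]
        if not self.need_check and np.any((d > self.th) & (old <= self.th)):
            self.need_check = True
        self.dist[i, :m] = d
        self.dist[:m, i] = d
        self.dist[i, i] = 0

    def diameter_partition(self) -> list:
        """Pairwise-divergence partition: while any member pair is beyond the
        threshold, split the group around its two most divergent poles (each
        member joins the nearer pole; ties go to the first pole in id order).
        Returns lists of pop ids."""
        m = len(self.ids)
        if m <= 1:
            return [list(self.ids)] if m else []
        # canonical order: rows sorted by population id, so tie-breaks are
        # identical to the pure reference implementation
        order = sorted(range(m), key=lambda i: self.ids[i])
        ids = [self.ids[i] for i in order]
        D = self.dist[np.ix_(order, order)]
        return _diameter_split(ids, D, self.th)

    def components(self) -> list:
        """Connected components of the threshold graph, as lists of pop ids.

        Vectorized frontier propagation: compatibility graphs are dense
        (members are close relatives), so a handful of whole-matrix boolean
        sweeps reaches the fixpoint.
        """
        m = len(self.ids)
        if m <= 1:
            return [list(self.ids)] if m else []
        adj = self.dist[:m, :m] <= self.th
        unvisited = np.ones(m, dtype=bool)
        out = []
        while True:
            seeds = np.flatnonzero(unvisited)
            if seeds.size == 0:
                break
            comp = np.zeros(m, dtype=bool)
            comp[seeds[0]] = True
            frontier = comp
            while frontier.any():
                reach = adj[frontier].any(axis=0)
                frontier = reach & ~comp & unvisited
                comp |= frontier
            unvisited &= ~comp
            out.append([self.ids[i] for i in np.flatnonzero(comp)])
        return out

    def partition(self) -> list:
        return (self.components() if self.rule == "connected_components"
                else self.diameter_partition())

    @classmethod
    def build(cls, species: "Species", populations: dict,
              rule: str = "pairwise_diameter") -> "ReproIndex":
        idx = cls(species.params.th_speciation_bits, rule)
        for pid in sorted(species.members):
            idx.add(pid, populations[pid].genotype.reproductive)
        return idx


# ---------------------------------------------------------------------------
# Splitting and migration
# ---------------------------------------------------------------------------

def make_child(
    parent: Population,
    child_id: int,
    cfg,
    rng: np.random.Generator,
    adjacent_region_ids,
    iteration: int,
):
    """Build the daughter population of a split event.

    The genotype is deep-copied (reproductive distance 0 at birth), the
    fitness function is inherited unchanged, lineage parameters follow the
    inheritance rules of :class:`LineageParams`, and with ``ppopmig`` the
    child migrates to one uniformly chosen adjacent region (an adjacent
    region always exists on a torus with more than one region).  Returns
    (child, migrated).
    """
    params = parent.params.daughter(cfg, rng)
    region_id = parent.region_id
    migrated = False
    if adjacent_region_ids and rng.random() < parent.params.ppopmig:
        region_id = int(adjacent_region_ids[int(rng.integers(len(adjacent_region_ids)))])
        migrated = True
    child = Population(
        id=child_id,
        species_id=parent.species_id,
        region_id=region_id,
        genotype=parent.genotype.copy(),
        params=params,
        fitness_fn=parent.fitness_fn,
        niche=NicheState(parent.niche.n, parent.niche.c, parent.niche.r),
        birth=iteration,
        profile=parent.profile,          # identical bits -> identical mapping
        trait_values=None,
        fitness=parent.fitness,
        phen_dirty=parent.profile is None,
        _niche_mut=parent._niche_mut,  # identical genome structure at birth
    )
    return child, migrated


def split_population(
    pop: Population,
    next_id: int,
    cfg,
    rng: np.random.Generator,
    adjacent_region_ids=(),
    iteration: int = 0,
):
    """Bernoulli split: with ``ppopsplit`` return (child, migrated), else None."""
    if rng.random() >= pop.params.ppopsplit:
        return None
    return make_child(pop, next_id, cfg, rng, tuple(adjacent_region_ids), iteration)


# ---------------------------------------------------------------------------
# Speciation
# ---------------------------------------------------------------------------

def _pair_distance_bits(a: Population, b: Population, method: str) -> float:
    sa, sb = a.genotype.reproductive, b.genotype.reproductive
    if method == "hamming_normalized":
        return float(hamming_bits(sa, sb))
    # numeric distances are compared on their own scale
    return reproductive_distance(sa, sb, method)


def partition_members(
    species: Species,
    populations: dict,
    method: str = "hamming_normalized",
    rule: str = "pairwise_diameter",
) -> list:
    """Reference partition of a species' members under either rule.

    Builds the pairwise distance matrix directly from the genotypes; the
    engine's incremental :class:`ReproIndex` must agree with this.
    """
    ids = sorted(species.members)
    if len(ids) <= 1:
        return [list(ids)]
    if rule == "connected_components":
        return compatibility_components(species, populations, method)
    th = species.params.th_speciation_bits
    m = len(ids)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = _pair_distance_bits(
                populations[ids[i]], populations[ids[j]], method
            )
    return _diameter_split(ids, D, th)


def _diameter_split(ids: list, D: np.ndarray, th: float) -> list:
    """Recursive diameter bipartition over an id-sorted distance matrix.

    The pole pair is the row-major first maximal entry (lowest id pair among
    ties); members at equal distance to both poles join the lower-id pole.
    """
    out = []
    stack = [np.arange(len(ids))]
    while stack:
        idx = stack.pop()
        if idx.size <= 1:
            out.append([ids[i] for i in idx])
            continue
        sub = D[np.ix_(idx, idx)]
        a, b = divmod(int(np.argmax(sub)), idx.size)
        if sub[a, b] <= th:
            out.append([ids[i] for i in idx])
            continue
        to_a = sub[a] <= sub[b]
        stack.append(idx[to_a])
        stack.append(idx[~to_a])
    return sorted(out, key=lambda grp: min(grp))


def compatibility_components(
    species: Species, populations: dict, method: str = "hamming_normalized"
) -> list:
    """Connected components of the member compatibility graph (edge iff
    reproductive distance <= the species threshold), as lists of pop ids."""
    ids = sorted(species.members)
    th = species.params.th_speciation_bits
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        pa = populations[a]
        for b in ids[i + 1 :]:
            if find(a) == find(b):
                continue
            if _pair_distance_bits(pa, populations[b], method) <= th:
                parent[find(b)] = find(a)
    comps = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    return [comps[r] for r in sorted(comps)]


def update_species_partition(
    species: Species,
    populations: dict,
    current_iteration: int,
    next_species_id: int,
    cfg=None,
    rng: np.random.Generator | None = None,
    method: str = "hamming_normalized",
    components: list | None = None,
    rule: str = "pairwise_diameter",
):
    """Re-partition a species once reproductive divergence crosses threshold.

    Under the default pairwise rule the species splits while any member pair
    exceeds the threshold (groups form around the most divergent poles);
    under ``connected_components`` it splits only into components of the
    compatibility graph.  The group containing the oldest member (earliest
    birth, ties by lowest id) keeps the original species id; every other
    group founds a new species with the original as parent.  New species
    draw fresh species-scope parameters at emergence when ``cfg`` and ``rng``
    are given, otherwise they inherit the parent's.  Returns the list of new
    :class:`Species` (empty if the species stayed whole).
    """
    if len(species.members) < 2:
        return []
    if components is None:
        components = partition_members(species, populations, method, rule)
    if len(components) == 1:
        return []

    def oldest(members):
        return min((populations[i].birth, i) for i in members)

    keep = min(range(len(components)), key=lambda k: oldest(components[k]))
    new_species = []
    sid = next_species_id
    for k, members in enumerate(components):
        if k == keep:
            species.members = set(members)
            continue
        if cfg is not None and rng is not None:
            founder = populations[min(members, key=lambda i: (populations[i].birth, i))]
            params = SpeciesParams.draw(
                cfg, founder.genotype.reproductive.n_bits, rng
            )
        else:
            params = species.params
        sp = Species(
            id=sid,
            parent_id=species.id,
            birth=current_iteration,
            params=params,
            members=set(members),
        )
        for m in members:
            populations[m].species_id = sid
        sid += 1
        new_species.append(sp)
    return new_species


# ---------------------------------------------------------------------------
# Extinction
# ---------------------------------------------------------------------------

FITNESS_ROUTE = "fitness"
NEI_ROUTE = "nei"
NICHE_ROUTE = "niche_mismatch"


def extinction_route(pop: Population, sp_params: SpeciesParams) -> str | None:
    """First matching route in the fixed order fitness -> NEI -> niche mismatch.

    The predicates are independent, so the order affects only the label a
    doomed population gets, never the removal set.
    """
    if pop.fitness < sp_params.thextfit:
        return FITNESS_ROUTE
    if pop.nei < sp_params.thextrel:
        return NEI_ROUTE
    if not (pop.niche.c - pop.niche.r <= pop.niche.n <= pop.niche.c + pop.niche.r):
        return NICHE_ROUTE
    return None


def apply_extinctions(populations: dict, species: dict, iteration: int,
                      candidates=None):
    """Remove doomed populations; mark species extinct when their last member
    dies.  ``candidates`` restricts the scan (the engine pre-screens with
    vectorized predicates; semantics are identical to scanning everything).
    Returns (removed [(pop_id, route, species_id, region_id)],
    extinct_species_ids)."""
    removed = []
    scan = sorted(populations) if candidates is None else sorted(candidates)
    for pid in scan:
        pop = populations[pid]
        route = extinction_route(pop, species[pop.species_id].params)
        if route is not None:
            removed.append((pid, route, pop.species_id, pop.region_id))
    extinct = []
    for pid, _route, sid, _rid in removed:
        del populations[pid]
        sp = species[sid]
        sp.members.discard(pid)
        sp.repro_dirty = True
        if sp.repro_index is not None:
            sp.repro_index.remove(pid)
        if not sp.members and sp.extinction is None:
            sp.extinction = iteration
            extinct.append(sid)
    return removed, extinct
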
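"""Simulation orchestration: founder initialization, the canonical
per-iteration process order, shock scheduling, event logging and seeded
reproducibility.

Each iteration applies, in this fixed order: environment update, mutation,
gene flow, genome expansion, phenotype re-derivation and fitness evaluation,
ecological-network update and NEI, adaptive niche shifts, the three
extinction routes, population splitting and migration, and the speciation
check.  Variation precedes selection; newborn populations are first
evaluated in the iteration after their birth.  All randomness flows through
a single seeded generator in documented draw order, so a run is a pure
function of (config, seed).

Implementation note: the per-population Bernoulli screens (mutation, gene
flow, expansion, splitting, the extinction predicates) are vectorized over a
slot-indexed structure of arrays, and phenotypes are re-derived only for the
traits whose consumed codons overlap bits that actually changed.  Both are
pure optimizations: event semantics and the per-event random draws operate
exactly as the process definitions state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bitgenome as bg
from . import demography as dg
from . import ecology as ec
from . import environment as env
from . import grammar as gr
from .config import SimulationConfig

ORIGINATION = "origination"
EXTINCTION = "extinction"
POPULATION_SPLIT = "population_split"
MIGRATION = "migration"
NICHE_SHIFT = "niche_shift"
GENE_DUPLICATION = "gene_duplication"
SHOCK_START = "shock_start"
SHOCK_END = "shock_end"
TOTAL_EXTINCTION = "total_extinction"


class _Slots:
    """Slot-indexed per-population arrays for the vectorized screens."""

    ROWS = 3  # phenotypic / reproductive / niche rows

    def __init__(self, capacity: int = 256):
        self._alloc(capacity)
        self.free = list(range(capacity - 1, -1, -1))
        self.hi = 0

    def _alloc(self, cap):
        self.capacity = cap
        self.active = np.zeros(cap, dtype=bool)
        self.pid = np.full(cap, -1, dtype=np.int64)
        self.mut_n = np.zeros((3, cap), dtype=np.int64)
        self.mut_p = np.zeros((3, cap))
        self.flow_n = np.zeros((3, cap), dtype=np.int64)
        self.flow_p = np.zeros((3, cap))
        self.pexp = np.zeros((3, cap))
        self.split_p = np.zeros(cap)
        self.fitness = np.ones(cap)
        self.nei = np.zeros(cap)
        self.th_fit = np.full(cap, -1.0)
        self.th_rel = np.full(cap, -np.inf)
        self.nn = np.zeros(cap, dtype=np.int64)
        self.nc = np.zeros(cap, dtype=np.int64)
        self.nr = np.zeros(cap, dtype=np.int64)

    def _grow(self):
        old = self.__dict__.copy()
        cap = self.capacity * 2
        self._alloc(cap)
        for name in ("active", "pid", "split_p", "fitness", "nei",
                     "th_fit", "th_rel", "nn", "nc", "nr"):
            getattr(self, name)[: old["capacity"]] = old[name]
        for name in ("mut_n", "mut_p", "flow_n", "flow_p", "pexp"):
            getattr(self, name)[:, : old["capacity"]] = old[name]
        self.free = list(range(cap - 1, old["capacity"] - 1, -1))

    def acquire(self, pop, sp_params) -> int:
        if not self.free:
            self._grow()
        s = self.free.pop()
        self.hi = max(self.hi, s + 1)
        pop.slot = s
        self.active[s] = True
        self.pid[s] = pop.id
        self.update_genome(s, pop, niche_mut=getattr(pop, "_niche_mut", None))
        p = pop.params
        self.mut_p[:, s] = (p.pmutp, p.pmutr, p.pmutn)
        self.flow_p[:, s] = (p.pflowp, p.pflowr, p.pflown)
        self.split_p[s] = p.ppopsplit
        self.fitness[s] = pop.fitness
        self.nei[s] = pop.nei
        self.set_species_params(s, sp_params)
        self.set_niche(s, pop.niche)
        return s

    def release(self, s: int):
        self.active[s] = False
        self.pid[s] = -1
        self.mut_n[:, s] = 0
        self.mut_p[:, s] = 0.0
        self.flow_n[:, s] = 0
        self.flow_p[:, s] = 0.0
        self.pexp[:, s] = 0.0
        self.split_p[s] = 0.0
        self.fitness[s] = 1.0
        self.nei[s] = 0.0
        self.th_fit[s] = -1.0
        self.th_rel[s] = -np.inf
        self.nn[s] = self.nc[s] = self.nr[s] = 0
        self.free.append(s)

    def update_genome(self, s: int, pop, niche_mut=None):
        g = pop.genotype
        if niche_mut is None:
            niche_mut = np.flatnonzero(g.niche.mutable_mask())
        pop._niche_mut = niche_mut
        self.mut_n[:, s] = (g.phenotypic.n_bits, g.reproductive.n_bits, niche_mut.size)
        self.flow_n[:, s] = (g.phenotypic.n_genes, g.reproductive.n_genes, g.niche.n_genes)

    def set_species_params(self, s: int, sp_params):
        self.th_fit[s] = sp_params.thextfit
        self.th_rel[s] = sp_params.thextrel
        self.pexp[:, s] = (sp_params.pexpp, sp_params.pexpr, sp_params.pexpn)

    def set_niche(self, s: int, niche):
        self.nn[s] = niche.n
        self.nc[s] = niche.c
        self.nr[s] = niche.r


@dataclass
class SimulationState:
    config: SimulationConfig
    rng: np.random.Generator
    grid: env.EnvironmentGrid
    trait_grammar: gr.Grammar
    fitness_grammar: gr.Grammar
    populations: dict = field(default_factory=dict)   # id -> Population
    species: dict = field(default_factory=dict)       # id -> Species
    region_pops: dict = field(default_factory=dict)   # region id -> set(pop id)
    groups: dict = field(default_factory=dict)        # (region, species) -> set
    multi_regions: set = field(default_factory=set)   # regions with >= 2 pops
    networks: dict = field(default_factory=dict)      # region id -> network
    events: list = field(default_factory=list)
    iteration: int = 0
    next_pop_id: int = 0
    next_species_id: int = 0
    richness: int = 0
    slots: _Slots = field(default_factory=_Slots)
    dirty_eval: set = field(default_factory=set)      # pids needing re-evaluation
    changed_bits: dict = field(default_factory=dict)  # pid -> set of phen bits | None
    dirty_species: set = field(default_factory=set)
    genotype_samples: list = field(default_factory=list)
    occupancy_samples: list = field(default_factory=list)
    _norm_cache: dict = field(default_factory=dict)   # region id -> (version, norm)

    def log(self, kind: str, subject, info=()):
        self.events.append((self.iteration, kind, subject, tuple(info)))

    # -- placement bookkeeping ----------------------------------------------

    def place(self, pop):
        s = self.region_pops.setdefault(pop.region_id, set())
        s.add(pop.id)
        if len(s) == 2:
            self.multi_regions.add(pop.region_id)
        self.groups.setdefault((pop.region_id, pop.species_id), set()).add(pop.id)

    def displace(self, pop, species_id=None):
        sid = pop.species_id if species_id is None else species_id
        rid = pop.region_id
        s = self.region_pops.get(rid)
        if s is not None:
            s.discard(pop.id)
            if len(s) == 1:
                self.multi_regions.discard(rid)
                (lone,) = s
                other = self.populations.get(lone)
                if other is not None:
                    other.nei = 0.0
                    self.slots.nei[other.slot] = 0.0
                net = self.networks.get(rid)
                if net is not None:
                    net.nodes.discard(pop.id)
                    net.noncomp.clear()
            elif not s:
                del self.region_pops[rid]
                self.multi_regions.discard(rid)
                self.networks.pop(rid, None)
            else:
                net = self.networks.get(rid)
                if net is not None:
                    net.nodes.discard(pop.id)
                    for key in [k for k in net.noncomp if pop.id in k]:
                        del net.noncomp[key]
        g = self.groups.get((rid, sid))
        if g is not None:
            g.discard(pop.id)
            if not g:
                del self.groups[(rid, sid)]

    def normalized_properties(self, region_id: int) -> np.ndarray:
        region = self.grid.regions[region_id]
        cached = self._norm_cache.get(region_id)
        if cached is None or cached[0] != region.env_version:
            norm = region.normalized(self.grid.size_property)
            self._norm_cache[region_id] = (region.env_version, norm)
            return norm
        return cached[1]


def _load_grammars(config: SimulationConfig):
    if config.trait_grammar:
        tg = gr.parse_grammar(Path(config.trait_grammar).read_text())
    else:
        tg = gr.load_packaged_grammar("trait")
    if config.fitness_grammar:
        fg = gr.parse_grammar(Path(config.fitness_grammar).read_text())
    else:
        fg = gr.load_packaged_grammar("fitness")
    return tg, fg


def init_state(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulationState:
    """Initialize environment and founder: one species, one population with a
    uniform-random genotype, placed in a uniformly chosen region."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tg, fg = _load_grammars(config)
    grid = env.init_environment(
        config.d1, config.d2, config.nenv, config.size_property, rng,
        config.pregionchange_low, config.pregionchange_high,
    )
    state = SimulationState(config=config, rng=rng, grid=grid,
                            trait_grammar=tg, fitness_grammar=fg)
    genotype = bg.random_genotype(
        config.ngenp, config.ngenr, config.ngenn, config.size_gene, rng
    )
    sp = dg.Species(
        id=0, parent_id=None, birth=0,
        params=dg.SpeciesParams.draw(config, config.ngenr * config.size_gene, rng),
    )
    n, c, r = bg.niche_values(genotype)
    region_id = int(rng.integers(config.d1 * config.d2))
    pop = dg.Population(
        id=0, species_id=0, region_id=region_id,
        genotype=genotype,
        params=dg.LineageParams.founder(config, rng),
        fitness_fn=gr.generate_fitness_function(fg, rng, config.max_depth),
        niche=ec.NicheState(n, c, r),
        birth=0,
    )
    sp.members.add(0)
    sp.repro_index = dg.ReproIndex.build(sp, {0: pop}, config.speciation_rule)
    state.species[0] = sp
    state.populations[0] = pop
    state.place(pop)
    state.slots.acquire(pop, sp.params)
    state.dirty_eval.add(0)
    state.next_pop_id = 1
    state.next_species_id = 1
    state.richness = 1
    state.log(ORIGINATION, 0, ("",))
    return state


# ---------------------------------------------------------------------------
# Per-iteration sub-processes
# ---------------------------------------------------------------------------

def _apply_environment(state: SimulationState):
    cfg = state.config
    changed, structural = env.step_environment(
        state.grid, cfg.penvmerge, cfg.penvsplit, state.rng
    )
    for rid in changed:
        for pid in state.region_pops.get(rid, ()):
            state.dirty_eval.add(pid)
    for record in structural:
        if record[0] == "merge":
            _kind, kept, removed = record
            moved = sorted(state.region_pops.get(removed, set()))
            for pid in moved:
                pop = state.populations[pid]
                state.displace(pop)
                pop.region_id = kept
                state.place(pop)
                state.dirty_eval.add(pid)
            state._norm_cache.pop(removed, None)
            # the kept region's properties were re-combined
            for pid in state.region_pops.get(kept, ()):
                state.dirty_eval.add(pid)
        else:
            _kind, parent_id, new_id, _cells = record
            here = sorted(state.region_pops.get(parent_id, ()))
            for pid in here:
                if state.rng.random() < 0.5:
                    pop = state.populations[pid]
                    state.displace(pop)
                    pop.region_id = new_id
                    state.place(pop)
                    state.dirty_eval.add(pid)


_MISSING = object()


def _note_phen_change(state, pid, positions):
    """Record which phenotypic bits changed (None = length change, re-map all)."""
    prev = state.changed_bits.get(pid, _MISSING)
    if prev is None:
        return
    if positions is None:
        state.changed_bits[pid] = None
    elif prev is _MISSING:
        state.changed_bits[pid] = set(positions)
    else:
        prev.update(positions)


def _repro_changed(state, pop):
    sp = state.species[pop.species_id]
    if sp.repro_index is not None:
        sp.repro_index.update(pop.id, pop.genotype.reproductive)
        if sp.repro_index.need_check:
            state.dirty_species.add(sp.id)
    else:
        state.dirty_species.add(sp.id)
    sp.repro_dirty = True


def _niche_changed(state, pop):
    _n, c, r = bg.niche_values(pop.genotype)
    pop.niche.c, pop.niche.r = c, r  # n stays: state, not genotype
    state.slots.set_niche(pop.slot, pop.niche)


def _pick(rng, n: int, k: int):
    """k distinct uniform indices out of n (k == 1 fast path)."""
    if k <= 1:
        return [int(rng.integers(n))]
    return [int(x) for x in rng.choice(n, size=min(k, n), replace=False)]


def _apply_mutation(state: SimulationState):
    slots = state.slots
    hi = slots.hi
    if hi == 0:
        return
    rng = state.rng
    counts = rng.binomial(slots.mut_n[:, :hi], slots.mut_p[:, :hi])
    hits = np.flatnonzero(counts.any(axis=0))
    for s in hits:
        pop = state.populations[int(slots.pid[s])]
        k = int(counts[0, s])
        if k:
            seg = pop.genotype.phenotypic
            pos = _pick(rng, seg.n_bits, k)
            seg.bits[pos] ^= 1
            _note_phen_change(state, pop.id, pos)
        k = int(counts[1, s])
        if k:
            seg = pop.genotype.reproductive
            pos = _pick(rng, seg.n_bits, k)
            seg.bits[pos] ^= 1
            _repro_changed(state, pop)
        k = int(counts[2, s])
        if k:
            idx = pop._niche_mut
            pos = idx[_pick(rng, idx.size, k)]
            pop.genotype.niche.bits[pos] ^= 1
            _niche_changed(state, pop)


def _apply_gene_flow(state: SimulationState):
    slots = state.slots
    hi = slots.hi
    if hi == 0:
        return
    rng = state.rng
    counts = rng.binomial(slots.flow_n[:, :hi], slots.flow_p[:, :hi])
    hits = np.flatnonzero(counts.any(axis=0))
    for s in hits:
        pop = state.populations[int(slots.pid[s])]
        group = state.groups.get((pop.region_id, pop.species_id))
        if group is None or len(group) < 2:
            continue  # no coexisting conspecific donor
        others = sorted(group - {pop.id})
        donor = state.populations[others[int(rng.integers(len(others)))]]
        for row, kind in enumerate(bg.SEGMENT_KINDS):
            k = int(counts[row, s])
            if not k:
                continue
            seg = pop.genotype.segment(kind)
            dseg = donor.genotype.segment(kind)
            pos = _pick(rng, seg.n_genes, k)
            g = seg.size_gene
            changed_bits = []
            for i in sorted(pos):
                if i >= dseg.n_genes:
                    continue  # beyond the aligned prefix
                lo = i * g
                new = dseg.bits[lo : lo + g]
                old = seg.bits[lo : lo + g]
                if not np.array_equal(old, new):
                    diff = np.flatnonzero(old != new) + lo
                    seg.bits[lo : lo + g] = new
                    changed_bits.extend(int(x) for x in diff)
            if not changed_bits:
                continue
            if kind == bg.PHENOTYPIC:
                _note_phen_change(state, pop.id, changed_bits)
            elif kind == bg.REPRODUCTIVE:
                _repro_changed(state, pop)
            else:
                _niche_changed(state, pop)


def _apply_expansion(state: SimulationState):
    slots = state.slots
    hi = slots.hi
    if hi == 0:
        return
    rng = state.rng
    u = rng.random((3, hi))
    events = np.argwhere(u < slots.pexp[:, :hi])
    for row, s in sorted((int(r), int(c)) for r, c in events):
        if not slots.active[s]:
            continue
        pop = state.populations[int(slots.pid[s])]
        kind = bg.SEGMENT_KINDS[row]
        seg = pop.genotype.segment(kind)
        idx = int(rng.integers(seg.n_genes))
        bg.duplicate_gene_inplace(seg, idx)
        state.log(GENE_DUPLICATION, pop.id, (kind, idx))
        slots.update_genome(s, pop)
        if kind == bg.PHENOTYPIC:
            _note_phen_change(state, pop.id, None)  # length changed: full re-map
        elif kind == bg.REPRODUCTIVE:
            _repro_changed(state, pop)
        else:
            _niche_changed(state, pop)


def _refresh_phenotypes(state: SimulationState):
    cfg = state.config
    pops = state.populations
    for pid in sorted(state.changed_bits):
        pop = pops[pid]
        bits = state.changed_bits[pid]
        if pop.profile is None:
            pop.profile = gr.derive_traits(
                pop.genotype.phenotypic, state.trait_grammar,
                cfg.n_traits, cfg.max_wraps, cfg.max_depth, cfg.stagger,
            )
            state.dirty_eval.add(pid)
            continue
        if getattr(pop.profile, "shared", False):
            pop.profile = gr.PhenotypeProfile(
                list(pop.profile.traits),
                list(pop.profile.consumed_codons),
                list(pop.profile.consumed_positions),
                list(pop.profile.expressed_by_trait),
                pop.profile.expressed_gene_indices,
            )
        changed = gr.update_profile(
            pop.profile, pop.genotype.phenotypic, state.trait_grammar,
            bits, cfg.max_wraps, cfg.max_depth, cfg.stagger,
        )
        if changed:
            state.dirty_eval.add(pid)
    state.changed_bits.clear()
    for pid in sorted(state.dirty_eval):
        pop = pops.get(pid)
        if pop is None:
            continue
        if pop.profile is None:
            pop.profile = gr.derive_traits(
                pop.genotype.phenotypic, state.trait_grammar,
                cfg.n_traits, cfg.max_wraps, cfg.max_depth, cfg.stagger,
            )
        norm = state.normalized_properties(pop.region_id)
        pop.trait_values, pop.fitness = gr.evaluate_population(
            pop.fitness_fn, pop.profile, norm
        )
        state.slots.fitness[pop.slot] = pop.fitness
        region = state.grid.regions[pop.region_id]
        pop.env_seen = region.env_version
        pop.region_seen = pop.region_id
    state.dirty_eval.clear()


def _update_ecology(state: SimulationState):
    cfg = state.config
    pops = state.populations
    slots = state.slots
    for rid in sorted(state.multi_regions):
        here = state.region_pops[rid]
        net = state.networks.setdefault(rid, ec.RegionalEcologicalNetwork(rid))
        net.nodes = set(here)
        niche_of = lambda p: pops[p].niche
        fitness_of = lambda p: pops[p].fitness
        ec.update_network(net, niche_of, cfg.preladd, cfg.preldel, state.rng,
                          cfg.link_magnitude)
        for pid, val in ec.compute_all_nei(net, fitness_of, niche_of).items():
            pops[pid].nei = val
            slots.nei[pops[pid].slot] = val


def _apply_niche_shifts(state: SimulationState):
    cfg = state.config
    slots = state.slots
    hi = slots.hi
    cand = np.flatnonzero(slots.active[:hi] & (slots.nei[:hi] < cfg.thnicheshift))
    if cand.size == 0:
        return
    pops = state.populations
    for s in sorted(int(x) for x in cand):
        pop = pops[int(slots.pid[s])]
        net = state.networks.get(pop.region_id)
        if net is None or len(net.nodes) < 2:
            continue
        new = ec.adaptive_shift(
            pop.id, pop.niche, pop.nei, net,
            lambda p: pops[p].niche, lambda p: pops[p].fitness,
            cfg.thnicheshift, state.rng,
        )
        if new is not None:
            if cfg.log_population_events:
                state.log(NICHE_SHIFT, pop.id,
                          (pop.niche.n, pop.niche.r, new.n, new.r))
            pop.niche = new
            slots.set_niche(s, new)


def _apply_extinctions(state: SimulationState):
    slots = state.slots
    hi = slots.hi
    doomed = (
        (slots.fitness[:hi] < slots.th_fit[:hi])
        | (slots.nei[:hi] < slots.th_rel[:hi])
        | (slots.nn[:hi] < slots.nc[:hi] - slots.nr[:hi])
        | (slots.nn[:hi] > slots.nc[:hi] + slots.nr[:hi])
    ) & slots.active[:hi]
    cand = slots.pid[:hi][doomed]
    if cand.size == 0:
        return
    candidates = [int(x) for x in cand]
    doomed_pops = {pid: state.populations[pid] for pid in candidates}
    removed, extinct = dg.apply_extinctions(
        state.populations, state.species, state.iteration, candidates
    )
    extinct_set = set(extinct)
    verbose = state.config.log_population_events
    # the species-extinct flag belongs to the single removal that emptied the
    # species: several members may fall in the same iteration
    final_death = {}
    for pid, _route, sid, _rid in removed:
        if sid in extinct_set:
            final_death[sid] = pid
    for pid, route, sid, _rid in removed:
        extinguished = final_death.get(sid) == pid
        if verbose or extinguished:
            state.log(EXTINCTION, pid, (route, sid, extinguished))
        pop = doomed_pops[pid]
        state.displace(pop)
        slots.release(pop.slot)
        if sid not in extinct_set:
            state.dirty_species.add(sid)
    state.richness -= len(extinct)


def _apply_splits(state: SimulationState):
    cfg = state.config
    slots = state.slots
    hi = slots.hi
    rng = state.rng
    u = rng.random(hi)
    sel = np.flatnonzero(slots.active[:hi] & (u < slots.split_p[:hi]))
    for s in sorted(int(x) for x in sel):
        parent = state.populations[int(slots.pid[s])]
        region = state.grid.regions[parent.region_id]
        adjacent = state.grid.adjacent_region_ids(region)
        child, migrated = dg.make_child(
            parent, state.next_pop_id, cfg, rng, adjacent, state.iteration
        )
        state.next_pop_id += 1
        if child.profile is not None:
            child.profile.shared = True
        state.populations[child.id] = child
        sp = state.species[child.species_id]
        sp.members.add(child.id)
        if sp.repro_index is not None:
            sp.repro_index.add_clone(child.id, parent.id)
        state.place(child)
        slots.acquire(child, sp.params)
        if cfg.log_population_events:
            state.log(POPULATION_SPLIT, child.id, (parent.id,))
            if migrated:
                state.log(MIGRATION, child.id, (parent.region_id, child.region_id))
            child.trait_values = None
            state.dirty_eval.add(child.id)
        elif parent.trait_values is None:
            state.dirty_eval.add(child.id)
        else:
            # same region, identical genome: the parent's current evaluation
            # applies verbatim until something changes
            child.trait_values = list(parent.trait_values)
            child.env_seen = parent.env_seen
            child.region_seen = parent.region_seen
            slots.fitness[child.slot] = child.fitness


def _apply_speciation(state: SimulationState):
    cfg = state.config
    for sid in sorted(state.dirty_species):
        sp = state.species.get(sid)
        if sp is None or sp.extinct:
            continue
        if sp.repro_index is None:
            sp.repro_index = dg.ReproIndex.build(
                sp, state.populations, cfg.speciation_rule)
        index = sp.repro_index
        if not (index.need_check or sp.repro_dirty):
            continue
        index.need_check = False
        sp.repro_dirty = False
        if len(sp.members) < 2:
            continue
        comps = index.partition()
        if len(comps) == 1:
            continue
        new = dg.update_species_partition(
            sp, state.populations, state.iteration, state.next_species_id,
            cfg, state.rng, cfg.distance_method, components=comps,
            rule=cfg.speciation_rule,
        )
        sp.repro_index = dg.ReproIndex.build(
            sp, state.populations, cfg.speciation_rule)
        for ns in new:
            state.species[ns.id] = ns
            state.next_species_id = ns.id + 1
            state.richness += 1
            state.log(ORIGINATION, ns.id, (sid,))
            ns.repro_index = dg.ReproIndex.build(
                ns, state.populations, cfg.speciation_rule)
            for pid in ns.members:
                pop = state.populations[pid]
                # move the member's group key and refresh species-scope params
                g = state.groups.get((pop.region_id, sid))
                if g is not None:
                    g.discard(pid)
                    if not g:
                        del state.groups[(pop.region_id, sid)]
                state.groups.setdefault((pop.region_id, ns.id), set()).add(pid)
                state.slots.set_species_params(pop.slot, ns.params)
    state.dirty_species.clear()


def _sample(state: SimulationState):
    cfg = state.config
    t = state.iteration
    if cfg.occupancy_sample_every and t % cfg.occupancy_sample_every == 0:
        occupied = {(p.region_id, p.niche.n) for p in state.populations.values()}
        state.occupancy_samples.append(
            (t, len(occupied), len(state.grid.regions),
             len(state.populations), state.richness)
        )
    if cfg.genotype_sample_every and t % cfg.genotype_sample_every == 0:
        for sid in sorted(state.species):
            sp = state.species[sid]
            if sp.extinct or not sp.members:
                continue
            rep = state.populations[min(sp.members)]
            if rep.profile is None:
                continue
            classes = gr.classify_genes(
                rep.profile, rep.fitness_fn, rep.genotype.phenotypic.n_genes
            )
            alleles = [
                bytes(np.packbits(state.populations[m].genotype.phenotypic.bits))
                for m in sorted(sp.members)
            ]
            state.genotype_samples.append((t, sid, classes, alleles))


def step(state: SimulationState) -> bool:
    """One canonical pass; returns False once the world is empty."""
    state.iteration += 1
    _apply_environment(state)
    _apply_mutation(state)
    _apply_gene_flow(state)
    _apply_expansion(state)
    _refresh_phenotypes(state)
    _update_ecology(state)
    _apply_niche_shifts(state)
    _apply_extinctions(state)
    if not state.populations:
        state.log(TOTAL_EXTINCTION, -1)
        return False
    _apply_splits(state)
    _apply_speciation(state)
    _sample(state)
    return True


# ---------------------------------------------------------------------------
# Run driver
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    config: SimulationConfig
    state: SimulationState
    events: list
    summary: dict


def events_checksum(events: list) -> str:
    h = hashlib.sha256()
    for e in events:
        h.update(repr(e).encode())
    return h.hexdigest()


def run(config: SimulationConfig, progress=None) -> RunResult:
    """Run for ``config.iterations`` steps or until total extinction.

    Shocks replace every region's drift rate with the scheduled value during
    [start, start+duration); the original per-region rates are restored when
    the shock ends.
    """
    state = init_state(config)
    shocks = sorted(config.shocks, key=lambda s: s.start)
    saved_rates: dict | None = None
    active_end = None
    alive = True
    for t in range(1, config.iterations + 1):
        for s in shocks:
            if s.start == t:
                saved_rates = {
                    rid: r.pregionchange for rid, r in state.grid.regions.items()
                }
                state.grid.set_pregionchange(s.pregionchange)
                state.events.append((t, SHOCK_START, -1, (s.pregionchange,)))
                active_end = s.start + s.duration
        if active_end is not None and t == active_end:
            state.grid.set_pregionchange(saved_rates)
            state.events.append((t, SHOCK_END, -1, ()))
            saved_rates, active_end = None, None
        alive = step(state)
        if progress is not None and t % 10_000 == 0:
            progress(state)
        if not alive:
            break
    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "iterations_completed": state.iteration,
        "total_extinction": not alive,
        "extinction_iteration": state.iteration if not alive else None,
        "final_richness": state.richness,
        "final_populations": len(state.populations),
        "species_total": len(state.species),
        "events": len(state.events),
        "events_checksum": events_checksum(state.events),
    }
    return RunResult(config, state, state.events, summary)


def audit_state(state: SimulationState) -> None:
    """Consistency audit: partitions, cross-references, interval invariants."""
    env.check_partition(state.grid)
    seen = set()
    for sid, sp in state.species.items():
        if sp.extinct and sp.members:
            raise AssertionError(f"extinct species {sid} has members")
        for pid in sp.members:
            if pid in seen:
                raise AssertionError(f"population {pid} in two species")
            seen.add(pid)
            if state.populations[pid].species_id != sid:
                raise AssertionError(f"species id mismatch for population {pid}")
    if seen != set(state.populations):
        raise AssertionError("species membership is not a partition")
    for pid, pop in state.populations.items():
        if pop.region_id not in state.grid.regions:
            raise AssertionError(f"population {pid} in unknown region")
        if pid not in state.region_pops.get(pop.region_id, ()):
            raise AssertionError(f"population {pid} missing from region index")
        if pid not in state.groups.get((pop.region_id, pop.species_id), ()):
            raise AssertionError(f"population {pid} missing from group index")
        if pop.niche.r < 0 or pop.niche.n < 0:
            raise AssertionError(f"negative niche state for population {pid}")
        if int(state.slots.pid[pop.slot]) != pid:
            raise AssertionError(f"slot mismatch for population {pid}")
    for rid, members in state.region_pops.items():
        if (len(members) >= 2) != (rid in state.multi_regions):
            raise AssertionError(f"multi-region index stale for region {rid}")


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def species_table(state: SimulationState) -> list:
    rows = []
    for sid in sorted(state.species):
        sp = state.species[sid]
        rows.append({
            "species_id": sid,
            "parent_id": sp.parent_id if sp.parent_id is not None else "",
            "birth": sp.birth,
            "extinction": sp.extinction if sp.extinction is not None else "",
        })
    return rows


def write_outputs(result: RunResult, outdir) -> None:
    from . import metrics

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "events.csv", "w") as f:
        f.write("iteration,kind,subject,info\n")
        for it, kind, subject, info in result.events:
            payload = ";".join(str(x) for x in info)
            f.write(f"{it},{kind},{subject},{payload}\n")
    with open(out / "species.csv", "w") as f:
        f.write("species_id,parent_id,birth,extinction\n")
        for row in species_table(result.state):
            f.write("{species_id},{parent_id},{birth},{extinction}\n".format(**row))
    with open(out / "populations_final.csv", "w") as f:
        f.write("population_id,species_id,region_id,birth,fitness,nei,n,c,r\n")
        for pid in sorted(result.state.populations):
            p = result.state.populations[pid]
            f.write(
                f"{pid},{p.species_id},{p.region_id},{p.birth},"
                f"{p.fitness:.6g},{p.nei:.6g},{p.niche.n},{p.niche.c},{p.niche.r}\n"
            )
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
    (out / "config.yaml").write_text(result.config.to_yaml())
    (out / "phylogeny.nwk").write_text(
        metrics.export_newick(species_table(result.state),
                              result.state.iteration)
    )
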
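"""Population splitting, lineage parameter inheritance, speciation by
reproductive divergence and the three extinction routes."""

import numpy as np
import pytest

import ecoevosim as es
from ecoevosim.demography import (
    LineageParams,
    partition_members,
    Population,
    ReproIndex,
    Species,
    SpeciesParams,
    apply_extinctions,
    compatibility_components,
    extinction_route,
    make_child,
    split_population,
    update_species_partition,
)
from ecoevosim.ecology import NicheState

from conftest import make_segment


def make_pop(pid, rng, cfg=None, species_id=0, birth=0, repro_bits=None,
             fitness=0.5, nei=0.0, niche=None):
    cfg = cfg or es.SimulationConfig()
    gt = es.random_genotype(cfg.ngenp, cfg.ngenr, cfg.ngenn, cfg.size_gene, rng)
    if repro_bits is not None:
        gt.reproductive.bits = np.array([int(b) for b in repro_bits], dtype=np.uint8)
    return Population(
        id=pid, species_id=species_id, region_id=0, genotype=gt,
        params=LineageParams.founder(cfg, rng), fitness_fn=None,
        niche=niche or NicheState(10, 10, 5), birth=birth,
        fitness=fitness, nei=nei,
    )


@pytest.fixture
def cfg():
    return es.SimulationConfig(d1=4, d2=4)


class TestSplitting:
    def test_zero_split_probability_never_splits(self, cfg, rng):
        pop = make_pop(1, rng, cfg)
        pop.params.ppopsplit = 0.0
        for _ in range(5000):
            assert split_population(pop, 99, cfg, rng, (1, 2), 0) is None

    def test_child_starts_at_zero_reproductive_distance(self, cfg, rng):
        parent = make_pop(1, rng, cfg)
        parent.params.ppopmig = 0.0
        child, migrated = make_child(parent, 2, cfg, rng, (1, 2, 3), 10)
        assert not migrated
        assert child.region_id == parent.region_id
        assert child.species_id == parent.species_id
        assert child.birth == 10
        assert es.hamming_bits(
            child.genotype.reproductive, parent.genotype.reproductive
        ) == 0
        # deep copy: mutating the child leaves the parent untouched
        child.genotype.reproductive.bits[0] ^= 1
        assert es.hamming_bits(
            child.genotype.reproductive, parent.genotype.reproductive
        ) == 1

    def test_child_inherits_fitness_function_object(self, cfg, rng):
        parent = make_pop(1, rng, cfg)
        parent.fitness_fn = object()
        child, _ = make_child(parent, 2, cfg, rng, (), 0)
        assert child.fitness_fn is parent.fitness_fn

    def test_normal_draws_stay_within_three_sigma_of_lineage_mean(self, cfg, rng):
        # sigma 0.0025 around the inherited lineage mean
        parent = make_pop(1, rng, cfg)
        parent.params.means = (0.001, 0.001, 0.001, 0.5, 0.25)
        inside = 0
        n = 10_000
        for i in range(n):
            child, _ = make_child(parent, i + 2, cfg, rng, (), 0)
            assert child.params.means == parent.params.means
            inside += abs(child.params.ppopsplit - 0.5) <= 3 * 0.0025
        assert inside / n >= 0.99

    def test_migration_probability_honoured(self, cfg, rng):
        parent = make_pop(1, rng, cfg)
        parent.params.ppopmig = 1.0
        child, migrated = make_child(parent, 2, cfg, rng, (7, 8, 9), 0)
        assert migrated and child.region_id in (7, 8, 9)
        parent.params.ppopmig = 0.0
        child, migrated = make_child(parent, 3, cfg, rng, (7, 8, 9), 0)
        assert not migrated and child.region_id == parent.region_id


class TestSpeciation:
    def _species(self, pops, th_bits, cfg):
        sp = Species(
            id=0, parent_id=None, birth=0,
            params=SpeciesParams(th_bits, -1.0, 0.1, 0, 0, 0),
            members=set(pops),
        )
        return sp

    def test_single_population_species_never_splits(self, cfg, rng):
        pops = {1: make_pop(1, rng, cfg)}
        sp = self._species(pops, 8.0, cfg)
        assert update_species_partition(sp, pops, 5, 10) == []

    def test_divergence_above_table_maximum_threshold_splits(self, cfg, rng):
        # Table maximum: 2 genes x 8 bits x 0.9 = 14.4 bits; a 15-bit
        # divergent pair must be two species
        a = make_pop(1, rng, cfg, repro_bits="0" * 16, birth=0)
        b = make_pop(2, rng, cfg, repro_bits="1" * 15 + "0", birth=3)
        pops = {1: a, 2: b}
        sp = self._species(pops, 2 * 8 * 0.9, cfg)
        new = update_species_partition(sp, pops, 7, 10)
        assert len(new) == 1
        assert sp.members == {1}          # oldest member keeps the id
        assert new[0].members == {2}
        assert new[0].parent_id == 0 and new[0].birth == 7
        assert b.species_id == 10

    def test_divergence_below_threshold_keeps_one_species(self, cfg, rng):
        a = make_pop(1, rng, cfg, repro_bits="0" * 16)
        b = make_pop(2, rng, cfg, repro_bits="1" * 14 + "00")
        pops = {1: a, 2: b}
        sp = self._species(pops, 14.4, cfg)
        assert update_species_partition(sp, pops, 7, 10) == []

    def test_chain_compatibility_is_transitive_under_component_rule(self, cfg, rng):
        # A-B compatible, B-C compatible, A-C incompatible -> one species
        # when species are the connected components of the compatibility graph
        a = make_pop(1, rng, cfg, repro_bits="0" * 16)
        b = make_pop(2, rng, cfg, repro_bits="1" * 6 + "0" * 10)
        c = make_pop(3, rng, cfg, repro_bits="1" * 12 + "0" * 4)
        pops = {1: a, 2: b, 3: c}
        sp = self._species(pops, 8.0, cfg)
        comps = compatibility_components(sp, pops)
        assert comps == [[1, 2, 3]]
        assert update_species_partition(
            sp, pops, 7, 10, rule="connected_components") == []

    def test_pairwise_rule_splits_chains_around_divergent_poles(self, cfg, rng):
        # same chain under the default rule: A and C are reproductively
        # isolated (12 > 8 bits), so the species must split; B joins the
        # nearer pole (distance 6 to A, 6 to C -> tie goes to pole A)
        a = make_pop(1, rng, cfg, repro_bits="0" * 16, birth=0)
        b = make_pop(2, rng, cfg, repro_bits="1" * 6 + "0" * 10, birth=1)
        c = make_pop(3, rng, cfg, repro_bits="1" * 12 + "0" * 4, birth=2)
        pops = {1: a, 2: b, 3: c}
        sp = self._species(pops, 8.0, cfg)
        parts = partition_members(sp, pops)
        assert sorted(map(sorted, parts)) == [[1, 2], [3]]
        new = update_species_partition(sp, pops, 7, 10)
        assert len(new) == 1 and new[0].members == {3}
        assert sp.members == {1, 2}

    def test_fresh_species_params_drawn_at_emergence(self, cfg, rng):
        a = make_pop(1, rng, cfg, repro_bits="0" * 16)
        b = make_pop(2, rng, cfg, repro_bits="1" * 16)
        pops = {1: a, 2: b}
        sp = self._species(pops, 4.0, cfg)
        new = update_species_partition(sp, pops, 7, 10, cfg, rng)
        assert len(new) == 1
        lo = cfg.th_speciation_low * 16
        hi = cfg.th_speciation_high * 16
        assert lo <= new[0].params.th_speciation_bits <= hi
        assert cfg.thextrel_low <= new[0].params.thextrel <= cfg.thextrel_high

    def test_repro_index_components_match_pairwise_reference(self, cfg, rng):
        # the incremental distance index and the plain pairwise scan must
        # agree through adds, updates and removals
        for trial in range(20):
            pops = {
                i: make_pop(i, rng, cfg, birth=i)
                for i in range(8)
            }
            sp = self._species(pops, float(rng.uniform(2, 12)), cfg)
            index = ReproIndex.build(sp, pops)
            for _ in range(10):
                op = rng.integers(3)
                ids = sorted(index.row)
                if op == 0 and len(ids) > 2:
                    victim = ids[int(rng.integers(len(ids)))]
                    index.remove(victim)
                    sp.members.discard(victim)
                    del pops[victim]
                elif op == 1:
                    target = ids[int(rng.integers(len(ids)))]
                    seg = pops[target].genotype.reproductive
                    seg.bits[rng.integers(seg.n_bits)] ^= 1
                    index.update(target, seg)
                else:
                    nid = max(pops) + 1
                    pops[nid] = make_pop(nid, rng, cfg, birth=nid)
                    sp.members.add(nid)
                    index.add(nid, pops[nid].genotype.reproductive)
            got = sorted(sorted(c) for c in index.components())
            want = sorted(sorted(c) for c in compatibility_components(sp, pops))
            assert got == want
            got_d = sorted(sorted(c) for c in index.diameter_partition())
            want_d = sorted(
                sorted(c) for c in partition_members(sp, pops)
            )
            assert got_d == want_d

    def test_length_difference_counts_toward_divergence(self, cfg, rng):
        a = make_pop(1, rng, cfg, repro_bits="0" * 16)
        b = make_pop(2, rng, cfg, repro_bits="0" * 16)
        pops = {1: a, 2: b}
        sp = self._species(pops, 6.0, cfg)
        index = ReproIndex.build(sp, pops)
        # duplicate a gene in b: 8 surplus bits > 6-bit threshold
        es.bitgenome.duplicate_gene_inplace(b.genotype.reproductive, 0)
        index.update(2, b.genotype.reproductive)
        assert index.need_check
        assert sorted(map(sorted, index.components())) == [[1], [2]]


class TestExtinction:
    def _params(self, thextfit=0.10, thextrel=-1.0):
        return SpeciesParams(8.0, thextrel, thextfit, 0, 0, 0)

    def test_low_fitness_triggers_fitness_route(self, cfg, rng):
        pop = make_pop(1, rng, cfg, fitness=0.05)
        assert extinction_route(pop, self._params()) == "fitness"

    def test_nei_collapse_is_fitness_independent(self, cfg, rng):
        pop = make_pop(1, rng, cfg, fitness=1.0, nei=-1.2)
        assert extinction_route(pop, self._params(thextrel=-1.0)) == "nei"

    def test_niche_mismatch_route(self, cfg, rng):
        pop = make_pop(1, rng, cfg, fitness=1.0,
                       niche=NicheState(20, 10, 3))
        # 20 outside [7, 13]
        assert extinction_route(pop, self._params()) == "niche_mismatch"

    def test_healthy_population_survives(self, cfg, rng):
        pop = make_pop(1, rng, cfg, fitness=0.5, nei=0.0,
                       niche=NicheState(10, 10, 3))
        assert extinction_route(pop, self._params()) is None

    def test_species_marked_extinct_when_last_member_dies(self, cfg, rng):
        pops = {1: make_pop(1, rng, cfg, fitness=0.01)}
        sp = Species(id=0, parent_id=None, birth=0, params=self._params(),
                     members={1})
        removed, extinct = apply_extinctions(pops, {0: sp}, iteration=42)
        assert [(r[0], r[1]) for r in removed] == [(1, "fitness")]
        assert extinct == [0]
        assert sp.extinction == 42
        assert pops == {}

    def test_candidate_prescreen_matches_full_scan(self, cfg, rng):
        pops = {
            i: make_pop(i, rng, cfg,
                        fitness=float(rng.random()),
                        nei=float(-2 * rng.random()),
                        niche=NicheState(int(rng.integers(30)), 10, 5))
            for i in range(20)
        }
        sp = Species(id=0, parent_id=None, birth=0,
                     params=self._params(thextrel=-1.0), members=set(pops))
        reference = {
            pid for pid, p in pops.items()
            if extinction_route(p, sp.params) is not None
        }
        removed, _ = apply_extinctions(dict(pops), {0: Species(
            id=0, parent_id=None, birth=0, params=sp.params,
            members=set(pops))}, 1)
        assert {r[0] for r in removed} == reference
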
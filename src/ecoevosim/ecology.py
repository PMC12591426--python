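"""Niche intervals, regional ecological networks, the net-ecological-impact
(NEI) metric and NEI-triggered adaptive niche shifts.

Each population's ecology is summarised by three integers: niche position
``n`` (where it actually sits on an abstract gradient), optimum ``c`` and
range ``r``.  The *fundamental* niche is the interval [c-r, c+r] the
population could tolerate; the *realized* niche [n-r, n+r] is what it
occupies.  Cohabiting populations with overlapping realized niches compete
automatically (bidirectional negative links); non-overlapping pairs may form
stochastic facilitative or inhibitory links whose direction follows an
allometric rule (higher-``n`` organisms facilitate lower-``n`` ones, never
the reverse).

For a focal population A the net ecological impact is

    NEI_A = sum over cohabitants i of  L_Ai * (1 - F_Ai) + W_Ai

where L_Ai is the (negative) competitive link weight, i.e. minus the realized
overlap; F_Ai = clamp(fitness_A - fitness_i, -1, 1) shrinks the competitive
burden for the fitter party; and W_Ai sums the signed weights of
non-competitive links directed at A.  Positive NEI marks favourable
integration in the community, negative NEI ecological stress; a population
alone in its region has NEI exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMPETITIVE = "competitive"
FACILITATIVE = "facilitative"
INHIBITORY = "inhibitory"


@dataclass
class NicheState:
    n: int
    c: int
    r: int

    def realized(self) -> tuple:
        return (self.n - self.r, self.n + self.r)

    def fundamental(self) -> tuple:
        return (self.c - self.r, self.c + self.r)


@dataclass(frozen=True)
class InteractionLink:
    source: int
    target: int
    kind: str
    weight: float


def niche_overlap(a: NicheState, b: NicheState) -> float:
    """Jaccard overlap of realized niche intervals, in [0, 1].

    Degenerate zero-length intervals overlap fully iff they are the same
    point; a point against a proper interval contributes zero length.
    """
    return _overlap_intervals(a.n - a.r, a.n + a.r, b.n - b.r, b.n + b.r)


def _overlap_intervals(lo_a, hi_a, lo_b, hi_b) -> float:
    if lo_a == hi_a and lo_b == hi_b:
        return 1.0 if lo_a == lo_b else 0.0
    inter = min(hi_a, hi_b) - max(lo_a, lo_b)
    if inter <= 0:
        return 0.0
    return inter / (max(hi_a, hi_b) - min(lo_a, lo_b))


class RegionalEcologicalNetwork:
    """Per-region interaction graph over the populations present.

    Competitive links are implied by pairwise overlap and refreshed on every
    update; non-competitive links (``noncomp``) are persistent state, keyed
    by ordered pair (source, target) with signed weight.
    """

    def __init__(self, region_id: int):
        self.region_id = region_id
        self.nodes: set = set()
        self.noncomp: dict = {}  # (src, tgt) -> weight
        self._overlaps: dict = {}  # unordered pair key -> overlap, last update

    def links(self, niche_of) -> list:
        """Materialise the full link set (competitive pairs + non-competitive)."""
        out = []
        nodes = sorted(self.nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1 :]:
                ov = niche_overlap(niche_of(a), niche_of(b))
                if ov > 0.0:
                    out.append(InteractionLink(a, b, COMPETITIVE, -ov))
                    out.append(InteractionLink(b, a, COMPETITIVE, -ov))
        for (s, t), w in sorted(self.noncomp.items()):
            kind = FACILITATIVE if w > 0 else INHIBITORY
            out.append(InteractionLink(s, t, kind, w))
        return out

    def edge_list_csv(self, niche_of) -> str:
        lines = ["source,target,kind,weight"]
        for link in self.links(niche_of):
            lines.append(f"{link.source},{link.target},{link.kind},{link.weight:.6g}")
        return "\n".join(lines) + "\n"


def update_network(
    network: RegionalEcologicalNetwork,
    niche_of,
    preladd: float,
    preldel: float,
    rng: np.random.Generator,
    link_magnitude: float = 0.5,
) -> None:
    """Refresh overlaps and evolve the stochastic non-competitive links.

    Competitive links exist exactly for overlapping cohabiting pairs (they
    are recomputed, not stored).  For each ordered non-overlapping pair
    without a non-competitive link, one forms with probability ``preladd``:
    facilitative (+magnitude) if source.n > target.n, inhibitory (-magnitude)
    if source.n < target.n, none at equal positions.  Existing links die with
    probability ``preldel`` and deterministically when their pair overlaps
    again or an endpoint left the region.
    """
    nodes = sorted(network.nodes)
    overlaps = {}
    niches = {p: niche_of(p) for p in nodes}
    for i, a in enumerate(nodes):
        na = niches[a]
        for b in nodes[i + 1 :]:
            overlaps[(a, b)] = niche_overlap(na, niches[b])
    network._overlaps = overlaps
    # removal: stochastic + structural
    for key in sorted(network.noncomp):
        s, t = key
        pair = (s, t) if s < t else (t, s)
        if (
            s not in network.nodes
            or t not in network.nodes
            or overlaps.get(pair, 0.0) > 0.0
            or (preldel > 0.0 and rng.random() < preldel)
        ):
            del network.noncomp[key]
    # formation on disjoint ordered pairs
    if preladd > 0.0:
        for (a, b), ov in overlaps.items():
            if ov > 0.0:
                continue
            for s, t in ((a, b), (b, a)):
                if (s, t) in network.noncomp:
                    continue
                if rng.random() < preladd:
                    ns, nt = niches[s], niches[t]
                    if ns.n > nt.n:
                        network.noncomp[(s, t)] = link_magnitude
                    elif ns.n < nt.n:
                        network.noncomp[(s, t)] = -link_magnitude


def compute_nei(
    network: RegionalEcologicalNetwork,
    focal: int,
    fitness_of,
    niche_of,
) -> float:
    """NEI of ``focal``: competition terms plus incoming non-competitive weights."""
    if focal not in network.nodes:
        raise KeyError(f"population {focal} not in network {network.region_id}")
    nf = niche_of(focal)
    ff = fitness_of(focal)
    total = 0.0
    for other in network.nodes:
        if other == focal:
            continue
        ov = niche_overlap(nf, niche_of(other))
        if ov > 0.0:
            f = ff - fitness_of(other)
            f = -1.0 if f < -1.0 else (1.0 if f > 1.0 else f)
            total += -ov * (1.0 - f)
        w = network.noncomp.get((other, focal))
        if w is not None:
            total += w
    return total


def compute_all_nei(network, fitness_of, niche_of) -> dict:
    """NEI for every node at once (engine hot path, same maths as compute_nei)."""
    nodes = sorted(network.nodes)
    if len(nodes) == 1:
        return {nodes[0]: 0.0}
    data = []
    for p in nodes:
        nb = niche_of(p)
        data.append((p, nb.n - nb.r, nb.n + nb.r, fitness_of(p)))
    nei = dict.fromkeys(nodes, 0.0)
    for i, (a, lo_a, hi_a, fa) in enumerate(data):
        for b, lo_b, hi_b, fb in data[i + 1 :]:
            if lo_a == hi_a and lo_b == hi_b:
                ov = 1.0 if lo_a == lo_b else 0.0
            else:
                inter = (hi_a if hi_a < hi_b else hi_b) - (lo_a if lo_a > lo_b else lo_b)
                if inter <= 0:
                    ov = 0.0
                else:
                    ov = inter / ((hi_a if hi_a > hi_b else hi_b)
                                  - (lo_a if lo_a < lo_b else lo_b))
            if ov > 0.0:
                f = fa - fb
                f = -1.0 if f < -1.0 else (1.0 if f > 1.0 else f)
                nei[a] += -ov * (1.0 - f)
                nei[b] += -ov * (1.0 + f)
    for (s, t), w in network.noncomp.items():
        nei[t] += w
    return nei


def _prospective_nei(lo, hi, others, ff):
    """NEI if the focal population occupied the realized interval [lo, hi].

    ``others`` is [(lo_i, hi_i, fitness_i, w_in_i)]; incoming non-competitive
    weights count only while the pair stays disjoint (overlap dissolves them).
    """
    total = 0.0
    for lo_b, hi_b, fit, w in others:
        if lo == hi and lo_b == hi_b:
            ov = 1.0 if lo == lo_b else 0.0
        else:
            inter = (hi if hi < hi_b else hi_b) - (lo if lo > lo_b else lo_b)
            if inter <= 0:
                ov = 0.0
            else:
                ov = inter / ((hi if hi > hi_b else hi_b)
                              - (lo if lo < lo_b else lo_b))
        if ov > 0.0:
            f = ff - fit
            f = -1.0 if f < -1.0 else (1.0 if f > 1.0 else f)
            total += -ov * (1.0 - f)
        elif w != 0.0:
            total += w
    return total


def adaptive_shift(
    focal: int,
    niche: NicheState,
    nei: float,
    network: RegionalEcologicalNetwork,
    niche_of,
    fitness_of,
    thnicheshift: float,
    rng: np.random.Generator,
):
    """Ecology-triggered niche displacement (+-1 in n and/or r).

    Fires only when NEI has dropped below ``thnicheshift``.  All candidate
    moves (n+-1 crossed with r-1/r/r+1, plus pure r+-1; negative n or r
    excluded) are scored by their prospective NEI; the best is adopted iff it
    strictly beats staying put, ties broken uniformly at random.  This is the
    only process that ever changes ``n``.
    """
    if nei >= thnicheshift:
        return None
    noncomp = network.noncomp
    others = []
    for p in sorted(network.nodes):
        if p == focal:
            continue
        nb = niche_of(p)
        w = noncomp.get((p, focal), 0.0)
        others.append((nb.n - nb.r, nb.n + nb.r, fitness_of(p), w))
    ff = fitness_of(focal)
    candidates = []
    for dn in (-1, 0, 1):
        for dr in (-1, 0, 1):
            if dn == 0 and dr == 0:
                continue
            n2, r2 = niche.n + dn, niche.r + dr
            if n2 < 0 or r2 < 0:
                continue
            candidates.append((n2, r2))
    if not candidates:
        return None
    scores = [_prospective_nei(n2 - r2, n2 + r2, others, ff)
              for n2, r2 in candidates]
    best = max(scores)
    if best <= _prospective_nei(niche.n - niche.r, niche.n + niche.r, others, ff):
        return None
    ties = [c for c, s in zip(candidates, scores) if s == best]
    n2, r2 = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
    return NicheState(n2, niche.c, r2)
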
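"""Simulation configuration: parameter set, validation, YAML round-trip.

Defaults are the proof-of-concept parameterization: a 1000x1000 toroidal
grid, 24 eight-bit environmental properties per region, 36/2/1 phenotypic /
reproductive / per-role niche genes of 8 bits, segment-specific mutation and
gene-flow rates, disabled region merge/split and niche-segment expansion,
and the speciation / extinction thresholds listed below.  Parameters whose
value is a distribution (uniform ranges, normal jitter around an inherited
mean) are drawn per entity at its creation; the *_low/*_high and founder_*
fields here parameterize those draws.

The full scale (1000x1000 grid, 5e6 iterations) is supported but expensive;
:mod:`ecoevosim.study` builds the scaled-down configurations used for the
packaged replicate experiments.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class ShockSpec:
    """Global environmental shock: override every region's drift rate."""

    start: int
    duration: int
    pregionchange: float


@dataclass
class SimulationConfig:
    # environment
    d1: int = 1000
    d2: int = 1000
    nenv: int = 24
    size_property: int = 8
    pregionchange_low: float = 0.005
    pregionchange_high: float = 0.025
    penvmerge: float = 0.0
    penvsplit: float = 0.0
    # genotype architecture
    ngenp: int = 36
    ngenr: int = 2
    ngenn: int = 1  # niche genes per role (n, c, r)
    size_gene: int = 8
    # genetic variation: U(0, high) per population for mutation rates;
    # gene-flow probabilities follow a lineage random walk N(parent, sigma)
    pmutp_high: float = 0.0005
    pmutr_high: float = 0.0001
    pmutn_high: float = 0.00001
    pflow_sigma: float = 0.001
    founder_pflowp: float = 0.001
    founder_pflowr: float = 0.001
    founder_pflown: float = 0.001
    pexpp: float = 5e-7
    pexpr: float = 1e-7
    pexpn: float = 0.0
    # population dynamics (lineage random walks, sigma per draw)
    popsplit_sigma: float = 0.0025
    popmig_sigma: float = 0.0025
    founder_ppopsplit: float = 0.005
    founder_ppopmig: float = 0.9
    # speciation / extinction
    th_speciation_low: float = 0.5   # fraction of reproductive bits
    th_speciation_high: float = 0.9
    thextfit: float = 0.10
    thextrel_low: float = -1.0
    thextrel_high: float = -0.25
    distance_method: str = "hamming_normalized"
    # how a species is partitioned once members diverge: "pairwise_diameter"
    # splits whenever any pair exceeds the threshold (members join the nearer
    # of the two most divergent poles, recursively); "connected_components"
    # requires whole subgroups to lose every compatible link first
    speciation_rule: str = "pairwise_diameter"
    # ecology
    thnicheshift: float = -0.5
    preladd: float = 0.01
    preldel: float = 0.01
    link_magnitude: float = 0.5
    # genotype-to-phenotype mapping
    n_traits: int = 8
    max_wraps: int = 8
    max_depth: int = 16  # derivation-tree depth cap; bounds trait complexity
    stagger: int = 4
    trait_grammar: str | None = None    # path; None -> packaged fixture
    fitness_grammar: str | None = None
    # run control
    iterations: int = 5_000_000
    seed: int = 0
    shocks: list = field(default_factory=list)  # list[ShockSpec]
    genotype_sample_every: int = 0  # 0 disables allele-frequency sampling
    occupancy_sample_every: int = 0
    # population-level events (splits, migrations, niche shifts and
    # extinctions that do not end a species) can be omitted from the log to
    # bound memory in large replicate studies; species-level bookkeeping is
    # always complete
    log_population_events: bool = True

    def __post_init__(self):
        self.shocks = [
            s if isinstance(s, ShockSpec) else ShockSpec(**s) for s in self.shocks
        ]

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Raise one ValueError enumerating every invalid field."""
        problems = []
        if self.d1 < 1 or self.d2 < 1:
            problems.append("grid dimensions must be >= 1")
        if self.iterations < 1:
            problems.append("iterations must be >= 1")
        for name in (
            "pregionchange_low", "pregionchange_high", "penvmerge", "penvsplit",
            "pmutp_high", "pmutr_high", "pmutn_high", "pflow_sigma",
            "founder_pflowp", "founder_pflowr", "founder_pflown",
            "pexpp", "pexpr", "pexpn", "popsplit_sigma", "popmig_sigma",
            "founder_ppopsplit", "founder_ppopmig", "thextfit",
            "preladd", "preldel",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.th_speciation_low <= self.th_speciation_high):
            problems.append("speciation threshold fractions must satisfy 0 < low <= high")
        if not (self.thextrel_low <= self.thextrel_high < 0.0):
            problems.append("thextrel range must be negative (low <= high < 0)")
        for name in ("ngenp", "ngenr", "ngenn", "size_gene", "nenv",
                     "size_property", "n_traits", "max_wraps", "max_depth", "stagger"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.distance_method not in ("hamming_normalized", "numeric_absolute"):
            problems.append(f"unknown distance_method {self.distance_method!r}")
        if self.speciation_rule not in ("pairwise_diameter", "connected_components"):
            problems.append(f"unknown speciation_rule {self.speciation_rule!r}")
        for s in self.shocks:
            if s.start < 0 or s.duration < 1 or not (0.0 <= s.pregionchange <= 1.0):
                problems.append(f"invalid shock {s}")
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shocks"] = [asdict(s) for s in self.shocks]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
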
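"""Bit-sequence genomes and their micro-evolutionary operators.

Population genotypes are variable-length bit sequences organised into three
segments: *phenotypic* genes feed the grammar-based genotype-to-phenotype
mapping, *reproductive* genes determine interbreeding compatibility, and
*niche* genes (roles ``n``, ``c``, ``r``) encode the population's position,
optimum and tolerance on an abstract niche gradient.  All operators are pure:
they return fresh genotypes and leave their inputs untouched.

Bits are stored as flat ``numpy`` ``uint8`` arrays (one entry per bit) so the
mutation / gene-flow / duplication operators and the distance measures can be
vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PHENOTYPIC = "phenotypic"
REPRODUCTIVE = "reproductive"
NICHE = "niche"
SEGMENT_KINDS = (PHENOTYPIC, REPRODUCTIVE, NICHE)
NICHE_ROLES = ("n", "c", "r")


def _check_prob(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class Gene:
    """A single gene: an ordered, fixed-length bit sequence."""

    bits: tuple

    def __post_init__(self):
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("gene bits must be 0 or 1")

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass
class GenotypeSegment:
    """One genome segment: a flat bit array plus per-gene bookkeeping.

    ``roles`` is only meaningful for the niche segment, where it assigns each
    gene one of the roles ``n`` (position), ``c`` (optimum) or ``r`` (range).
    """

    kind: str
    bits: np.ndarray  # uint8, length = n_genes * size_gene
    size_gene: int = 8
    roles: list | None = None  # niche segment only

    def __post_init__(self):
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.size % self.size_gene:
            raise ValueError("bit length must be a multiple of size_gene")
        if self.kind == NICHE:
            if self.roles is None or len(self.roles) != self.n_genes:
                raise ValueError("niche segment needs one role per gene")
            for role in NICHE_ROLES:
                if role not in self.roles:
                    raise ValueError(f"niche segment lacks a {role!r}-role gene")
        elif self.roles is not None:
            raise ValueError("only niche segments carry roles")

    @property
    def n_genes(self) -> int:
        return self.bits.size // self.size_gene

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)

    def gene(self, index: int) -> Gene:
        s = index * self.size_gene
        return Gene(tuple(int(b) for b in self.bits[s : s + self.size_gene]))

    def genes(self) -> list:
        return [self.gene(i) for i in range(self.n_genes)]

    def copy(self) -> "GenotypeSegment":
        # bypass __init__/validation: the source segment is already valid
        new = object.__new__(GenotypeSegment)
        new.kind = self.kind
        new.bits = self.bits.copy()
        new.size_gene = self.size_gene
        new.roles = None if self.roles is None else list(self.roles)
        return new

    def mutable_mask(self) -> np.ndarray:
        """Boolean mask of bits that mutation may flip.

        Niche genes with role ``n`` never mutate directly: the niche position
        changes only through ecology-triggered adaptive shifts.
        """
        if self.kind != NICHE:
            return np.ones(self.n_bits, dtype=bool)
        mask = np.ones(self.n_bits, dtype=bool)
        for i, role in enumerate(self.roles):
            if role == "n":
                mask[i * self.size_gene : (i + 1) * self.size_gene] = False
        return mask


@dataclass
class Genotype:
    phenotypic: GenotypeSegment
    reproductive: GenotypeSegment
    niche: GenotypeSegment

    def segment(self, kind: str) -> GenotypeSegment:
        return getattr(self, kind)

    @property
    def n_bits(self) -> int:
        return self.phenotypic.n_bits + self.reproductive.n_bits + self.niche.n_bits

    def copy(self) -> "Genotype":
        new = object.__new__(Genotype)
        new.phenotypic = self.phenotypic.copy()
        new.reproductive = self.reproductive.copy()
        new.niche = self.niche.copy()
        return new


def random_genotype(
    ngenp: int,
    ngenr: int,
    ngenn: int,
    size_gene: int,
    rng: np.random.Generator,
) -> Genotype:
    """Draw a genotype with i.i.d. uniform bits.

    ``ngenn`` counts niche genes *per role*: every genotype carries ``ngenn``
    genes for each of the roles n, c and r (the niche description requires all
    three parameters to be encoded).
    """

    def seg(kind, n_genes, roles=None):
        bits = rng.integers(0, 2, n_genes * size_gene, dtype=np.uint8)
        return GenotypeSegment(kind, bits, size_gene, roles)

    roles = ["n"] * ngenn + ["c"] * ngenn + ["r"] * ngenn
    return Genotype(
        seg(PHENOTYPIC, ngenp),
        seg(REPRODUCTIVE, ngenr),
        seg(NICHE, 3 * ngenn, roles),
    )


# ---------------------------------------------------------------------------
# Micro-evolutionary operators
# ---------------------------------------------------------------------------

def mutate_segment_inplace(
    segment: GenotypeSegment, rate: float, rng: np.random.Generator
) -> int:
    """Flip each mutable bit independently with probability ``rate``.

    Mutates ``segment.bits`` in place and returns the number of flipped bits.
    This is the engine's hot path; :func:`mutate_genotype` wraps it purely.
    """
    _check_prob(rate, "mutation rate")
    if rate == 0.0 or segment.n_bits == 0:
        return 0
    mask = segment.mutable_mask()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return 0
    flips = rng.random(idx.size) < rate
    n = int(flips.sum())
    if n:
        pos = idx[flips]
        segment.bits[pos] ^= 1
    return n


def mutate_genotype(genotype: Genotype, rates: dict, rng: np.random.Generator) -> Genotype:
    """Per-bit Bernoulli mutation with per-segment rates.

    ``rates`` maps ``{"pmutp": ..., "pmutr": ..., "pmutn": ...}`` to the
    phenotypic / reproductive / niche segments.  n-role niche bits never flip.
    """
    out = genotype.copy()
    for key, kind in (("pmutp", PHENOTYPIC), ("pmutr", REPRODUCTIVE), ("pmutn", NICHE)):
        mutate_segment_inplace(out.segment(kind), rates[key], rng)
    return out


def gene_flow_segment_inplace(
    recipient: GenotypeSegment,
    donor: GenotypeSegment,
    prob: float,
    rng: np.random.Generator,
) -> int:
    """Replace recipient genes by donor copies, position by position.

    Only positions present in *both* segments are eligible (the aligned
    prefix); each is exchanged independently with probability ``prob``.
    Returns the number of positions whose bits actually changed.
    """
    _check_prob(prob, "gene flow probability")
    if prob == 0.0:
        return 0
    n = min(recipient.n_genes, donor.n_genes)
    if n == 0:
        return 0
    take = np.flatnonzero(rng.random(n) < prob)
    changed = 0
    g = recipient.size_gene
    for i in take:
        s = i * g
        new = donor.bits[s : s + g]
        if not np.array_equal(recipient.bits[s : s + g], new):
            recipient.bits[s : s + g] = new
            changed += 1
    return changed


def gene_flow(
    recipient: Genotype, donor: Genotype, probs: dict, rng: np.random.Generator
) -> Genotype:
    """Exchange genes between conspecific genotypes, preserving position.

    ``probs`` maps ``{"pflowp", "pflowr", "pflown"}`` to the three segments.
    n-role niche genes *are* exchangeable: gene flow is not mutation.
    """
    out = recipient.copy()
    for key, kind in (("pflowp", PHENOTYPIC), ("pflowr", REPRODUCTIVE), ("pflown", NICHE)):
        gene_flow_segment_inplace(out.segment(kind), donor.segment(kind), probs[key], rng)
    return out


def duplicate_gene_inplace(segment: GenotypeSegment, index: int) -> None:
    """Tandem-duplicate gene ``index``: insert a bit-identical copy after it."""
    g = segment.size_gene
    s = index * g
    segment.bits = np.concatenate(
        [segment.bits[: s + g], segment.bits[s : s + g], segment.bits[s + g :]]
    )
    if segment.roles is not None:
        segment.roles.insert(index + 1, segment.roles[index])


def expand_segment(
    genotype: Genotype, segment_kind: str, pexp: float, rng: np.random.Generator
) -> Genotype:
    """With probability ``pexp``, duplicate one uniformly chosen gene."""
    _check_prob(pexp, "pexp")
    out = genotype.copy()
    if pexp > 0.0 and rng.random() < pexp:
        seg = out.segment(segment_kind)
        duplicate_gene_inplace(seg, int(rng.integers(seg.n_genes)))
    return out


# ---------------------------------------------------------------------------
# Distances and niche decoding
# ---------------------------------------------------------------------------

def hamming_bits(a: GenotypeSegment, b: GenotypeSegment) -> int:
    """Differing-bit count: aligned-prefix mismatches plus surplus length.

    Surplus bits of the longer segment all count as differences, so the
    measure stays valid and comparable after genome expansion.
    """
    la, lb = a.n_bits, b.n_bits
    m = min(la, lb)
    diff = int(np.count_nonzero(a.bits[:m] != b.bits[:m]))
    return diff + abs(la - lb)


def reproductive_distance(
    a: GenotypeSegment, b: GenotypeSegment, method: str = "hamming_normalized"
) -> float:
    """Reproductive divergence between two reproductive segments.

    ``hamming_normalized``: differing bits (prefix mismatches + length
    surplus) over the longer bit length, in [0, 1].  ``numeric_absolute``:
    absolute difference of the unsigned big-endian integers, which weights
    changes in the most significant (leading) bits most heavily.
    """
    if a.n_bits == 0 or b.n_bits == 0:
        raise ValueError("reproductive segments must be non-empty")
    if method == "hamming_normalized":
        return hamming_bits(a, b) / max(a.n_bits, b.n_bits)
    if method == "numeric_absolute":
        return float(abs(bits_to_uint(a.bits) - bits_to_uint(b.bits)))
    raise ValueError(f"unknown distance method {method!r}")


def bits_to_uint(bits: Sequence[int]) -> int:
    """Unsigned big-endian integer over a bit sequence (leading bit first)."""
    value = 0
    for b in bits:
        value = (value << 1) | int(b)
    return value


def niche_values(genotype: Genotype) -> tuple:
    """Decode (n, c, r) as big-endian integers over each role's genes.

    With one 8-bit gene per role the range is 0-255; duplicated role genes
    concatenate, e.g. two n-genes span 0-65535.
    """
    seg = genotype.niche
    out = []
    for role in NICHE_ROLES:
        chunks = [
            seg.bits[i * seg.size_gene : (i + 1) * seg.size_gene]
            for i, r in enumerate(seg.roles)
            if r == role
        ]
        if not chunks:
            raise ValueError(f"niche segment lacks role {role!r}")
        out.append(bits_to_uint(np.concatenate(chunks)))
    return tuple(out)


# ---------------------------------------------------------------------------
# Plain-text serialization (fixtures and logs)
# ---------------------------------------------------------------------------

def genotype_to_text(genotype: Genotype) -> str:
    lines = []
    for kind in SEGMENT_KINDS:
        seg = genotype.segment(kind)
        lines.append(f">{kind}")
        for i in range(seg.n_genes):
            gene = "".join(str(int(b)) for b in seg.bits[i * seg.size_gene : (i + 1) * seg.size_gene])
            if seg.roles is not None:
                lines.append(f"{seg.roles[i]} {gene}")
            else:
                lines.append(gene)
    return "\n".join(lines) + "\n"


def genotype_from_text(text: str, size_gene: int = 8) -> Genotype:
    segments = {}
    kind, bits, roles = None, [], []
    def close():
        if kind is None:
            return
        arr = np.array([int(b) for gene in bits for b in gene], dtype=np.uint8)
        segments[kind] = GenotypeSegment(
            kind, arr, size_gene, roles[:] if kind == NICHE else None
        )
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            close()
            kind, bits, roles = line[1:], [], []
            if kind not in SEGMENT_KINDS:
                raise ValueError(f"unknown segment header {kind!r}")
        else:
            parts = line.split()
            if len(parts) == 2:
                roles.append(parts[0])
                bits.append(parts[1])
            else:
                bits.append(parts[0])
    close()
    missing = [k for k in SEGMENT_KINDS if k not in segments]
    if missing:
        raise ValueError(f"missing segments: {missing}")
    return Genotype(segments[PHENOTYPIC], segments[REPRODUCTIVE], segments[NICHE])
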
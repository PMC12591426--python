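"""Grammatical-evolution machinery: BNF grammars, codon-guided trait
derivation, stochastic fitness-function generation and expressed-gene
accounting.

The phenotypic segment of a genotype is read as a circular stream of
fixed-width *codons*.  A left-most derivation of the trait grammar consumes
one codon at every nonterminal that offers more than one production option,
choosing option ``codon_value mod n_options`` (the canonical grammatical-
evolution rule).  Wrapping past the end of the segment re-reads earlier bits,
so compact genotypes can still express large phenotypes.  Only the codons a
derivation actually consumed make the overlapped genes *expressed*; everything
else is silent, which is what lets genetic drift emerge on non-expressed genes.

Fitness functions are derived from a second grammar, but stochastically at
population initialization (uniform option choices) rather than genetically;
the chosen derivation path is recorded so descendants inherit the function
unchanged.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .bitgenome import GenotypeSegment

# --- safe math primitives available to generated expressions ----------------
# Division, logarithm and exponential are protected so that every expression
# evaluates to a float (possibly +-inf, which the fitness clamp absorbs).

def _div(a, b):
    return a / b if abs(b) > 1e-12 else a

def _plog(x):
    ax = abs(x)
    return math.log(ax) if ax > 1e-300 else -690.0  # ~log(smallest double)

def _pexp(x):
    return math.exp(min(x, 60.0))

def _sim(a, b):
    d = a - b
    return 1.0 / (1.0 + d * d)

def _gauss(a, b):
    # sharp trait-environment match kernel: ~0.1 at |a-b| ~ 0.54
    d = a - b
    return math.exp(-8.0 * min(d * d, 80.0))

def _lin(a, b):
    return 1.0 - abs(a - b)

def _avg(a, b):
    return 0.5 * (a + b)

SAFE_FUNCS = {
    "add": lambda a, b: a + b,
    "sub": lambda a, b: a - b,
    "mul": lambda a, b: a * b,
    "div": _div,
    "sin": math.sin,
    "cos": math.cos,
    "plog": _plog,
    "pexp": _pexp,
    "sim": _sim,
    "gauss": _gauss,
    "lin": _lin,
    "avg": _avg,
    "low": min,
}

_NT_RE = re.compile(r"<[^<>\s]+>")
_TRAIT_RE = re.compile(r"T\((\d)\s*,\s*(\d)\)")
_ENV_RE = re.compile(r"X\((\d)\s*,\s*(\d)\)")


class GrammarError(ValueError):
    pass


@dataclass
class Grammar:
    """A context-free grammar in BNF form, pre-processed for derivation.

    ``productions`` maps each nonterminal to its ordered option list; an
    option is a tuple of tokens, each either ``("nt", name)`` or
    ``("t", text)``.  ``codon_bits`` is the codon width implied by the widest
    rule (two bits suffice for up to four options).  ``best_option`` holds,
    per nonterminal, the option with the smallest terminating depth — used
    for forced termination when depth or wrap budgets run out.
    """

    start: str
    productions: dict
    codon_bits: int = field(init=False)
    min_depth: dict = field(init=False)
    best_option: dict = field(init=False)

    def __post_init__(self):
        if not self.productions:
            raise GrammarError("grammar has no rules")
        for sym, options in self.productions.items():
            if not options:
                raise GrammarError(f"rule {sym!r} has an empty option list")
            for opt in options:
                for kind, tok in opt:
                    if kind == "nt" and tok not in self.productions:
                        raise GrammarError(
                            f"rule {sym!r} references undefined symbol <{tok}>"
                        )
        if self.start not in self.productions:
            raise GrammarError(f"start symbol <{self.start}> undefined")
        widest = max(len(opts) for opts in self.productions.values())
        self.codon_bits = max(1, math.ceil(math.log2(widest)) if widest > 1 else 1)
        self._compute_min_depths()

    def _compute_min_depths(self):
        """Fixpoint of minimal terminating depth per nonterminal.

        A rule with no finite depth can never terminate (every option recurses
        forever) and is rejected, which enforces the termination guarantee.
        """
        INF = math.inf
        depth = {sym: INF for sym in self.productions}
        changed = True
        while changed:
            changed = False
            for sym, options in self.productions.items():
                for opt in options:
                    d = 1 + max(
                        (depth[tok] for kind, tok in opt if kind == "nt"),
                        default=0,
                    )
                    if d < depth[sym]:
                        depth[sym] = d
                        changed = True
        bad = [s for s, d in depth.items() if d == INF]
        if bad:
            raise GrammarError(f"rules with no terminating option: {bad}")
        self.min_depth = depth
        self.best_option = {}
        for sym, options in self.productions.items():
            depths = [
                1 + max((depth[tok] for kind, tok in opt if kind == "nt"), default=0)
                for opt in options
            ]
            self.best_option[sym] = int(np.argmin(depths))


def parse_grammar(text: str) -> Grammar:
    """Parse a BNF-style grammar: ``<sym> ::= option | option | ...``.

    Option order in the file defines the codon-index semantics.  Nonterminals
    are ``<name>`` tokens; all other text is terminal and kept verbatim.
    """
    productions = {}
    start = None
    pending_sym = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if "::=" in line:
            lhs, rhs = line.split("::=", 1)
            lhs = lhs.strip()
            if not (lhs.startswith("<") and lhs.endswith(">")):
                raise GrammarError(f"malformed rule head {lhs!r}")
            pending_sym = lhs[1:-1]
            if start is None:
                start = pending_sym
            productions[pending_sym] = []
        elif pending_sym is None:
            raise GrammarError(f"option line before any rule: {line!r}")
        else:
            rhs = line
        if pending_sym is not None and "::=" in line:
            rhs = line.split("::=", 1)[1]
        for opt_text in rhs.split("|"):
            opt_text = opt_text.strip()
            if not opt_text:
                raise GrammarError(f"empty option in rule <{pending_sym}>")
            tokens = []
            pos = 0
            for m in _NT_RE.finditer(opt_text):
                if m.start() > pos:
                    tokens.append(("t", opt_text[pos : m.start()]))
                tokens.append(("nt", m.group(0)[1:-1]))
                pos = m.end()
            if pos < len(opt_text):
                tokens.append(("t", opt_text[pos:]))
            productions[pending_sym].append(tuple(tokens))
    if start is None:
        raise GrammarError("grammar has no rules")
    return Grammar(start, productions)


def load_packaged_grammar(name: str) -> Grammar:
    """Load one of the packaged grammar fixtures (``trait`` or ``fitness``)."""
    text = resources.files(__package__).joinpath(f"grammars/{name}.bnf").read_text()
    return parse_grammar(text)


# ---------------------------------------------------------------------------
# Codon-guided derivation
# ---------------------------------------------------------------------------

_CODE_CACHE: dict = {}


def _compiled(text: str):
    """Compile-once cache: generated expressions repeat heavily."""
    code = _CODE_CACHE.get(text)
    if code is None:
        if len(_CODE_CACHE) > 100_000:
            _CODE_CACHE.clear()
        code = compile(text, "<ge>", "eval")
        _CODE_CACHE[text] = code
    return code


@dataclass
class TraitExpression:
    """A derived phenotypic trait: a math expression over environment inputs."""

    text: str
    code: object  # compiled code object

    def evaluate(self, env: np.ndarray) -> float:
        ns = dict(SAFE_FUNCS)
        n = len(env)
        ns["X"] = lambda a, b, _e=env, _n=n: float(_e[(4 * a + b) % _n])
        try:
            return float(eval(self.code, {"__builtins__": {}}, ns))
        except (ArithmeticError, ValueError):
            return math.nan


@dataclass
class PhenotypeProfile:
    traits: list  # list[TraitExpression]
    consumed_codons: list  # per trait: list[(bit offset mod L, codon value)]
    consumed_positions: list  # per trait: frozenset of absolute bit offsets read
    expressed_by_trait: list  # per trait: frozenset of gene indices
    expressed_gene_indices: frozenset

    def trait_values(self, env: np.ndarray) -> list:
        ns = dict(SAFE_FUNCS)
        n = len(env)
        ns["X"] = lambda a, b, _e=env, _n=n: float(_e[(4 * a + b) % _n])
        out = []
        for t in self.traits:
            try:
                out.append(float(eval(t.code, {"__builtins__": {}}, ns)))
            except (ArithmeticError, ValueError):
                out.append(math.nan)
        return out


def _derive_tokens(grammar, bits, L, offset, max_wraps, max_depth):
    """Left-most derivation of one trait, returning (text, consumed codons).

    ``bits`` is the circular bit stream as a plain list.  At each branching
    nonterminal the ``codon_bits`` bits at the current offset pick the option
    ``value mod n_options``; single-option rules consume nothing.  When the
    recursion depth exceeds ``max_depth`` or the stream has wrapped
    ``max_wraps`` times, remaining nonterminals expand through their
    fastest-terminating option without consuming codons, forcing termination.
    """
    cb = grammar.codon_bits
    budget = max_wraps * L  # total bits we may read
    consumed = []
    out = []
    read = 0
    # stack of (token, depth); left-most order => push reversed
    stack = [(("nt", grammar.start), 0)]
    prods = grammar.productions
    best = grammar.best_option
    while stack:
        (kind, tok), depth = stack.pop()
        if kind == "t":
            out.append(tok)
            continue
        options = prods[tok]
        k = len(options)
        if k == 1:
            choice = 0
        elif depth >= max_depth or read + cb > budget:
            choice = best[tok]
        else:
            start = (offset + read) % L
            value = 0
            for j in range(cb):
                p = start + j
                value = (value << 1) | bits[p - L if p >= L else p]
            read += cb
            consumed.append((start, value))
            choice = value % k
        d1 = depth + 1
        for item in reversed(options[choice]):
            stack.append((item, d1))
    return "".join(out), consumed


def _derive_one(grammar, bits, L, size_gene, offset, max_wraps, max_depth):
    text, consumed = _derive_tokens(grammar, bits, L, offset, max_wraps, max_depth)
    cb = grammar.codon_bits
    positions = set()
    genes = set()
    for off, _val in consumed:
        for k in range(cb):
            p = (off + k) % L
            positions.add(p)
            genes.add(p // size_gene)
    return (
        TraitExpression(text, _compiled(text)),
        consumed,
        frozenset(positions),
        frozenset(genes),
    )


def derive_traits(
    phenotypic_segment: GenotypeSegment,
    grammar: Grammar,
    n_traits: int = 8,
    max_wraps: int = 8,
    max_depth: int = 32,
    stagger: int = 4,
) -> PhenotypeProfile:
    """Derive the full phenotype: one expression per trait.

    Trait ``t`` starts reading the circular bit stream at offset
    ``t * size_gene * stagger`` bits, so distinct traits consume shifted
    (possibly overlapping) codon windows of the same segment.  The derivation
    is a pure function of the segment bits, the grammar and the limits.
    """
    bits = phenotypic_segment.bits
    if bits.size < grammar.codon_bits:
        raise ValueError("phenotypic segment shorter than one codon")
    g = phenotypic_segment.size_gene
    L = bits.size
    stream = bits.tolist()
    traits, consumed_all, positions_all, expressed = [], [], [], []
    for t in range(n_traits):
        offset = (t * g * stagger) % L
        trait, consumed, positions, genes = _derive_one(
            grammar, stream, L, g, offset, max_wraps, max_depth
        )
        traits.append(trait)
        consumed_all.append(consumed)
        positions_all.append(positions)
        expressed.append(genes)
    union = frozenset().union(*expressed) if expressed else frozenset()
    return PhenotypeProfile(traits, consumed_all, positions_all, expressed, union)


def update_profile(
    profile: PhenotypeProfile,
    phenotypic_segment: GenotypeSegment,
    grammar: Grammar,
    changed_bits,
    max_wraps: int = 8,
    max_depth: int = 32,
    stagger: int = 4,
) -> list:
    """Re-derive only the traits whose consumed codons overlap changed bits.

    A derivation reads exactly the bit positions recorded in
    ``consumed_positions``; flipping any other bit cannot alter the
    derivation path, so those traits are provably unchanged.  Returns the
    indices of traits whose expression actually changed.  ``changed_bits``
    of ``None`` (segment length changed) forces a full re-derivation.
    """
    bits = phenotypic_segment.bits
    g = phenotypic_segment.size_gene
    L = bits.size
    n_traits = len(profile.traits)
    if changed_bits is None:
        affected = range(n_traits)
    else:
        affected = [
            t for t in range(n_traits)
            if not changed_bits.isdisjoint(profile.consumed_positions[t])
        ]
        if not affected:
            return []
    stream = bits.tolist()
    changed = []
    for t in affected:
        offset = (t * g * stagger) % L
        trait, consumed, positions, genes = _derive_one(
            grammar, stream, L, g, offset, max_wraps, max_depth
        )
        if (
            trait.text != profile.traits[t].text
            or consumed != profile.consumed_codons[t]
        ):
            changed.append(t)
        profile.traits[t] = trait
        profile.consumed_codons[t] = consumed
        profile.consumed_positions[t] = positions
        profile.expressed_by_trait[t] = genes
    profile.expressed_gene_indices = frozenset().union(*profile.expressed_by_trait)
    return changed


# ---------------------------------------------------------------------------
# Fitness functions
# ---------------------------------------------------------------------------

@dataclass
class FitnessFunction:
    """A stochastic grammar-derived map (traits, environment) -> [0, 1].

    ``path`` records the option chosen at every branching nonterminal, in
    derivation order, so the exact function can be rebuilt or inherited by
    daughter populations.  Output is clamped to [0, 1]; NaN maps to 0.
    """

    text: str
    code: object
    path: tuple
    trait_indices: frozenset

    def evaluate(self, trait_values, env: np.ndarray) -> float:
        ns = dict(SAFE_FUNCS)
        n = len(env)
        nt = len(trait_values)
        ns["X"] = lambda a, b, _e=env, _n=n: float(_e[(4 * a + b) % _n])
        ns["T"] = lambda a, b, _t=trait_values, _n=nt: float(_t[(4 * a + b) % _n])
        try:
            value = float(eval(self.code, {"__builtins__": {}}, ns))
        except (ArithmeticError, ValueError):
            return 0.0
        if math.isnan(value):
            return 0.0
        return min(1.0, max(0.0, value))


def _derive_random(grammar, rng, max_depth, path=None):
    """Depth-limited derivation with uniform (or replayed) option choices."""
    out, chosen = [], []
    replay = list(path) if path is not None else None
    stack = [(("nt", grammar.start), 0)]
    i = 0
    while stack:
        (kind, tok), depth = stack.pop()
        if kind == "t":
            out.append(tok)
            continue
        options = grammar.productions[tok]
        if len(options) == 1:
            choice = 0
        elif depth >= max_depth:
            choice = grammar.best_option[tok]
        elif replay is not None:
            choice = replay[i]
            i += 1
            chosen.append(choice)
        else:
            choice = int(rng.integers(len(options)))
            chosen.append(choice)
        for item in reversed(options[choice]):
            stack.append((item, depth + 1))
    return "".join(out), tuple(chosen)


def _referenced_traits(text: str) -> frozenset:
    return frozenset(4 * int(a) + int(b) for a, b in _TRAIT_RE.findall(text))


def generate_fitness_function(
    fitness_grammar: Grammar,
    rng: np.random.Generator,
    max_depth: int = 32,
    path: tuple | None = None,
) -> FitnessFunction:
    """Generate (or replay, via ``path``) a fitness function.

    The grammar must expose both trait terminals ``T(i,j)`` and environment
    terminals ``X(i,j)``; a grammar lacking either cannot express phenotype-
    environment compatibility and is rejected.
    """
    has_t = has_x = False
    for options in fitness_grammar.productions.values():
        for opt in options:
            for kind, tok in opt:
                if kind == "t":
                    has_t = has_t or "T(" in tok
                    has_x = has_x or "X(" in tok
    if not (has_t and has_x):
        raise GrammarError(
            "fitness grammar must declare trait (T) and environment (X) terminals"
        )
    text, chosen = _derive_random(fitness_grammar, rng, max_depth, path)
    return FitnessFunction(text, _compiled(text), chosen, _referenced_traits(text))


def evaluate_fitness(
    fn: FitnessFunction, profile: PhenotypeProfile, properties: np.ndarray
) -> float:
    """Fitness of a phenotype in a region with normalized properties in [0,1].

    Traits are evaluated on the property vector first, then fed to the
    fitness expression; the result is clamped to [0, 1] with NaN -> 0.
    """
    return fn.evaluate(profile.trait_values(properties), properties)


_EVAL_NS = {**SAFE_FUNCS, "__builtins__": {}}


def evaluate_population(fn: FitnessFunction, profile: PhenotypeProfile, env: np.ndarray):
    """(trait values, fitness) with one shared namespace — the engine hot path.

    Identical semantics to :func:`evaluate_fitness`, but trait and fitness
    expressions are evaluated in one reused namespace instead of rebuilding
    the primitive table per expression.
    """
    ns = _EVAL_NS
    elist = env.tolist()
    n = len(elist)
    ns["X"] = lambda a, b: elist[(4 * a + b) % n]
    values = []
    for t in profile.traits:
        try:
            values.append(float(eval(t.code, ns)))
        except (ArithmeticError, ValueError):
            values.append(math.nan)
    nt = len(values)
    ns["T"] = lambda a, b: values[(4 * a + b) % nt]
    try:
        value = float(eval(fn.code, ns))
    except (ArithmeticError, ValueError):
        return values, 0.0
    if math.isnan(value):
        return values, 0.0
    return values, min(1.0, max(0.0, value))


def classify_genes(profile: PhenotypeProfile, fn: FitnessFunction, n_genes: int) -> list:
    """Partition phenotypic genes by their evolutionary exposure.

    ``fitness_influencing``: expressed in a trait the fitness function reads;
    ``expressed_non_fitness``: expressed only in ignored traits;
    ``non_expressed``: touched by no consumed codon (selectively neutral).
    """
    n_traits = len(profile.traits)
    used = {i % n_traits for i in fn.trait_indices}
    influencing, expressed = set(), set()
    for t, genes in enumerate(profile.expressed_by_trait):
        expressed |= genes
        if t in used:
            influencing |= genes
    classes = []
    for g in range(n_genes):
        if g in influencing:
            classes.append("fitness_influencing")
        elif g in expressed:
            classes.append("expressed_non_fitness")
        else:
            classes.append("non_expressed")
    return classes
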
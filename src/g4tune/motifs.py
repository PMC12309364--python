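"""Combinatorial design of synthetic G-quadruplex (G4) motifs.

A G4 motif is an alternating arrangement of guanine tracts (G-tracts) and
non-G loops: ``G{t} L1 G{t} L2 ... G{t}``.  Libraries are enumerated under two
full-factorial strategies — (i) fixed tract number, varying tract length and
loop length; (ii) fixed loop length, varying tract length and tract number —
and loop sequences are realized either with a balanced A:T(:U):C composition
or as a single fixed permutation repeated in every loop.  Disabled control
motifs carry the minimum number of G-to-A substitutions that abolishes
detection by the package's quadruplex-propensity scanner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence


class Level(str, Enum):
    """Nucleic-acid level at which a motif operates.

    DNA-level motifs act in the core promoter (template strand, tuning
    transcription); RNA-level motifs act in the 5'UTR of the transcript
    (tuning translation).
    """

    DNA = "DNA"
    RNA = "RNA"

    @property
    def keto_base(self) -> str:
        """'T' for DNA-level motifs, 'U' for RNA-level motifs."""
        return "T" if self is Level.DNA else "U"


#: Default full-factorial design, strategy (i): four G-tracts, tract length
#: 2-6 nt, uniform loop length 1-5 nt.
STRATEGY_I_DEFAULTS = {
    "tract_count": 4,
    "tract_lengths": range(2, 7),
    "loop_lengths": range(1, 6),
}

#: Default full-factorial design, strategy (ii): 2-nt loops, tract length
#: 2-6 nt, 4-7 G-tracts.
STRATEGY_II_DEFAULTS = {
    "loop_length": 2,
    "tract_lengths": range(2, 7),
    "tract_counts": range(4, 8),
}

#: Loop alphabet (DNA rendering).  Loops never contain G, so they cannot
#: extend or create G-tracts.
LOOP_ALPHABET = ("A", "T", "C")


@dataclass(frozen=True)
class G4MotifSpec:
    """Design parameters of one G4 motif.

    Parameters
    ----------
    level : Level
        DNA or RNA.
    tract_length : int
        Guanines per G-tract (>= 2).
    tract_count : int
        Number of G-tracts (>= 4; four tracts are the minimum able to form
        a G-tetrad stack from a single strand).
    loop_lengths : tuple of int
        One entry per inter-tract loop, i.e. ``tract_count - 1`` entries,
        each >= 1.
    """

    level: Level
    tract_length: int
    tract_count: int
    loop_lengths: tuple

    def __post_init__(self):
        object.__setattr__(self, "level", Level(self.level))
        object.__setattr__(self, "loop_lengths", tuple(int(x) for x in self.loop_lengths))
        if self.tract_length < 2:
            raise ValueError(f"tract_length must be >= 2, got {self.tract_length}")
        if self.tract_count < 4:
            raise ValueError(f"tract_count must be >= 4, got {self.tract_count}")
        if len(self.loop_lengths) != self.tract_count - 1:
            raise ValueError(
                f"expected {self.tract_count - 1} loop lengths "
                f"(tract_count - 1), got {len(self.loop_lengths)}"
            )
        if any(l < 1 for l in self.loop_lengths):
            raise ValueError(f"every loop length must be >= 1, got {self.loop_lengths}")

    @property
    def length(self) -> int:
        """Total motif length in nucleotides."""
        return self.tract_count * self.tract_length + sum(self.loop_lengths)

    @property
    def mean_loop_length(self) -> float:
        return sum(self.loop_lengths) / len(self.loop_lengths)

    @property
    def features(self) -> tuple:
        """(tract_length, tract_count, mean_loop_length) feature triple."""
        return (self.tract_length, self.tract_count, self.mean_loop_length)


@dataclass(frozen=True)
class G4Motif:
    """A realized G4 motif: spec plus concrete loop sequences.

    ``sequence`` alternates strictly between G-tracts and loops, starting and
    ending with a G-tract; loops contain no G.
    """

    spec: G4MotifSpec
    loop_seqs: tuple
    label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "loop_seqs", tuple(str(s) for s in self.loop_seqs))
        keto = self.spec.level.keto_base
        allowed = {"A", "C", keto}
        if len(self.loop_seqs) != len(self.spec.loop_lengths):
            raise ValueError("one loop sequence required per inter-tract loop")
        for seq, want in zip(self.loop_seqs, self.spec.loop_lengths):
            if len(seq) != want:
                raise ValueError(f"loop {seq!r} does not match designed length {want}")
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"loop {seq!r} contains disallowed bases {sorted(bad)} "
                    f"(loops use {sorted(allowed)} only)"
                )

    @property
    def sequence(self) -> str:
        tract = "G" * self.spec.tract_length
        parts = [tract]
        for loop in self.loop_seqs:
            parts.append(loop)
            parts.append(tract)
        return "".join(parts)

    def with_label(self, label: str) -> "G4Motif":
        return G4Motif(self.spec, self.loop_seqs, label)


@dataclass(frozen=True)
class MutantMotif:
    """A G4-disabled control: the parent motif with minimal G->A substitutions.

    Same length as the parent, differing only at ``substitution_positions``
    (0-based within the motif), each a G replaced by A, and no longer
    detected as a putative quadruplex-forming sequence at the parent's tract
    parameters.
    """

    parent: G4Motif
    sequence: str
    n_substitutions: int
    substitution_positions: tuple

    def __post_init__(self):
        object.__setattr__(
            self, "substitution_positions", tuple(self.substitution_positions)
        )
        parent_seq = self.parent.sequence
        if len(self.sequence) != len(parent_seq):
            raise ValueError("mutant must have the same length as its parent")
        diffs = [i for i, (a, b) in enumerate(zip(parent_seq, self.sequence)) if a != b]
        if tuple(diffs) != self.substitution_positions:
            raise ValueError("substitution_positions do not match the sequence diff")
        for i in diffs:
            if not (parent_seq[i] == "G" and self.sequence[i] == "A"):
                raise ValueError("only G->A substitutions are allowed")
        if self.n_substitutions != len(diffs):
            raise ValueError("n_substitutions inconsistent with sequence")


def _specs_strategy_i(tract_count: int, tract_lengths, loop_lengths, level) -> list:
    """Full factorial over (tract_length, loop_length) at fixed tract count."""
    tract_lengths = sorted(set(int(x) for x in tract_lengths))
    loop_lengths = sorted(set(int(x) for x in loop_lengths))
    if not tract_lengths or not loop_lengths:
        raise ValueError("strategy (i) parameter ranges must be nonempty")
    specs = []
    for tl, ll in itertools.product(tract_lengths, loop_lengths):
        specs.append(
            G4MotifSpec(level, tl, tract_count, (ll,) * (tract_count - 1))
        )
    return specs


def _specs_strategy_ii(loop_length: int, tract_lengths, tract_counts, level) -> list:
    """Full factorial over (tract_length, tract_count) at fixed loop length."""
    tract_lengths = sorted(set(int(x) for x in tract_lengths))
    tract_counts = sorted(set(int(x) for x in tract_counts))
    if not tract_lengths or not tract_counts:
        raise ValueError("strategy (ii) parameter ranges must be nonempty")
    specs = []
    for tl, tc in itertools.product(tract_lengths, tract_counts):
        specs.append(G4MotifSpec(level, tl, tc, (loop_length,) * (tc - 1)))
    return specs


def enumerate_library(
    strategy_i_params: Optional[dict] = None,
    strategy_ii_params: Optional[dict] = None,
    levels: Sequence = (Level.DNA, Level.RNA),
) -> list:
    """Enumerate the synthetic G4 component library.

    The union of the two strategies' full-factorial products, with exact
    duplicate specs (arising where the strategies overlap, e.g. tract count 4
    with 2-nt loops) removed once.  Order is deterministic: for each level,
    strategy (i) specs sorted by (tract_length, loop_length) precede the
    non-duplicate strategy (ii) specs sorted by (tract_length, tract_count).

    With the packaged defaults this yields 40 specs per level — 80 across
    both levels.

    Parameter dicts may be ``None`` (use the default design) or override any
    key of :data:`STRATEGY_I_DEFAULTS` / :data:`STRATEGY_II_DEFAULTS`.  To
    enumerate a single strategy use :func:`enumerate_strategy_i` or
    :func:`enumerate_strategy_ii` directly.
    """
    levels = [Level(l) for l in levels]
    if not levels:
        raise ValueError("at least one level required")
    i_params = dict(STRATEGY_I_DEFAULTS, **(strategy_i_params or {}))
    ii_params = dict(STRATEGY_II_DEFAULTS, **(strategy_ii_params or {}))
    out = []
    for level in levels:
        specs_i = _specs_strategy_i(
            i_params["tract_count"], i_params["tract_lengths"],
            i_params["loop_lengths"], level,
        )
        specs_ii = _specs_strategy_ii(
            ii_params["loop_length"], ii_params["tract_lengths"],
            ii_params["tract_counts"], level,
        )
        seen = set(specs_i)
        merged = list(specs_i)
        for s in specs_ii:
            if s not in seen:
                seen.add(s)
                merged.append(s)
        out.extend(merged)
    return out


def enumerate_strategy_i(level=Level.DNA, **overrides) -> list:
    """Strategy (i) alone: fixed tract count, varying tract and loop length."""
    p = dict(STRATEGY_I_DEFAULTS, **overrides)
    return _specs_strategy_i(p["tract_count"], p["tract_lengths"], p["loop_lengths"], level)


def enumerate_strategy_ii(level=Level.DNA, **overrides) -> list:
    """Strategy (ii) alone: fixed loop length, varying tract length and count."""
    p = dict(STRATEGY_II_DEFAULTS, **overrides)
    return _specs_strategy_ii(p["loop_length"], p["tract_lengths"], p["tract_counts"], level)


def assign_loops(
    spec: G4MotifSpec,
    policy: str = "balanced",
    fixed_loop: Optional[str] = None,
) -> G4Motif:
    """Realize loop sequences for a spec.

    ``balanced``
        Cycle A -> T/U -> C across the concatenated loop positions 5'->3',
        so over all loops the counts of the three bases differ by at most
        one (exactly equal when the total loop length is divisible by 3;
        otherwise earlier alphabet letters receive the extra copies).
    ``fixed``
        Every loop is the supplied ``fixed_loop`` permutation (given over
        {A, T, C}; T is rendered as U for RNA-level motifs).
    """
    if policy == "balanced":
        if fixed_loop is not None:
            raise ValueError("fixed_loop is only meaningful with policy='fixed'")
        keto = spec.level.keto_base
        cycle = ("A", keto, "C")
        flat = [cycle[i % 3] for i in range(sum(spec.loop_lengths))]
        loops, pos = [], 0
        for n in spec.loop_lengths:
            loops.append("".join(flat[pos:pos + n]))
            pos += n
        return G4Motif(spec, tuple(loops))
    if policy == "fixed":
        if fixed_loop is None:
            raise ValueError("policy='fixed' requires a fixed_loop sequence")
        fixed_loop = fixed_loop.upper().replace("U", "T")
        if set(fixed_loop) - set(LOOP_ALPHABET):
            raise ValueError(f"fixed_loop {fixed_loop!r} must use A/T(U)/C only")
        if any(len(fixed_loop) != n for n in spec.loop_lengths):
            raise ValueError(
                f"fixed_loop length {len(fixed_loop)} does not match the "
                f"designed loop lengths {spec.loop_lengths}"
            )
        rendered = fixed_loop.replace("T", spec.level.keto_base)
        return G4Motif(spec, (rendered,) * len(spec.loop_lengths))
    raise ValueError(f"unknown loop policy {policy!r}")


def all_fixed_loop_motifs(spec: G4MotifSpec) -> list:
    """All fixed-loop realizations of ``spec`` over {A, T, C}.

    For 3-nt loops this is the 27-permutation panel used to probe loop
    nucleotide-composition effects.  Ordered lexicographically (A < C < T in
    DNA rendering? no — alphabet order A, C, T as itertools.product over
    sorted letters).
    """
    letters = sorted(LOOP_ALPHABET)  # A, C, T
    n = spec.loop_lengths[0]
    if any(l != n for l in spec.loop_lengths):
        raise ValueError("fixed-loop panels require uniform loop lengths")
    return [
        assign_loops(spec, "fixed", "".join(p))
        for p in itertools.product(letters, repeat=n)
    ]


def design_mutant(
    motif: G4Motif,
    min_tract: Optional[int] = None,
    max_loop: int = 7,
    min_tracts: int = 4,
    max_substitutions: int = 6,
) -> MutantMotif:
    """Minimal G->A disabling mutant of ``motif``.

    Searches exhaustively over substitution counts k = 1, 2, ... up to
    ``max_substitutions``; within each k, candidate G-position sets are tried
    in lexicographic position order, so ties break toward the 5'-most set.
    ``min_tract`` defaults to the parent's designed tract length, so breaking
    any single tract below that length removes it from the scan.

    Raises ``ValueError`` if the motif is not detected to begin with, and
    ``RuntimeError`` if no mutant within the cap disables detection.
    """
    from .pqs import is_pqs_positive  # local import: avoid module cycle

    seq = motif.sequence
    if min_tract is None:
        min_tract = motif.spec.tract_length
    params = dict(min_tract=min_tract, max_loop=max_loop, min_tracts=min_tracts)
    if not is_pqs_positive(seq, **params):
        raise ValueError(
            "motif is already PQS-negative under the given detector parameters"
        )
    g_positions = [i for i, b in enumerate(seq) if b == "G"]
    for k in range(1, max_substitutions + 1):
        for combo in itertools.combinations(g_positions, k):
            chars = list(seq)
            for i in combo:
                chars[i] = "A"
            mutated = "".join(chars)
            if not is_pqs_positive(mutated, **params):
                return MutantMotif(motif, mutated, k, combo)
    raise RuntimeError(
        f"no G->A mutant with <= {max_substitutions} substitutions abolishes "
        f"detection at {params}"
    )


class ComponentNamer:
    """Canonical component naming: ``<LEVEL>.<R>REU`` with collision suffixes.

    R is the measured REU rounded to the nearest 5 (half rounds up).  The
    second, third, ... components registering at the same label gain a
    ``.2``, ``.3``, ... suffix in registration order (e.g. ``DNA.50REU.2``).
    """

    def __init__(self):
        self._counts = {}

    def name(self, level, measured_reu: float) -> str:
        level = Level(level)
        if measured_reu < 0:
            raise ValueError(f"measured REU must be >= 0, got {measured_reu}")
        r = int((measured_reu + 2.5) // 5) * 5
        base = f"{level.value}.{r}REU"
        n = self._counts.get(base, 0) + 1
        self._counts[base] = n
        return base if n == 1 else f"{base}.{n}"


def name_component(motif: G4Motif, measured_reu: float) -> str:
    """Name a single motif in isolation (no collision registry)."""
    return ComponentNamer().name(motif.spec.level, measured_reu)
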
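"""Constrained sequence space for charge-complementary peptide pairs.

The design target is an 11-mer pair (A cationic, B anionic) over a fixed
hydrophobic/polar pattern.  Positions marked ``H`` accept only hydrophobic
residues; positions marked ``P`` accept polar or charged residues (charged
residues are "polar-site occupants").  Each chain carries a fixed number of
hydrophobic, polar and charged residues; chain A carries only positively
charged residues, chain B only negatively charged ones; cysteine, proline
and glycine are excluded everywhere.  Termini are treated as capped, so net
charge counts side chains only.  Positions are 1-based in all reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, InputError
from .scales import AA_ALPHABET

__all__ = [
    "ResidueClassTable",
    "SequencePattern",
    "CompositionConstraint",
    "PeptidePair",
    "ValidationReport",
    "SpaceSize",
    "classify_residue",
    "validate_sequence",
    "validate_pair",
    "random_pair",
    "enumerate_space_size",
    "DEFAULT_PATTERN",
]

DEFAULT_PATTERN = "PPPHPHPHPPP"

_CLASS_LABELS = ("hydrophobic", "polar", "positive", "negative", "excluded")


@dataclass(frozen=True)
class ResidueClassTable:
    """Partition of the residue alphabet into design classes.

    The five sets are pairwise disjoint; the excluded set always contains
    C, P and G.  Histidine is excluded by default because its protonation
    state (and hence charge class) is ambiguous at neutral pH.
    """

    hydrophobic_set: frozenset = frozenset("AVLIMFWY")
    polar_set: frozenset = frozenset("STNQ")
    positive_set: frozenset = frozenset("KR")
    negative_set: frozenset = frozenset("DE")
    excluded_set: frozenset = frozenset("CPGH")

    def __post_init__(self):
        sets = {
            "hydrophobic_set": frozenset(self.hydrophobic_set),
            "polar_set": frozenset(self.polar_set),
            "positive_set": frozenset(self.positive_set),
            "negative_set": frozenset(self.negative_set),
            "excluded_set": frozenset(self.excluded_set),
        }
        for name, s in sets.items():
            object.__setattr__(self, name, s)
            bad = s - set(AA_ALPHABET)
            if bad:
                raise ConfigurationError(
                    f"{name} contains non-standard residues: {sorted(bad)}")
        for (na, a), (nb, b) in itertools.combinations(sets.items(), 2):
            if a & b:
                raise ConfigurationError(
                    f"{na} and {nb} overlap: {sorted(a & b)}")
        if not frozenset("CPG") <= self.excluded_set:
            raise ConfigurationError("excluded_set must contain C, P and G")

    def classify(self, code: str) -> str:
        return classify_residue(code, self)

    @property
    def charged_set(self) -> frozenset:
        return self.positive_set | self.negative_set


@dataclass(frozen=True)
class SequencePattern:
    """Hydrophobic/polar site pattern, a string over {H, P}."""

    pattern: str = DEFAULT_PATTERN

    def __post_init__(self):
        if not self.pattern or set(self.pattern) - {"H", "P"}:
            raise ConfigurationError(
                f"pattern must be a non-empty string over H/P, got {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def h_sites(self) -> tuple:
        """0-based indices of hydrophobic sites."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "H")

    @property
    def p_sites(self) -> tuple:
        """0-based indices of polar/charged sites."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "P")


@dataclass(frozen=True)
class CompositionConstraint:
    """Per-chain residue-class counts and per-chain net formal charges."""

    n_hydrophobic: int = 3
    n_polar: int = 3
    n_charged: int = 5
    charge_a: int = +5
    charge_b: int = -5

    def __post_init__(self):
        if min(self.n_hydrophobic, self.n_polar, self.n_charged) < 0:
            raise ConfigurationError("composition counts must be nonnegative")
        if abs(self.charge_a) != self.n_charged or abs(self.charge_b) != self.n_charged:
            raise ConfigurationError(
                "chain net charges must have magnitude n_charged "
                "(single-sign charged residues per chain)")

    @property
    def length(self) -> int:
        return self.n_hydrophobic + self.n_polar + self.n_charged


@dataclass(frozen=True)
class PeptidePair:
    """The two designed sequences: A cationic, B anionic."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        object.__setattr__(self, "seq_a", str(self.seq_a).upper())
        object.__setattr__(self, "seq_b", str(self.seq_b).upper())

    def chains(self) -> dict:
        return {"A": self.seq_a, "B": self.seq_b}


@dataclass
class ValidationReport:
    ok: bool
    violations: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


@dataclass(frozen=True)
class SpaceSize:
    """Exact combinatorial size of the admissible sequence space."""

    n_single_a: int
    n_single_b: int

    @property
    def n_pairs(self) -> int:
        return self.n_single_a * self.n_single_b


def classify_residue(code: str, table: ResidueClassTable | None = None) -> str:
    """Classify a one-letter residue code into exactly one design class.

    Raises :class:`InputError` for letters outside the 20 standard residues
    and :class:`ConfigurationError` if the table does not cover the code.
    """
    table = table or ResidueClassTable()
    code = str(code).upper()
    if code not in AA_ALPHABET:
        raise InputError(f"unknown residue code {code!r}")
    for label, members in (
        ("hydrophobic", table.hydrophobic_set),
        ("polar", table.polar_set),
        ("positive", table.positive_set),
        ("negative", table.negative_set),
        ("excluded", table.excluded_set),
    ):
        if code in members:
            return label
    raise ConfigurationError(f"residue {code!r} not covered by the class table")


def _charged_class(sign: int) -> str:
    return "positive" if sign > 0 else "negative"


def validate_sequence(
    seq: str,
    charge_sign: int,
    pattern: SequencePattern | None = None,
    comp: CompositionConstraint | None = None,
    table: ResidueClassTable | None = None,
    chain_label: str = "",
) -> list:
    """Return the list of constraint violations for one chain (empty = pass).

    ``charge_sign`` is +1 for the cationic chain, -1 for the anionic one.
    Raises :class:`InputError` if the sequence length does not match the
    pattern length.
    """
    pattern = pattern or SequencePattern()
    comp = comp or CompositionConstraint()
    table = table or ResidueClassTable()
    tag = f"{chain_label}: " if chain_label else ""
    seq = str(seq).upper()
    if len(seq) != len(pattern):
        raise InputError(
            f"{tag}sequence length {len(seq)} != pattern length {len(pattern)}")

    violations = []
    counts = {"hydrophobic": 0, "polar": 0, "charged": 0}
    net_charge = 0
    want_charged = _charged_class(charge_sign)
    for i, (aa, site) in enumerate(zip(seq, pattern.pattern), start=1):
        cls = classify_residue(aa, table)
        if cls == "excluded":
            violations.append(f"{tag}excluded residue {aa} at position {i}")
            continue
        if cls == "hydrophobic":
            counts["hydrophobic"] += 1
            if site != "H":
                violations.append(
                    f"{tag}hydrophobic residue {aa} at polar site {i}")
        elif cls == "polar":
            counts["polar"] += 1
            if site != "P":
                violations.append(f"{tag}polar residue {aa} at hydrophobic site {i}")
        else:  # positive / negative
            counts["charged"] += 1
            net_charge += 1 if cls == "positive" else -1
            if site != "P":
                violations.append(
                    f"{tag}charged residue {aa} at hydrophobic site {i}")
            if cls != want_charged:
                violations.append(
                    f"{tag}{cls} residue {aa} at position {i} on a "
                    f"{want_charged}-only chain")
    for key, want in (("hydrophobic", comp.n_hydrophobic),
                      ("polar", comp.n_polar),
                      ("charged", comp.n_charged)):
        if counts[key] != want:
            violations.append(
                f"{tag}composition: {counts[key]} {key} residues, expected {want}")
    want_net = comp.charge_a if charge_sign > 0 else comp.charge_b
    if net_charge != want_net:
        violations.append(f"{tag}net charge {net_charge:+d}, expected {want_net:+d}")
    return violations


def validate_pair(
    pair: PeptidePair,
    pattern: SequencePattern | None = None,
    comp: CompositionConstraint | None = None,
    table: ResidueClassTable | None = None,
) -> ValidationReport:
    """Validate both chains of a pair against pattern/composition/charge rules."""
    violations = validate_sequence(pair.seq_a, +1, pattern, comp, table, "A")
    violations += validate_sequence(pair.seq_b, -1, pattern, comp, table, "B")
    return ValidationReport(ok=not violations, violations=violations)


def _random_chain(rng: np.random.Generator, charge_sign: int,
                  pattern: SequencePattern, comp: CompositionConstraint,
                  table: ResidueClassTable) -> str:
    charged_pool = sorted(table.positive_set if charge_sign > 0
                          else table.negative_set)
    polar_pool = sorted(table.polar_set)
    hydro_pool = sorted(table.hydrophobic_set)
    p_sites = list(pattern.p_sites)
    h_sites = list(pattern.h_sites)
    if comp.n_charged > len(p_sites):
        raise ConfigurationError(
            f"{comp.n_charged} charged residues do not fit on "
            f"{len(p_sites)} polar sites")
    if comp.n_hydrophobic != len(h_sites):
        raise ConfigurationError(
            f"pattern has {len(h_sites)} H sites but composition requires "
            f"{comp.n_hydrophobic} hydrophobic residues")
    if comp.n_polar + comp.n_charged != len(p_sites):
        raise ConfigurationError(
            "n_polar + n_charged must equal the number of P sites")
    for name, pool, need in (("charged", charged_pool, comp.n_charged),
                             ("polar", polar_pool, comp.n_polar),
                             ("hydrophobic", hydro_pool, comp.n_hydrophobic)):
        if need > 0 and not pool:
            raise ConfigurationError(f"empty {name} residue pool")
    charged_sites = set(rng.choice(p_sites, size=comp.n_charged, replace=False))
    seq = [""] * len(pattern)
    for i in h_sites:
        seq[i] = hydro_pool[rng.integers(len(hydro_pool))]
    for i in p_sites:
        pool = charged_pool if i in charged_sites else polar_pool
        seq[i] = pool[rng.integers(len(pool))]
    return "".join(seq)


def random_pair(
    rng_seed: int | None = None,
    pattern: SequencePattern | None = None,
    comp: CompositionConstraint | None = None,
    table: ResidueClassTable | None = None,
    rng: np.random.Generator | None = None,
) -> PeptidePair:
    """Draw a uniformly random admissible pair; deterministic per seed."""
    pattern = pattern or SequencePattern()
    comp = comp or CompositionConstraint()
    table = table or ResidueClassTable()
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    pair = PeptidePair(
        seq_a=_random_chain(rng, +1, pattern, comp, table),
        seq_b=_random_chain(rng, -1, pattern, comp, table),
    )
    report = validate_pair(pair, pattern, comp, table)
    assert report.ok, report.violations  # construction guarantees validity
    return pair


def enumerate_space_size(
    pattern: SequencePattern | None = None,
    comp: CompositionConstraint | None = None,
    table: ResidueClassTable | None = None,
) -> SpaceSize:
    """Exact count of admissible single-chain sequences and of A-B pairs.

    The count is the closed-form product: choose which P sites carry charge,
    then independent residue choices per site class.
    """
    pattern = pattern or SequencePattern()
    comp = comp or CompositionConstraint()
    table = table or ResidueClassTable()
    n_p = len(pattern.p_sites)
    n_h = len(pattern.h_sites)
    if comp.n_hydrophobic != n_h or comp.n_polar + comp.n_charged != n_p:
        return SpaceSize(0, 0)

    def chain_count(charged_pool_size: int) -> int:
        return (comb(n_p, comp.n_charged)
                * charged_pool_size ** comp.n_charged
                * len(table.polar_set) ** comp.n_polar
                * len(table.hydrophobic_set) ** comp.n_hydrophobic)

    return SpaceSize(chain_count(len(table.positive_set)),
                     chain_count(len(table.negative_set)))


def brute_force_space(
    pattern: SequencePattern,
    comp: CompositionConstraint,
    table: ResidueClassTable,
    charge_sign: int = +1,
) -> Iterable[str]:
    """Enumerate every admissible single-chain sequence by exhaustion.

    Intended for toy alphabets/lengths as an independent check of
    :func:`enumerate_space_size`; cost is |alphabet|**length.
    """
    alphabet = sorted(table.hydrophobic_set | table.polar_set
                      | (table.positive_set if charge_sign > 0 else table.negative_set))
    for letters in itertools.product(alphabet, repeat=len(pattern)):
        seq = "".join(letters)
        if not validate_sequence(seq, charge_sign, pattern, comp, table):
            yield seq
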
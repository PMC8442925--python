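"""Analysis of multi-chain assembly structures and trajectory frames.

Works on C-alpha-only coordinates: strand direction vectors, parallel vs
antiparallel classification, partitioning of chains into beta sheets,
nearest/next-nearest neighbor identity statistics, A:B composition of
aggregated material, and beta-sheet content over time.  Frames come from
multi-model PDB files (each MODEL = one frame) or are built in memory.

Beta-sheet membership here is a contact/registry definition (aligned
C-alpha pairs within a cutoff), not a dihedral-based one, so coarse
C-alpha-only inputs suffice.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import AnalysisError, InputError
from .scales import RESIDUE_CHARGE, THREE_TO_ONE

__all__ = [
    "ChainRecord",
    "AssemblyFrame",
    "OrientationStats",
    "BetaContentSeries",
    "AnalysisParams",
    "read_frames",
    "strand_vector",
    "classify_pair_orientation",
    "aligned_distance",
    "partition_sheets",
    "neighbor_statistics",
    "composition_ratio",
    "beta_content",
]

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"
UNCLASSIFIED = "unclassified"


@dataclass
class AnalysisParams:
    """Cutoffs of the contact-based sheet/registry analysis (Angstrom)."""

    in_sheet_cutoff: float = 5.5       # mean aligned C-alpha distance
    registry_cutoff: float = 6.0       # per aligned C-alpha pair
    min_aligned: int = 4               # aligned pairs for beta membership
    cos_threshold: float = 0.5
    neighbor_tie_tolerance: float = 1.5  # distance grouping for ranks


@dataclass
class ChainRecord:
    chain_id: str
    species: str                      # "A", "B" or "unknown"
    coords: np.ndarray                # (n_residues, 3)
    sequence: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("chain coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InputError(f"non-finite coordinates in chain {self.chain_id}")


@dataclass
class AssemblyFrame:
    chains: list
    time_stamp: float = 0.0

    def __post_init__(self):
        lengths = {c.coords.shape[0] for c in self.chains}
        if len(lengths) > 1:
            raise InputError(f"chains differ in residue count: {lengths}")

    @property
    def n_chains(self) -> int:
        return len(self.chains)


@dataclass
class OrientationStats:
    """Neighbor-pair tallies keyed by (species-pair label, orientation)."""

    within_nearest: Counter = field(default_factory=Counter)
    within_next_nearest: Counter = field(default_factory=Counter)
    cross_nearest: Counter = field(default_factory=Counter)

    @staticmethod
    def _fraction(counter: Counter, key) -> float:
        total = sum(counter.values())
        return counter[key] / total if total else float("nan")

    def fraction_within_nearest(self, species_pair: str, orient: str) -> float:
        return self._fraction(self.within_nearest, (species_pair, orient))

    def fraction_within_next(self, species_pair: str, orient: str) -> float:
        return self._fraction(self.within_next_nearest, (species_pair, orient))

    def fraction_cross(self, orient: str) -> float:
        total = sum(self.cross_nearest.values())
        if not total:
            return float("nan")
        return sum(v for (_, o), v in self.cross_nearest.items()
                   if o == orient) / total

    def total_pairs(self) -> int:
        return (sum(self.within_nearest.values())
                + sum(self.within_next_nearest.values())
                + sum(self.cross_nearest.values()))


@dataclass
class BetaContentSeries:
    fractions: np.ndarray             # in [0, 1], one per frame
    times: np.ndarray


def _species_from_sequence(seq: str) -> str:
    net = sum(RESIDUE_CHARGE.get(aa, 0.0) for aa in seq)
    if net > 0:
        return "A"
    if net < 0:
        return "B"
    return "unknown"


def read_frames(pdb_path, species_map: dict | None = None) -> list:
    """Read a (multi-model) PDB file into a list of frames.

    Species labels come from ``species_map`` (chain id -> "A"/"B") when
    given, otherwise are inferred from the net side-chain charge of the
    chain's residue sequence.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("error")  # strict: malformed records fail
        structure = PDBParser(QUIET=False).get_structure("frames", str(pdb_path))
    frames = []
    for model in structure:
        chains = []
        for chain in model:
            coords, seq = [], []
            for residue in chain:
                if "CA" not in residue:
                    continue
                coords.append(residue["CA"].coord)
                seq.append(THREE_TO_ONE.get(residue.get_resname(), "X"))
            if not coords:
                continue
            seq = "".join(seq)
            if species_map is not None:
                species = species_map.get(chain.id, "unknown")
            else:
                species = _species_from_sequence(seq)
            chains.append(ChainRecord(chain_id=chain.id, species=species,
                                      coords=np.array(coords), sequence=seq))
        frames.append(AssemblyFrame(chains=chains, time_stamp=float(model.id)))
    return frames


def strand_vector(chain: ChainRecord | np.ndarray) -> np.ndarray:
    """Principal-axis unit vector of a strand's C-alpha trace, signed N->C."""
    coords = chain.coords if isinstance(chain, ChainRecord) else np.asarray(chain)
    if coords.shape[0] < 2:
        raise AnalysisError("strand vector needs at least 2 C-alpha positions")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise AnalysisError("degenerate strand: all C-alpha coincide")
    v = vt[0]
    if np.dot(v, coords[-1] - coords[0]) < 0:
        v = -v
    return v / np.linalg.norm(v)


def classify_pair_orientation(v1: np.ndarray, v2: np.ndarray,
                              cos_threshold: float = 0.5) -> str:
    """Parallel/antiparallel by the sign of the strand-vector dot product."""
    dot = float(np.dot(v1, v2))
    if dot >= cos_threshold:
        return PARALLEL
    if dot <= -cos_threshold:
        return ANTIPARALLEL
    return UNCLASSIFIED


def aligned_distance(ci: np.ndarray, cj: np.ndarray):
    """Best in-register alignment of two equal-length strands.

    Tries direct (i<->i) and reversed (i<->n-1-i) index pairing and keeps
    the one with the smaller mean C-alpha distance.  Returns
    ``(mean_distance, per_residue_distances)``.
    """
    direct = np.linalg.norm(ci - cj, axis=1)
    reverse = np.linalg.norm(ci - cj[::-1], axis=1)
    return (direct.mean(), direct) if direct.mean() <= reverse.mean() \
        else (reverse.mean(), reverse)


def _pairwise_aligned(frame: AssemblyFrame) -> np.ndarray:
    n = frame.n_chains
    d = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            m, _ = aligned_distance(frame.chains[i].coords,
                                    frame.chains[j].coords)
            d[i, j] = d[j, i] = m
    return d


def partition_sheets(frame: AssemblyFrame,
                     params: AnalysisParams | None = None) -> list:
    """Group chains into sheets by in-register proximity.

    Chains are linked when their mean aligned C-alpha distance is below the
    in-sheet cutoff; connected components are sheets.  Sheets are ordered by
    their lowest chain index, isolated chains form singleton sheets.
    """
    params = params or AnalysisParams()
    n = frame.n_chains
    if n == 0:
        return []
    d = _pairwise_aligned(frame)
    adj = csr_matrix((d < params.in_sheet_cutoff).astype(int))
    _, labels = connected_components(adj, directed=False)
    sheets = {}
    for idx, lab in enumerate(labels):
        sheets.setdefault(lab, []).append(idx)
    return sorted(sheets.values(), key=min)


def _distance_rank_groups(dists: dict, tie_tol: float) -> list:
    """Group neighbor distances into rank tiers (ties within tie_tol)."""
    items = sorted(dists.items(), key=lambda kv: kv[1])
    groups, current, ref = [], [], None
    for idx, dist in items:
        if ref is None or dist - ref <= tie_tol:
            current.append(idx)
            ref = dist if ref is None else ref
        else:
            groups.append(current)
            current, ref = [idx], dist
    if current:
        groups.append(current)
    return groups


def _species_pair_label(a: str, b: str) -> str:
    return "".join(sorted((a, b)))


def neighbor_statistics(frame: AssemblyFrame,
                        partition: list | None = None,
                        params: AnalysisParams | None = None) -> OrientationStats:
    """Species/orientation tallies of nearest and next-nearest neighbors.

    For every chain the same-sheet neighbors are ranked by mean aligned
    C-alpha distance (distances closer than the tie tolerance share a rank);
    the first tier is "nearest", the second "next-nearest".  The nearest
    chain on any other sheet gives the cross-sheet tally.  Each unordered
    pair is counted once; a pair seen as nearest by either member is not
    also counted as next-nearest.
    """
    params = params or AnalysisParams()
    if partition is None:
        partition = partition_sheets(frame, params)
    d = _pairwise_aligned(frame)
    vectors = [strand_vector(c) for c in frame.chains]
    sheet_of = {}
    for s_idx, members in enumerate(partition):
        for c in members:
            sheet_of[c] = s_idx

    nearest_pairs, next_pairs, cross_pairs = set(), set(), set()
    for members in partition:
        for c in members:
            same = {o: d[c, o] for o in members if o != c}
            groups = _distance_rank_groups(same, params.neighbor_tie_tolerance)
            if groups:
                nearest_pairs.update(frozenset((c, o)) for o in groups[0])
            if len(groups) > 1:
                next_pairs.update(frozenset((c, o)) for o in groups[1])
    for c in range(frame.n_chains):
        others = {o: d[c, o] for o in range(frame.n_chains)
                  if sheet_of.get(o) != sheet_of.get(c)}
        if others:
            nearest = min(others, key=others.get)
            cross_pairs.add(frozenset((c, nearest)))
    next_pairs -= nearest_pairs

    stats = OrientationStats()
    for pairs, counter in ((nearest_pairs, stats.within_nearest),
                           (next_pairs, stats.within_next_nearest),
                           (cross_pairs, stats.cross_nearest)):
        for pair in pairs:
            i, j = sorted(pair)
            label = _species_pair_label(frame.chains[i].species,
                                        frame.chains[j].species)
            orient = classify_pair_orientation(vectors[i], vectors[j],
                                               params.cos_threshold)
            counter[(label, orient)] += 1
    return stats


def composition_ratio(frames, params: AnalysisParams | None = None):
    """A:B ratio among aggregated chains (members of sheets of size >= 2).

    Accepts one frame or a list of frames (counts pooled).  Returns the
    ratio as a float, or ``None`` when no aggregated B chains exist.
    """
    params = params or AnalysisParams()
    if isinstance(frames, AssemblyFrame):
        frames = [frames]
    n_a = n_b = 0
    for frame in frames:
        for members in partition_sheets(frame, params):
            if len(members) < 2:
                continue
            for c in members:
                species = frame.chains[c].species
                if species == "A":
                    n_a += 1
                elif species == "B":
                    n_b += 1
    if n_b == 0:
        return None
    return n_a / n_b


def beta_content(frames, params: AnalysisParams | None = None) -> BetaContentSeries:
    """Fraction of chains participating in inter-strand registry, per frame.

    A chain is in-sheet when at least one other chain has >= ``min_aligned``
    aligned C-alpha pairs within the registry cutoff.
    """
    params = params or AnalysisParams()
    if isinstance(frames, AssemblyFrame):
        frames = [frames]
    if not frames:
        raise InputError("beta_content requires at least one frame")
    fractions, times = [], []
    for frame in frames:
        n = frame.n_chains
        in_sheet = np.zeros(n, dtype=bool)
        for i in range(n):
            for j in range(n):
                if i == j or in_sheet[i]:
                    continue
                _, dists = aligned_distance(frame.chains[i].coords,
                                            frame.chains[j].coords)
                if int((dists < params.registry_cutoff).sum()) >= params.min_aligned:
                    in_sheet[i] = True
        fractions.append(in_sheet.mean() if n else 0.0)
        times.append(frame.time_stamp)
    return BetaContentSeries(fractions=np.array(fractions),
                             times=np.array(times))
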
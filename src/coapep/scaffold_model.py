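"""Idealized two-layer antiparallel beta-sheet fibril scaffold.

The scaffold is the fixed backbone used during sequence design: two stacked
beta sheets, each an array of straight 11-residue strands.  Adjacent strands
within a sheet run antiparallel; strands in register across the sheets run
parallel; species alternate A,B,A,B,... along each sheet.  Strands carry no
twist or pleat curvature -- only relative distances enter the score, so the
idealization is exact for scoring purposes.

Geometry conventions (default build):
  * strand axis along x, C-alpha spacing 3.5 A;
  * strands stacked along y at 4.8 A within a sheet;
  * sheets stacked along z at 10.0 A separation;
  * side-chain centroids displaced from the C-alpha along +/-z with
    alternating pleat parity; the displacement magnitude is the per-residue
    canonical centroid distance, so centroid coordinates depend on the
    threaded sequence.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .scales import AA_THREE, SIDECHAIN_CENTROID_DISTANCE
from .sequence_space import PeptidePair

__all__ = [
    "ScaffoldGeometry",
    "Slot",
    "FibrilScaffold",
    "build_scaffold",
    "write_scaffold_pdb",
]


@dataclass(frozen=True)
class ScaffoldGeometry:
    """Dimensions of the idealized fibril lattice (Angstrom)."""

    strand_spacing: float = 4.8      # inter-strand, within sheet
    sheet_separation: float = 10.0   # sheet-to-sheet
    ca_spacing: float = 3.5          # along the strand
    n_strands_per_sheet: int = 6
    n_sheets: int = 2
    n_residues: int = 11

    def __post_init__(self):
        if min(self.strand_spacing, self.sheet_separation, self.ca_spacing) <= 0:
            raise ConfigurationError("all scaffold distances must be positive")
        if self.n_sheets < 1 or self.n_strands_per_sheet < 1 or self.n_residues < 2:
            raise ConfigurationError("scaffold counts out of range")


@dataclass(frozen=True)
class Slot:
    """One strand position in the lattice."""

    sheet: int
    strand: int
    orientation: int   # +1 / -1 along the strand axis (N -> C)
    species: str       # "A" or "B"


_CHAIN_IDS = string.ascii_uppercase + string.digits + string.ascii_lowercase


@dataclass
class FibrilScaffold:
    """Slot lattice plus backbone coordinates and centroid directions."""

    geometry: ScaffoldGeometry
    slots: list
    ca_coords: np.ndarray          # (n_slots, n_residues, 3)
    centroid_dirs: np.ndarray      # (n_slots, n_residues, 3) unit vectors
    hbond_registry: list = field(default_factory=list)  # [(slot_i, slot_j)]

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def n_residues(self) -> int:
        return self.ca_coords.shape[1]

    def sequences(self, pair: PeptidePair) -> list:
        """Thread the pair onto the lattice: one sequence per slot."""
        chains = pair.chains()
        return [chains[s.species] for s in self.slots]

    def centroid_positions(self, pair: PeptidePair,
                           distances: dict | None = None) -> np.ndarray:
        """Side-chain centroid coordinates for a threaded pair, (S, R, 3)."""
        distances = distances or SIDECHAIN_CENTROID_DISTANCE
        seqs = self.sequences(pair)
        d = np.array([[distances[aa] for aa in seq] for seq in seqs])
        return self.ca_coords + self.centroid_dirs * d[:, :, None]

    def sheet_indices(self) -> np.ndarray:
        return np.array([s.sheet for s in self.slots])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "FibrilScaffold":
        """Rigidly transformed copy (coordinates and centroid directions)."""
        ca = self.ca_coords
        dirs = self.centroid_dirs
        if rotation is not None:
            rotation = np.asarray(rotation, dtype=float)
            ca = ca @ rotation.T
            dirs = dirs @ rotation.T
        if translation is not None:
            ca = ca + np.asarray(translation, dtype=float)
        return replace(self, ca_coords=ca, centroid_dirs=dirs,
                       slots=list(self.slots),
                       hbond_registry=list(self.hbond_registry))

    def permuted(self, order) -> "FibrilScaffold":
        """Copy with slots re-enumerated in ``order`` (a permutation)."""
        order = list(order)
        inv = {old: new for new, old in enumerate(order)}
        return replace(
            self,
            slots=[self.slots[i] for i in order],
            ca_coords=self.ca_coords[order],
            centroid_dirs=self.centroid_dirs[order],
            hbond_registry=[(inv[i], inv[j]) for i, j in self.hbond_registry],
        )


def build_scaffold(geometry: ScaffoldGeometry | None = None,
                   antiparallel_within_sheet: bool = True,
                   alternate_species: bool = True) -> FibrilScaffold:
    """Construct the idealized lattice.

    The default build realizes the target architecture exactly: adjacent
    in-sheet strands antiparallel, cross-sheet in-register strands parallel
    (orientation depends only on the strand index), species alternating
    A,B,A,B,... identically in every sheet.
    """
    g = geometry or ScaffoldGeometry()
    if alternate_species and g.n_strands_per_sheet < 2:
        raise ConfigurationError(
            "species alternation requires at least 2 strands per sheet")
    slots, ca_all, dir_all = [], [], []
    center = (g.n_residues - 1) / 2.0
    for s in range(g.n_sheets):
        # Centroids on even sheets point +z, odd sheets -z, so the two
        # sheets of the default build face each other (steric-zipper core).
        inward = 1.0 if s % 2 == 0 else -1.0
        for t in range(g.n_strands_per_sheet):
            orientation = -1 if (antiparallel_within_sheet and t % 2) else 1
            species = "B" if (alternate_species and t % 2) else "A"
            slots.append(Slot(sheet=s, strand=t, orientation=orientation,
                              species=species))
            i = np.arange(g.n_residues)
            ca = np.zeros((g.n_residues, 3))
            ca[:, 0] = orientation * (i - center) * g.ca_spacing
            ca[:, 1] = t * g.strand_spacing
            ca[:, 2] = s * g.sheet_separation
            dirs = np.zeros((g.n_residues, 3))
            dirs[:, 2] = inward * (-1.0) ** i
            ca_all.append(ca)
            dir_all.append(dirs)
    registry = []
    for s in range(g.n_sheets):
        base = s * g.n_strands_per_sheet
        for t in range(g.n_strands_per_sheet - 1):
            registry.append((base + t, base + t + 1))
    return FibrilScaffold(geometry=g, slots=slots,
                          ca_coords=np.array(ca_all),
                          centroid_dirs=np.array(dir_all),
                          hbond_registry=registry)


def write_scaffold_pdb(scaffold: FibrilScaffold, pair: PeptidePair,
                       path) -> Path:
    """Write the threaded scaffold as a coarse PDB file.

    One chain per slot; each residue carries its C-alpha plus a CB
    pseudo-atom at the side-chain centroid.  Chain IDs enumerate slots in
    sheet-major order so the file round-trips through the assembly reader.
    """
    from Bio.PDB import PDBIO
    from Bio.PDB.StructureBuilder import StructureBuilder

    if scaffold.n_slots > len(_CHAIN_IDS):
        raise ConfigurationError("too many slots for single-character chain IDs")
    seqs = scaffold.sequences(pair)
    centroids = scaffold.centroid_positions(pair)
    builder = StructureBuilder()
    builder.init_structure("fibril")
    builder.init_model(0)
    for k, slot in enumerate(scaffold.slots):
        builder.init_chain(_CHAIN_IDS[k])
        builder.init_seg("    ")
        for r, aa in enumerate(seqs[k]):
            builder.init_residue(AA_THREE[aa], " ", r + 1, " ")
            builder.init_atom("CA", scaffold.ca_coords[k, r].astype(float),
                              0.0, 1.0, " ", " CA ", element="C")
            builder.init_atom("CB", centroids[k, r].astype(float),
                              0.0, 1.0, " ", " CB ", element="C")
    io = PDBIO()
    io.set_structure(builder.get_structure())
    path = Path(path)
    io.save(str(path))
    return path
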
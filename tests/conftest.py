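"""Shared fixtures and the independent brute-force energy oracle."""

from __future__ import annotations

import numpy as np
import pytest

from coapep.scales import AA_ALPHABET, RESIDUE_CHARGE, dielectric_class
from coapep.scaffold_model import ScaffoldGeometry, build_scaffold
from coapep.sequence_space import (CompositionConstraint, ResidueClassTable,
                                   SequencePattern)
from coapep.fixtures import DESIGN_PAIRS

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@pytest.fixture
def table():
    return ResidueClassTable()


@pytest.fixture
def pattern():
    return SequencePattern()


@pytest.fixture
def comp():
    return CompositionConstraint()


@pytest.fixture
def design4():
    return DESIGN_PAIRS[4]


@pytest.fixture
def scaffold():
    return build_scaffold()


@pytest.fixture
def small_scaffold():
    return build_scaffold(ScaffoldGeometry(n_strands_per_sheet=4, n_sheets=2))


def brute_force_binding(pair, scaffold, params):
    """All-pairs double-loop energy oracle, independent of the vectorized path.

    Recomputes every term with explicit Python loops from the scaffold
    geometry and the parameter set; used only to cross-check
    ``scoring.binding_energy``.
    """
    seqs = scaffold.sequences(pair)
    centroids = scaffold.centroid_positions(pair, params.centroid_distances)
    residues = []  # (slot, aa, xyz)
    for k, seq in enumerate(seqs):
        for r, aa in enumerate(seq):
            residues.append((k, aa, centroids[k, r]))

    e_hbond = (params.hbond_energy * params.hbonds_per_neighbor_pair
               * len(scaffold.hbond_registry))
    e_contact = 0.0
    e_elec = 0.0
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            k1, aa1, p1 = residues[a]
            k2, aa2, p2 = residues[b]
            if k1 == k2:
                continue
            d = float(np.sqrt(((p1 - p2) ** 2).sum()))
            if d <= params.contact_cutoff:
                e_contact += params.contact_table[_AA_INDEX[aa1],
                                                  _AA_INDEX[aa2]]
            q1, q2 = RESIDUE_CHARGE[aa1], RESIDUE_CHARGE[aa2]
            if q1 != 0.0 and q2 != 0.0:
                eps = max(params.dielectric_by_class[dielectric_class(aa1)],
                          params.dielectric_by_class[dielectric_class(aa2)])
                e_elec += params.coulomb_constant * q1 * q2 / (eps * d)

    sheets = sorted({s.sheet for s in scaffold.slots})
    n_buried = 0
    if len(sheets) >= 2:
        centers = []
        for s in sheets:
            pts = [scaffold.ca_coords[k, r]
                   for k, slot in enumerate(scaffold.slots)
                   if slot.sheet == s
                   for r in range(scaffold.n_residues)]
            centers.append(np.mean(pts, axis=0))
        axis = centers[-1] - centers[0]
        axis = axis / np.linalg.norm(axis)
        lo = float(centers[0] @ axis) + params.burial_margin
        hi = float(centers[-1] @ axis) - params.burial_margin
        for _, aa, p in residues:
            if RESIDUE_CHARGE[aa] != 0.0 and lo + 1e-9 < float(p @ axis) < hi - 1e-9:
                n_buried += 1
    e_desolv = params.desolvation_penalty * n_buried

    total = e_hbond + e_contact + e_elec + e_desolv
    return total / scaffold.n_slots, {
        "hbond": e_hbond, "contact": e_contact, "electrostatic": e_elec,
        "desolvation": e_desolv, "n_buried_charged": n_buried,
    }
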
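"""Design score: binding energy on the fibril scaffold plus intrinsic
self-aggregation propensity.

The objective minimized during sequence design is

    Gamma = dG_binding + lambda * P_agg

where ``dG_binding`` (kcal/mol, per peptide) is the total interaction energy
of the pair threaded onto the fixed two-layer scaffold divided by the number
of peptides, and ``P_agg`` (dimensionless) is the mean intrinsic
self-aggregation propensity of the two chains.  Lower is better: a strongly
co-binding pair whose individual chains resist self-assembly.

The binding model is a reference architecture with every constant exposed in
:class:`EnergyParams`:

  * a backbone hydrogen-bond term per registered in-sheet strand pair;
  * knowledge-based side-chain contact energies between centroids within a
    cutoff;
  * screened Coulomb electrostatics with a variable internal dielectric,
    eps_ij = max(eps_class(i), eps_class(j)) over {nonpolar, polar, charged}
    environment classes, which damps charge-charge terms relative to
    charge-nonpolar ones and avoids overestimating electrostatics in a
    highly charged interface;
  * a desolvation penalty per charged residue buried in the inter-sheet slab.

Absolute energies from this model are not comparable to atomistic MM/GBSA
numbers; only the combination arithmetic and score orderings are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, StateError
from .scales import (AA_ALPHABET, BETA_PROPENSITY, KYTE_DOOLITTLE,
                     RESIDUE_CHARGE, SIDECHAIN_CENTROID_DISTANCE,
                     dielectric_class)
from .scaffold_model import FibrilScaffold
from .sequence_space import PeptidePair, validate_pair

__all__ = [
    "EnergyParams",
    "AggregationParams",
    "ScoreBreakdown",
    "default_contact_table",
    "load_contact_table",
    "combine_score",
    "binding_energy",
    "aggregation_propensity",
    "pair_aggregation",
    "score_pair",
]

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def default_contact_table() -> np.ndarray:
    """Symmetric 20x20 side-chain contact energies (kcal/mol).

    Hydrophobic-hydrophobic contacts attract in proportion to the product of
    normalized hydropathies; uncharged-polar pairs get a small hydrogen-bond
    bonus (the N/T carboxamide-hydroxyl motif).  Rows/columns follow
    ``scales.AA_ALPHABET`` order.
    """
    h = np.array([(KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in AA_ALPHABET])
    table = -0.8 * np.outer(h, h)
    polar = np.array([aa in "STNQY" for aa in AA_ALPHABET])
    table = table - 0.25 * np.outer(polar, polar)
    return table


def load_contact_table(path) -> np.ndarray:
    """Read a 20x20 contact table CSV (header row/column of one-letter codes)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    try:
        table = df.loc[list(AA_ALPHABET), list(AA_ALPHABET)].to_numpy(dtype=float)
    except KeyError as exc:
        raise ConfigurationError(f"contact table missing residues: {exc}") from exc
    if not np.allclose(table, table.T):
        raise ConfigurationError("contact table must be symmetric")
    return table


@dataclass
class EnergyParams:
    """Constants of the binding-energy model (kcal/mol, Angstrom)."""

    hbond_energy: float = -1.5            # per backbone hydrogen bond
    hbonds_per_neighbor_pair: int = 10    # per registered in-sheet strand pair
    contact_table: np.ndarray = field(default_factory=default_contact_table)
    dielectric_by_class: dict = field(default_factory=lambda: {
        "nonpolar": 1.0, "polar": 2.0, "charged": 4.0})
    coulomb_constant: float = 332.06      # kcal*A/(mol*e^2)
    contact_cutoff: float = 6.5           # between side-chain centroids
    desolvation_penalty: float = 2.0      # per buried charged residue
    burial_margin: float = 0.0            # shrink of the inter-sheet slab
    centroid_distances: dict = field(
        default_factory=lambda: dict(SIDECHAIN_CENTROID_DISTANCE))

    def __post_init__(self):
        self.contact_table = np.asarray(self.contact_table, dtype=float)
        if self.contact_table.shape != (20, 20):
            raise ConfigurationError("contact_table must be 20x20")
        if not np.allclose(self.contact_table, self.contact_table.T):
            raise ConfigurationError("contact_table must be symmetric")
        if self.contact_cutoff <= 0:
            raise ConfigurationError("contact_cutoff must be positive")
        if any(v < 1.0 for v in self.dielectric_by_class.values()):
            raise ConfigurationError("dielectric constants must be >= 1")


@dataclass
class AggregationParams:
    """Constants of the sequence-based self-aggregation propensity.

    The raw per-residue profile is

        z_i = w_h * hydropathy(i) + w_b * beta_propensity(i) - w_c * |q_i|

    window-averaged (truncated at the termini), averaged over windows, then
    mapped through the affine normalization ``gain * mean + offset``.  With
    the defaults the charge-rich 11-mers of interest land in the range
    (-0.4, 0), dimensionless and small against dG so that lambda of a few
    units trades the two terms.
    """

    hydropathy_scale: dict = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    beta_propensity_scale: dict = field(
        default_factory=lambda: dict(BETA_PROPENSITY))
    weight_hydropathy: float = 0.05
    weight_beta: float = 0.5
    weight_charge: float = 0.4
    window: int = 5
    gain: float = 1.0
    offset: float = -0.5

    def __post_init__(self):
        if self.window < 1:
            raise ConfigurationError("window must be >= 1")
        for name, scale in (("hydropathy_scale", self.hydropathy_scale),
                            ("beta_propensity_scale", self.beta_propensity_scale)):
            missing = set(AA_ALPHABET) - set(scale)
            if missing:
                raise ConfigurationError(
                    f"{name} missing residues: {sorted(missing)}")


@dataclass
class ScoreBreakdown:
    """Full decomposition of one pair's design score (kcal/mol unless noted)."""

    dg_binding: float
    p_agg: float              # dimensionless, mean of the two chains
    lambda_weight: float
    gamma_score: float
    components: dict = field(default_factory=dict)
    p_agg_a: float = 0.0
    p_agg_b: float = 0.0


def combine_score(dg: float, p_agg: float, lambda_weight: float) -> float:
    """Gamma = dG_binding + lambda * P_agg (exact linear combination)."""
    if not (np.isfinite(dg) and np.isfinite(p_agg) and np.isfinite(lambda_weight)):
        raise ConfigurationError("combine_score requires finite inputs")
    return dg + lambda_weight * p_agg


def binding_energy(pair: PeptidePair, scaffold: FibrilScaffold,
                   params: EnergyParams | None = None):
    """Per-peptide interaction energy of the pair threaded onto the scaffold.

    Returns ``(dg_per_peptide, components)`` where components holds the
    hbond/contact/electrostatic/desolvation totals (kcal/mol, whole fibril,
    not yet divided by the peptide count).  Deterministic; independent of
    slot enumeration order; invariant under rigid motion of the coordinates.
    """
    params = params or EnergyParams()
    for slot in scaffold.slots:
        if slot.species not in ("A", "B"):
            raise StateError(f"slot without species assignment: {slot}")
    seqs = scaffold.sequences(pair)
    n_slots = scaffold.n_slots
    n_res = scaffold.n_residues
    centroids = scaffold.centroid_positions(
        pair, params.centroid_distances).reshape(-1, 3)
    res = np.array([aa for seq in seqs for aa in seq])
    slot_of = np.repeat(np.arange(n_slots), n_res)
    aa_idx = np.array([_AA_INDEX[aa] for aa in res])
    charge = np.array([RESIDUE_CHARGE[aa] for aa in res])
    eps = np.array([params.dielectric_by_class[dielectric_class(aa)]
                    for aa in res])

    e_hbond = (params.hbond_energy * params.hbonds_per_neighbor_pair
               * len(scaffold.hbond_registry))

    d = cdist(centroids, centroids)
    inter = slot_of[:, None] != slot_of[None, :]
    upper = np.triu(np.ones_like(inter, dtype=bool), k=1)
    contact_mask = inter & upper & (d <= params.contact_cutoff)
    ii, jj = np.nonzero(contact_mask)
    e_contact = float(params.contact_table[aa_idx[ii], aa_idx[jj]].sum())

    charged = np.nonzero(charge != 0.0)[0]
    e_elec = 0.0
    if charged.size:
        dc = d[np.ix_(charged, charged)]
        mask = inter[np.ix_(charged, charged)] & np.triu(
            np.ones((charged.size, charged.size), dtype=bool), k=1)
        qq = np.outer(charge[charged], charge[charged])
        ee = np.maximum.outer(eps[charged], eps[charged])
        with np.errstate(divide="ignore"):
            terms = params.coulomb_constant * qq / (ee * dc)
        e_elec = float(terms[mask].sum())

    n_buried = _count_buried_charges(scaffold, centroids, charge, params)
    e_desolv = params.desolvation_penalty * n_buried

    total = e_hbond + e_contact + e_elec + e_desolv
    components = {
        "hbond": e_hbond,
        "contact": e_contact,
        "electrostatic": e_elec,
        "desolvation": e_desolv,
        "n_buried_charged": n_buried,
    }
    return total / n_slots, components


def _count_buried_charges(scaffold: FibrilScaffold, centroids: np.ndarray,
                          charge: np.ndarray, params: EnergyParams) -> int:
    """Charged residues whose centroid sits in the inter-sheet slab.

    The slab is bounded by the mean C-alpha planes of the two outermost
    sheets, measured along the inter-sheet axis; the rule is purely
    geometric, so it is invariant under rigid motion.  Single-sheet
    scaffolds have no slab.
    """
    sheets = scaffold.sheet_indices()
    uniq = np.unique(sheets)
    if uniq.size < 2:
        return 0
    ca = scaffold.ca_coords
    sheet_centers = np.array([ca[sheets == s].reshape(-1, 3).mean(axis=0)
                              for s in uniq])
    lo_c, hi_c = sheet_centers[0], sheet_centers[-1]
    axis = hi_c - lo_c
    norm = np.linalg.norm(axis)
    if norm == 0:
        return 0
    axis = axis / norm
    proj = centroids @ axis
    lo = lo_c @ axis + params.burial_margin
    hi = hi_c @ axis - params.burial_margin
    buried = (proj > lo + 1e-9) & (proj < hi - 1e-9) & (charge != 0.0)
    return int(buried.sum())


def aggregation_propensity(seq: str,
                           params: AggregationParams | None = None) -> float:
    """Intrinsic self-aggregation propensity of one chain (dimensionless)."""
    params = params or AggregationParams()
    seq = str(seq).upper()
    try:
        z = np.array([
            params.weight_hydropathy * params.hydropathy_scale[aa]
            + params.weight_beta * params.beta_propensity_scale[aa]
            - params.weight_charge * abs(RESIDUE_CHARGE[aa])
            for aa in seq])
    except KeyError as exc:
        raise ConfigurationError(f"residue missing from a scale: {exc}") from exc
    if params.window > len(seq):
        raise ConfigurationError("window exceeds sequence length")
    half = params.window // 2
    averaged = np.array([z[max(0, i - half): i + half + 1].mean()
                         for i in range(len(seq))])
    return float(params.gain * averaged.mean() + params.offset)


def pair_aggregation(pair: PeptidePair,
                     params: AggregationParams | None = None):
    """Per-chain propensities and their mean (the pair's reported P_agg)."""
    pa = aggregation_propensity(pair.seq_a, params)
    pb = aggregation_propensity(pair.seq_b, params)
    return pa, pb, 0.5 * (pa + pb)


def score_pair(pair: PeptidePair, scaffold: FibrilScaffold,
               energy_params: EnergyParams | None = None,
               agg_params: AggregationParams | None = None,
               lambda_weight: float = 3.0,
               validate: bool = True) -> ScoreBreakdown:
    """Full score breakdown for one pair on one scaffold."""
    if validate:
        report = validate_pair(pair)
        if not report.ok:
            raise ConfigurationError(
                f"pair fails sequence constraints: {report.violations}")
    dg, components = binding_energy(pair, scaffold, energy_params)
    pa, pb, p_agg = pair_aggregation(pair, agg_params)
    return ScoreBreakdown(
        dg_binding=dg,
        p_agg=p_agg,
        lambda_weight=lambda_weight,
        gamma_score=combine_score(dg, p_agg, lambda_weight),
        components=components,
        p_agg_a=pa,
        p_agg_b=pb,
    )
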
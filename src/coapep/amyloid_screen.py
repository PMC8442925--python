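"""Sequence-based amyloidogenicity screen.

Implements the contact-scale rule used to check that individual designed
peptides are nonamyloidogenic: assign each residue its expected-contacts
(packing density) value, average over a centered window (truncated at the
termini), and classify the chain as amyloidogenic iff at least ``min_run``
consecutive residues have window-averaged values strictly above the
empirical threshold (default 21.4, minimum run 7).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError
from .scales import AA_ALPHABET
from .sequence_space import PeptidePair

__all__ = [
    "AmyloidScreenParams",
    "AmyloidProfile",
    "load_scale_csv",
    "packaged_contact_scale",
    "amyloid_profile",
    "screen_pair",
]

AMYLOIDOGENIC = "amyloidogenic"
NONAMYLOIDOGENIC = "nonamyloidogenic"


def packaged_contact_scale() -> dict:
    """The packaged expected-contacts scale (20 residues -> value)."""
    with resources.files("coapep.data").joinpath("contact_scale.csv").open() as fh:
        return _parse_scale(fh)


def load_scale_csv(path) -> dict:
    """Read a residue scale from a two-column CSV (residue, value)."""
    with open(path) as fh:
        return _parse_scale(fh)


def _parse_scale(fh) -> dict:
    scale = {}
    for row in csv.reader(line for line in fh if not line.startswith("#")):
        if not row or row[0].strip().lower() == "residue":
            continue
        scale[row[0].strip().upper()] = float(row[1])
    missing = set(AA_ALPHABET) - set(scale)
    if missing:
        raise ConfigurationError(f"scale missing residues: {sorted(missing)}")
    return scale


@dataclass
class AmyloidScreenParams:
    residue_scale: dict = field(default_factory=packaged_contact_scale)
    averaging_window: int = 5
    threshold: float = 21.4
    min_run: int = 7

    def __post_init__(self):
        if self.averaging_window < 1 or self.averaging_window % 2 == 0:
            raise ConfigurationError("averaging_window must be odd and >= 1")
        if self.min_run < 1:
            raise ConfigurationError("min_run must be >= 1")


@dataclass
class AmyloidProfile:
    sequence: str
    raw: np.ndarray
    averaged: np.ndarray
    longest_run: int
    classification: str

    @property
    def is_amyloidogenic(self) -> bool:
        return self.classification == AMYLOIDOGENIC


def _longest_true_run(mask: np.ndarray) -> int:
    best = run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        best = max(best, run)
    return best


def amyloid_profile(seq: str,
                    params: AmyloidScreenParams | None = None) -> AmyloidProfile:
    """Window-averaged contact profile and amyloidogenicity classification."""
    params = params or AmyloidScreenParams()
    seq = str(seq).upper()
    try:
        raw = np.array([params.residue_scale[aa] for aa in seq], dtype=float)
    except KeyError as exc:
        raise ConfigurationError(
            f"residue missing from the scale: {exc}") from exc
    half = params.averaging_window // 2
    averaged = np.array([raw[max(0, i - half): i + half + 1].mean()
                         for i in range(len(seq))])
    run = _longest_true_run(averaged > params.threshold)
    cls = AMYLOIDOGENIC if run >= params.min_run else NONAMYLOIDOGENIC
    return AmyloidProfile(sequence=seq, raw=raw, averaged=averaged,
                          longest_run=run, classification=cls)


def screen_pair(pair: PeptidePair,
                params: AmyloidScreenParams | None = None):
    """Classify both chains independently; returns (profile_A, profile_B)."""
    return (amyloid_profile(pair.seq_a, params),
            amyloid_profile(pair.seq_b, params))
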
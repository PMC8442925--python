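"""Shared FASTA/CSV helpers and logging setup."""

from __future__ import annotations

import logging
import sys
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .sequence_space import PeptidePair

__all__ = [
    "read_pair_fasta",
    "write_pair_fasta",
    "write_sequences_fasta",
    "read_sequences_fasta",
    "setup_logging",
]


def setup_logging(level=logging.INFO) -> logging.Logger:
    logger = logging.getLogger("coapep")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


def _normalize(seq: str) -> str:
    # normalize unicode minus and stray whitespace from hand-edited files
    return str(seq).strip().upper().replace("−", "-")


def write_pair_fasta(pair: PeptidePair, path, name: str = "design") -> Path:
    """Write one pair as two records tagged /chain=A and /chain=B."""
    records = [
        SeqRecord(Seq(pair.seq_a), id=f"{name}_A", description="/chain=A"),
        SeqRecord(Seq(pair.seq_b), id=f"{name}_B", description="/chain=B"),
    ]
    path = Path(path)
    SeqIO.write(records, str(path), "fasta")
    return path


def read_pair_fasta(path) -> PeptidePair:
    """Read a pair from FASTA: chain tags in descriptions, else record order."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise InputError(f"{path}: expected exactly 2 records, got {len(records)}")
    by_chain = {}
    for rec in records:
        desc = rec.description
        if "/chain=A" in desc:
            by_chain["A"] = _normalize(str(rec.seq))
        elif "/chain=B" in desc:
            by_chain["B"] = _normalize(str(rec.seq))
    if set(by_chain) != {"A", "B"}:
        by_chain = {"A": _normalize(str(records[0].seq)),
                    "B": _normalize(str(records[1].seq))}
    return PeptidePair(seq_a=by_chain["A"], seq_b=by_chain["B"])


def write_sequences_fasta(sequences: dict, path) -> Path:
    """Write ``{record id: sequence}`` preserving insertion order."""
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    path = Path(path)
    SeqIO.write(records, str(path), "fasta")
    return path


def read_sequences_fasta(path) -> dict:
    return {rec.id: _normalize(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}
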
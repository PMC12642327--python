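"""In-silico tryptic digestion and cross-proteome peptide uniqueness.

Implements the Trypsin/P rule — cleavage after every K or R, including when
the next residue is proline — with configurable missed cleavages and peptide
length bounds, and a uniqueness check answering: which tryptic peptides of a
target proteome (for instance, the rat immunoglobulin of an administered
antibody) can never arise from the host proteome? Isoleucine and leucine are
isobaric and indistinguishable by MS; an optional flag collapses them before
the uniqueness comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from pyteomics import parser as _pyt_parser

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Trypsin/P: cut C-terminal of K/R regardless of the following residue
TRYPSIN_P_RULE = r"[KR]"


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings (protease fixed to Trypsin/P)."""

    max_missed_cleavages: int = 1
    min_length: int = 6
    max_length: int = 30

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")


def digest(sequence: str, params: DigestParams = DigestParams()) -> set[str]:
    """Tryptic (Trypsin/P) peptides of one protein sequence.

    Returns the set of peptides with up to ``max_missed_cleavages`` internal
    uncleaved K/R sites and length within the configured bounds.
    """
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in sequence")
    peptides = _pyt_parser.cleave(
        sequence, TRYPSIN_P_RULE, missed_cleavages=params.max_missed_cleavages
    )
    return {p for p in peptides if params.min_length <= len(p) <= params.max_length}


def digest_fasta(path: str | Path, params: DigestParams = DigestParams()) -> set[str]:
    """Union of tryptic peptides over every sequence in a protein FASTA."""
    peptides: set[str] = set()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        peptides |= digest(str(record.seq), params)
    if n == 0:
        raise ValueError(f"{path}: no FASTA sequences parsed")
    return peptides


def unique_peptides(
    target_fasta: str | Path,
    other_fasta: str | Path,
    params: DigestParams = DigestParams(),
    collapse_il: bool = False,
) -> set[str]:
    """Tryptic peptides of the target proteome absent from the other proteome.

    With ``collapse_il`` the comparison treats I and L as equivalent (the
    mass-spectrometric view); returned peptides keep their literal target
    sequence either way.
    """
    target = digest_fasta(target_fasta, params)
    other = digest_fasta(other_fasta, params)
    if collapse_il:
        other_collapsed = {p.replace("L", "I") for p in other}
        return {p for p in target if p.replace("L", "I") not in other_collapsed}
    return target - other
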
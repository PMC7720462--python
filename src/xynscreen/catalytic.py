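"""Catalytic-domain extraction and molecular-mass prediction.

The catalytic-domain subsequence (the region matched by the family's Pfam
model) is what enters the alignment and the tree; the mass helper predicts
the average molecular mass of a mature protein the way standard protein
parameter tools do.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .architecture import DomainHit, SequenceRecord

#: Average (not monoisotopic) residue masses, Da — standard IUPAC values.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


class CoordinateError(ValueError):
    pass


@dataclass
class DomainSequence:
    """An extracted domain region with its parent coordinates (1-based,
    inclusive)."""

    seq_id: str
    parent_id: str
    residues: str
    seq_start: int
    seq_end: int

    def __post_init__(self) -> None:
        if len(self.residues) != self.seq_end - self.seq_start + 1:
            raise ValueError(f"{self.seq_id}: residues do not match coordinates")


def extract_catalytic_domain(seq: SequenceRecord, hit: DomainHit) -> DomainSequence:
    """Slice the hit interval out of the parent sequence.

    The derived id is ``parent/<start>-<end>`` so extracted domains from the
    same protein stay distinguishable.
    """
    if hit.seq_id != seq.id:
        raise CoordinateError(f"hit is for {hit.seq_id}, sequence is {seq.id}")
    if hit.seq_end > len(seq):
        raise CoordinateError(
            f"{seq.id}: hit interval {hit.seq_start}-{hit.seq_end} exceeds "
            f"sequence length {len(seq)}"
        )
    residues = seq.residues[hit.seq_start - 1 : hit.seq_end]
    return DomainSequence(
        seq_id=f"{seq.id}/{hit.seq_start}-{hit.seq_end}",
        parent_id=seq.id,
        residues=residues,
        seq_start=hit.seq_start,
        seq_end=hit.seq_end,
    )


def molecular_mass(residues: str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    if not residues:
        raise ValueError("empty sequence")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[a] for a in residues)
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r}") from None
    return total + WATER_MASS


def write_domains_fasta(domains: list[DomainSequence], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(d.residues), id=d.seq_id,
                  description=f"parent={d.parent_id}")
        for d in domains
    ]
    seqio_write(records, str(path), "fasta")
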
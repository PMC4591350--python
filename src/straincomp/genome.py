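"""Genome container: a named set of replicon sequences (chromosome + plasmids)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Genome"]


@dataclass
class Genome:
    genome_id: str
    replicons: Dict[str, str] = field(default_factory=dict)  # replicon id -> sequence

    @property
    def replicon_lengths(self) -> Dict[str, int]:
        return {rep: len(seq) for rep, seq in self.replicons.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self.replicons.values())

    @property
    def replicon_order(self) -> List[str]:
        """Declared replicon order (insertion order = FASTA order)."""
        return list(self.replicons)

    @classmethod
    def from_fasta(cls, genome_id: str, path) -> "Genome":
        reps = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not reps:
            raise ValueError(f"no sequences in {path}")
        return cls(genome_id, reps)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=rep, description="")
            for rep, seq in self.replicons.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
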
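"""Multiple-sequence alignments with partition maps (concatenated loci)."""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "read_fasta", "write_fasta", "write_nexus"]

_VALID = set("ACGTN-")


@dataclass
class Alignment:
    """Aligned sequences over {A,C,G,T,-,N} with named, disjoint partitions.

    ``partitions`` maps locus name -> (start, end) half-open column ranges
    that together cover the full alignment length.
    """

    labels: list[str]
    sequences: list[str]
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - _VALID
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(bad)}")
        if not self.partitions:
            self.partitions = {"all": (0, self.n_sites)}
        self._check_partitions()

    def _check_partitions(self) -> None:
        spans = sorted(self.partitions.values())
        covered = 0
        for start, end in spans:
            if start != covered:
                raise ValueError("partition ranges must be disjoint and covering")
            if end <= start:
                raise ValueError("empty partition range")
            covered = end
        if covered != self.n_sites:
            raise ValueError("partitions do not cover the alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def columns(self, locus: str) -> "Alignment":
        start, end = self.partitions[locus]
        return Alignment(list(self.labels),
                         [s[start:end] for s in self.sequences],
                         {locus: (0, end - start)})

    def sequence(self, label: str) -> str:
        return self.sequences[self.labels.index(label)]

    def missing_fraction(self) -> float:
        total = self.n_taxa * self.n_sites
        miss = sum(s.count("-") + s.count("N") for s in self.sequences)
        return miss / total if total else 0.0


def read_fasta(text: str, partitions: dict[str, tuple[int, int]] | None = None) -> Alignment:
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no sequences in FASTA input")
    return Alignment([r.id for r in records], [str(r.seq) for r in records],
                     partitions or {})


def write_fasta(aln: Alignment) -> str:
    buf = io.StringIO()
    records = [SeqRecord(Seq(s), id=lab, description="")
               for lab, s in zip(aln.labels, aln.sequences)]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def write_nexus(aln: Alignment) -> str:
    """NEXUS data block with a sets block recording the partition map."""
    buf = io.StringIO()
    buf.write("#NEXUS\nBEGIN DATA;\n")
    buf.write(f"  DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.n_sites};\n")
    buf.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
    width = max(len(l) for l in aln.labels) + 2
    for lab, seq in zip(aln.labels, aln.sequences):
        name = f"'{lab}'" if " " in lab else lab
        buf.write(f"    {name:<{width}} {seq}\n")
    buf.write("  ;\nEND;\nBEGIN SETS;\n")
    for locus, (start, end) in aln.partitions.items():
        buf.write(f"  CHARSET {locus} = {start + 1}-{end};\n")
    buf.write("END;\n")
    return buf.getvalue()
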
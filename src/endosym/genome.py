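"""Annotated circular genomes with typed features.

Coordinates are 0-based half-open throughout the package; GFF3 output is
converted to 1-based inclusive on write and back on read. Circular genomes
are linearized at position 0; the generator guarantees no wrapping feature,
so features never cross the origin in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "pseudogene")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class Feature:
    """A typed genome feature in 0-based half-open coordinates."""

    id: str
    kind: str  # one of FEATURE_KINDS
    start: int
    end: int  # exclusive
    strand: int  # +1 / -1
    family: str = ""  # gene-family label (shared by duplicate copies)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature span [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError("strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sequence(self, genome_seq: str) -> str:
        """Feature sequence on its coding strand."""
        s = genome_seq[self.start : self.end]
        return revcomp(s) if self.strand == -1 else s


@dataclass
class AnnotatedGenome:
    """Circular (or linear) genome sequence plus sorted features."""

    id: str
    seq: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: f.start)
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(f"feature {f.id} exceeds genome length")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def coding_mask(self) -> "list[bool]":
        """Boolean per-position mask: True where covered by a CDS/rRNA/tRNA."""
        import numpy as np

        mask = np.zeros(len(self.seq), dtype=bool)
        for f in self.features:
            if f.kind != "pseudogene":
                mask[f.start : f.end] = True
        return mask

    def rotate(self, offset: int) -> "AnnotatedGenome":
        """Rotate a circular genome so that ``offset`` becomes position 0.

        Features that would wrap after rotation are not supported and raise.
        """
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        n = len(self.seq)
        offset %= n
        new_seq = self.seq[offset:] + self.seq[:offset]
        new_feats = []
        for f in self.features:
            s = (f.start - offset) % n
            e = s + f.length
            if e > n:
                raise ValueError(f"rotation splits feature {f.id}")
            new_feats.append(replace(f, start=s, end=e))
        return AnnotatedGenome(self.id, new_seq, new_feats, circular=True)

    def rotate_to_gene(self, gene_id: str) -> "AnnotatedGenome":
        f = self.feature_by_id(gene_id)
        return self.rotate(f.start)

    # ---------------------------------------------------------------- I/O

    def to_fasta(self, path: str | Path) -> None:
        rec = SeqRecord(Seq(self.seq), id=self.id, description="")
        SeqIO.write([rec], str(path), "fasta")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.id} 1 {len(self.seq)}\n")
            for f in self.features:
                strand = "+" if f.strand == 1 else "-"
                attrs = f"ID={f.id}"
                if f.family:
                    attrs += f";family={f.family}"
                fh.write(
                    f"{self.id}\tendosym\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{strand}\t.\t{attrs}\n"
                )

    @classmethod
    def from_files(
        cls, fasta: str | Path, gff3: str | Path | None = None, circular: bool = True
    ) -> "AnnotatedGenome":
        rec = next(SeqIO.parse(str(fasta), "fasta"))
        feats: list[Feature] = []
        if gff3 is not None:
            feats = list(read_gff3(gff3))
        return cls(rec.id, str(rec.seq).upper(), feats, circular=circular)


def read_gff3(path: str | Path) -> Iterable[Feature]:
    """Parse the minimal GFF3 subset written by :meth:`AnnotatedGenome.to_gff3`."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            _, _, kind, start, end, _, strand, _, attrs = cols[:9]
            pairs = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            yield Feature(
                id=pairs.get("ID", ""),
                kind=kind,
                start=int(start) - 1,
                end=int(end),
                strand=1 if strand == "+" else -1,
                family=pairs.get("family", ""),
            )
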
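"""Gene models and genome/annotation I/O.

Coordinates are 0-based half-open everywhere in memory; GTF on disk is
1-based inclusive and converted at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
import pyfaidx

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon (and optionally CDS) structure on one chromosome.

    ``exons`` and ``cds`` are tuples of (start, end) half-open intervals,
    sorted by genomic start. ``cds`` is empty for non-coding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    biotype: str  # "protein_coding" | "lncRNA"
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def tss(self) -> int:
        """Transcription start site as a 0-based position."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_in_orf_order(self) -> tuple[tuple[int, int], ...]:
        """CDS exons ordered 5'->3' along the transcript."""
        return self.cds if self.strand == "+" else tuple(reversed(self.cds))

    def overlaps(self, start: int, end: int) -> bool:
        """Whether the gene body [start_gene, end_gene) intersects [start, end)."""
        return self.start < end and start < self.end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def write_gtf(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GTF (gene/transcript/exon/CDS lines, 1-based)."""
    with open(path, "w") as fh:
        for g in models:
            tid = f"{g.gene_id}.t1"
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                f'gene_type "{g.biotype}";'
            )
            rows = [("gene", g.start, g.end), ("transcript", g.start, g.end)]
            rows += [("exon", s, e) for s, e in g.exons]
            rows += [("CDS", s, e) for s, e in g.cds]
            for feat, s, e in rows:
                fh.write(
                    f"{g.chrom}\tpgscreen\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a GTF file (via gffutils, in-memory DB)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(gene, featuretype="exon")
            )
        )
        cds = tuple(
            sorted(
                (f.start - 1, f.end)
                for f in db.children(gene, featuretype="CDS")
            )
        )
        biotype = gene.attributes.get("gene_type", ["protein_coding"])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                biotype=biotype,
                exons=exons,
                cds=cds,
            )
        )
    return models
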
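"""Readers and writers for FASTA, BED and GTF.

Genomes are held as plain ``dict`` mapping chromosome name to an uppercase
sequence over {A, C, G, T, N}; interval tracks as lists of
:class:`~g4bulge.core.Interval`; gene models as :class:`GeneModel` records.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO

from .core import Interval

Genome = Dict[str, str]

_VALID = set("ACGTN")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_sequence(seq: str) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(c if c in _VALID else "N" for c in seq)


def read_fasta(path) -> Genome:
    """Read a (optionally gzipped) FASTA file into a genome dict.

    Sequences are uppercased; IUPAC ambiguity codes and any other non-ACGT
    character are mapped to N. Malformed input (leading non-header line,
    a record with no sequence, duplicate names) raises ``ValueError`` naming
    the offending line.
    """
    # Light structural validation with line numbers; Biopython does the
    # actual record parsing below.
    with _open_text(path) as fh:
        header_line = None
        has_seq = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header_line is not None and not has_seq:
                    raise ValueError(
                        f"{path}: empty FASTA record at line {header_line}"
                    )
                if line == ">":
                    raise ValueError(f"{path}: empty header at line {lineno}")
                header_line = lineno
                has_seq = False
            else:
                if header_line is None:
                    raise ValueError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                has_seq = True
        if header_line is None:
            raise ValueError(f"{path}: no FASTA records found")
        if not has_seq:
            raise ValueError(f"{path}: empty FASTA record at line {header_line}")

    genome: Genome = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
            genome[rec.id] = _clean_sequence(str(rec.seq))
    return genome


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def chrom_sizes(genome: Genome) -> Dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


def write_bed(items: Iterable, path, dialect: str = "bed6") -> None:
    """Write interval-like items as sorted BED6.

    Items need ``chrom``/``start``/``end``/``strand`` attributes and
    optionally ``name``/``score``; output is sorted by (chrom, start, end).
    """
    if dialect != "bed6":
        raise ValueError(f"unsupported BED dialect {dialect!r}")
    rows = []
    for it in items:
        if it.start < 0:
            raise ValueError(f"negative coordinate in {it}")
        name = getattr(it, "name", ".") or "."
        score = getattr(it, "score", None)
        score = "0" if score is None else f"{score:g}"
        rows.append((it.chrom, it.start, it.end, name, score, it.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[5]))
    with _open_text(path, "wt") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_bed(path) -> List[Interval]:
    """Read BED3/BED6 into a list of Interval (extra columns ignored)."""
    out: List[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            name = f[3] if len(f) > 3 else "."
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            strand = f[5] if len(f) > 5 else "."
            out.append(
                Interval(f[0], int(f[1]), int(f[2]), strand, name, score)
            )
    return out


@dataclass(frozen=True)
class GeneModel:
    """One transcript of a protein-coding gene.

    Exons are half-open, sorted by genomic start regardless of strand; the
    CDS span delimits coding exonic sequence so that UTRs can be derived.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside transcript "
                    f"span [{self.start},{self.end})"
                )

    @property
    def tss(self) -> int:
        """Transcription start site (rightmost coordinate on − genes)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GTF (gene/transcript/exon/CDS features)."""

    def line(feat, s, e, g, attrs):
        return (
            f"{g.chrom}\tg4bulge\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
        )

    with _open_text(path, "wt") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            ga = f'gene_id "{g.gene_id}";'
            ta = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
            fh.write(line("gene", g.start, g.end, g, ga))
            fh.write(line("transcript", g.start, g.end, g, ta))
            for s, e in g.exons:
                fh.write(line("exon", s, e, g, ta))
            if g.cds_start is not None:
                for s, e in g.exons:
                    cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                    if cs < ce:
                        fh.write(line("CDS", cs, ce, g, ta))


def read_gene_models(path) -> List[GeneModel]:
    """Read gene models from a GTF/GFF file (gene/transcript/exon/CDS only)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: List[GeneModel] = []
    for tx in db.features_of_type(("transcript", "mRNA")):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(tx, featuretype="exon")
        )
        cds = sorted(
            (f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")
        )
        genes.append(
            GeneModel(
                gene_id=tx.attributes["gene_id"][0],
                transcript_id=tx.attributes.get(
                    "transcript_id", [tx.id]
                )[0],
                chrom=tx.seqid,
                start=tx.start - 1,
                end=tx.end,
                strand=tx.strand,
                exons=tuple(exons) if exons else ((tx.start - 1, tx.end),),
                cds_start=cds[0][0] if cds else None,
                cds_end=cds[-1][1] if cds else None,
            )
        )
    return genes
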
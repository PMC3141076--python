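"""Shared domain types and readers/writers for the standard genomic formats.

All coordinates are 0-based half-open internally; 1-based coordinates appear
only in human-readable reports.  The transcription start site (TSS) of a
minus-strand gene is ``tx_end - 1`` (the last base of the transcript
interval), the standard convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class GenomeSequence:
    """Per-chromosome uppercase DNA strings over {A,C,G,T,N}.

    Parameters
    ----------
    sequences : mapping of chromosome name -> sequence string
    """

    def __init__(self, sequences: Mapping[str, str]):
        seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in seqs:
                raise ValueError(f"duplicate chromosome name {name!r}")
            s = str(seq).upper()
            bad = set(s) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )
            seqs[name] = s
        self.sequences = seqs

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the subsequence [start, end) of ``chrom``."""
        return self.sequences[chrom][start:end]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class GeneModel:
    """A gene's coordinates: transcript bounds, exons and optional CDS.

    ``exons`` are sorted, disjoint, the first starts at ``tx_start`` and the
    last ends at ``tx_end``.  ``cds_start``/``cds_end`` are ``None`` for
    non-coding genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.gene_id}: tx_start >= tx_end")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in exons:
            if not s < e:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping or unsorted exons")
            prev_end = e
        if exons[0][0] != self.tx_start or exons[-1][1] != self.tx_end:
            raise ValueError(
                f"gene {self.gene_id}: exons do not span transcript bounds"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.gene_id}: half-specified CDS")
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"gene {self.gene_id}: CDS outside transcript bounds")

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    def introns(self) -> list[tuple[int, int]]:
        """Intervals between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class TagAlignment:
    """A uniquely mapped sequence tag: chromosome, 0-based start, strand."""

    chrom: str
    start: int
    strand: str
    read_length: int = 36

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start < 0:
            raise ValueError("negative tag start")


def tss_of(gene: GeneModel) -> int:
    """Transcription start site: ``tx_start`` (+ strand) or ``tx_end - 1`` (-)."""
    return gene.tx_start if gene.strand == "+" else gene.tx_end - 1


# ---------------------------------------------------------------------------
# Gene models: BED12 and a minimal GFF3 dialect
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (default) or GFF3 (by extension).

    Records are returned in file order.  Malformed lines raise ``ValueError``
    naming the line number; invariant violations name the gene.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_bed12(path)


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated BED fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED12 line: {exc}")
            if len(sizes) != block_count or len(offsets) != block_count:
                raise ValueError(
                    f"{path}:{lineno}: block count does not match block lists"
                )
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            )
            cds_start: int | None = thick_start
            cds_end: int | None = thick_end
            if thick_start >= thick_end:  # BED convention for non-coding
                cds_start = cds_end = None
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand,
                    tx_start=start, tx_end=end, exons=exons,
                    cds_start=cds_start, cds_end=cds_end,
                )
            )
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    """Minimal GFF3 reader: gene features with exon/CDS children keyed by Parent."""
    gene_rows: list[tuple[str, str, str, int, int]] = []  # id, chrom, strand, s, e
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs = fields
            try:
                start, end = int(start1) - 1, int(end1)  # GFF3 is 1-based closed
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID attribute")
                gene_rows.append((gid, chrom, strand, start, end))
            elif ftype == "exon":
                exons.setdefault(attr.get("Parent", ""), []).append((start, end))
            elif ftype == "CDS":
                cds.setdefault(attr.get("Parent", ""), []).append((start, end))
    genes = []
    for gid, chrom, strand, start, end in gene_rows:
        ex = sorted(exons.get(gid, [(start, end)]))
        cd = cds.get(gid)
        cds_start = min(s for s, _ in cd) if cd else None
        cds_end = max(e for _, e in cd) if cd else None
        genes.append(
            GeneModel(
                gene_id=gid, chrom=chrom, strand=strand,
                tx_start=start, tx_end=end, exons=tuple(ex),
                cds_start=cds_start, cds_end=cds_end,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, _ in g.exons)
            thick_start = g.cds_start if g.is_coding else g.tx_start
            thick_end = g.cds_end if g.is_coding else g.tx_start
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                            thick_start, thick_end, "0,0,0",
                            len(g.exons), sizes, offsets,
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tags: BED6
# ---------------------------------------------------------------------------

def read_tags(
    path: str | Path,
    genome: GenomeSequence | None = None,
    read_length: int = 36,
    collapse_duplicates: bool = False,
) -> list[TagAlignment]:
    """Read mapped tags from a 6-column BED file (score ignored).

    Duplicate tags are retained by default (only multi-mapping reads are
    assumed removed upstream); ``collapse_duplicates=True`` keeps one copy of
    each identical (chrom, start, strand, length) record.  If ``genome`` is
    given, tags on unknown chromosomes or overrunning the chromosome end are
    errors.
    """
    tags: list[TagAlignment] = []
    seen: set[TagAlignment] = set()
    lengths = genome.lengths if genome is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            rl = end - start if end > start else read_length
            if lengths is not None:
                if chrom not in lengths:
                    raise ValueError(
                        f"{path}:{lineno}: unknown chromosome {chrom!r}"
                    )
                if start + rl > lengths[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: tag overruns end of {chrom}"
                    )
            tag = TagAlignment(chrom, start, strand, rl)
            if collapse_duplicates:
                if tag in seen:
                    continue
                seen.add(tag)
            tags.append(tag)
    counts = pd.Series([t.chrom for t in tags]).value_counts().to_dict() if tags else {}
    logger.info("read %d tags from %s (%s)", len(tags), path, counts)
    return tags


def write_tags(tags: Iterable[TagAlignment], path: str | Path) -> None:
    """Write tags as BED6 (name '.', score 0)."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.start + t.read_length}\t.\t0\t{t.strand}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrix and gene sets
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a TSV expression matrix (rows genes, columns samples).

    Column headers follow ``<condition>_<replicate>``; the returned list gives
    each column's condition label.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    conditions = [c.rsplit("_", 1)[0] for c in df.columns]
    return df, conditions


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line with <3 fields")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")
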
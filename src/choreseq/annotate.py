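"""Peak-to-gene assignment and genomic-feature categorisation.

Each peak is represented by its summit.  The nearest gene is the one whose
TSS lies closest to the summit (within 20 kb by default); the signed distance
is negative upstream of the TSS and positive downstream, in the gene's
orientation.  Feature categories use strand-aware promoter windows: proximal
promoter = 2 kb and distal promoter = 2-5 kb of 5'-flanking DNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, tss_of
from .peaks import Peak

CATEGORIES = (
    "proximal_promoter",
    "distal_promoter",
    "utr5",
    "utr3",
    "exon",
    "intron_1_2",
    "intron_other",
    "intergenic",
)

_PRECEDENCE = {c: k for k, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    chrom: str
    summit: int
    gene_id: str | None
    distance: int | None  # signed summit-to-TSS distance, negative upstream
    category: str
    multilabels: frozenset[str]


def signed_tss_distance(summit: int, gene: GeneModel) -> int:
    """Summit position relative to the TSS in the gene's orientation."""
    tss = tss_of(gene)
    return summit - tss if gene.strand == "+" else tss - summit


def assign_nearest_gene(
    peak: Peak,
    genes: Sequence[GeneModel],
    max_distance: int = 20_000,
) -> tuple[str | None, int | None]:
    """Gene whose TSS is closest to the peak summit, within ``max_distance``.

    Ties on |distance| go to the lexicographically smaller gene id.
    """
    best: tuple[int, str, int] | None = None  # (|d|, gene_id, signed d)
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = signed_tss_distance(peak.summit, g)
        if abs(d) >= max_distance:
            continue
        key = (abs(d), g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (abs(d), g.gene_id, d)
    if best is None:
        return None, None
    return best[1], best[2]


def _gene_features(summit: int, gene: GeneModel) -> set[str]:
    """All features of ``gene`` that the summit falls in."""
    feats: set[str] = set()
    d = signed_tss_distance(summit, gene)
    if -2000 <= d < 0:
        feats.add("proximal_promoter")
    elif -5000 <= d < -2000:
        feats.add("distal_promoter")
    if not (gene.tx_start <= summit < gene.tx_end):
        return feats
    in_exon = any(s <= summit < e for s, e in gene.exons)
    if in_exon:
        if gene.is_coding:
            if gene.cds_start <= summit < gene.cds_end:
                feats.add("exon")
            else:
                before_cds = summit < gene.cds_start
                utr5 = before_cds if gene.strand == "+" else not before_cds
                feats.add("utr5" if utr5 else "utr3")
        else:
            feats.add("exon")
    else:
        introns = gene.introns()
        idx = next(
            k for k, (s, e) in enumerate(introns) if s <= summit < e
        )
        ordinal = idx if gene.strand == "+" else len(introns) - 1 - idx
        feats.add("intron_1_2" if ordinal < 2 else "intron_other")
    return feats


def categorize_peak(
    peak: Peak, genes: Sequence[GeneModel]
) -> tuple[str, frozenset[str]]:
    """Single-label category (promoter-first precedence) plus the full set
    of features overlapped across all genes."""
    labels: set[str] = set()
    for g in genes:
        if g.chrom == peak.chrom:
            labels |= _gene_features(peak.summit, g)
    if not labels:
        return "intergenic", frozenset()
    single = min(labels, key=_PRECEDENCE.__getitem__)
    return single, frozenset(labels)


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_distance: int = 20_000,
) -> list[PeakAnnotation]:
    out = []
    for k, p in enumerate(peaks):
        gene_id, dist = assign_nearest_gene(p, genes, max_distance)
        category, labels = categorize_peak(p, genes)
        out.append(
            PeakAnnotation(
                peak_id=f"peak_{k + 1}", chrom=p.chrom, summit=p.summit,
                gene_id=gene_id, distance=dist,
                category=category, multilabels=labels,
            )
        )
    return out


def category_fractions(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Fraction of peaks per single-label category (sums to 1)."""
    if not annotations:
        return {c: 0.0 for c in CATEGORIES}
    n = len(annotations)
    return {
        c: sum(a.category == c for a in annotations) / n for c in CATEGORIES
    }


def multilabel_fractions(annotations: Sequence[PeakAnnotation]) -> dict[str, float]:
    """Fraction of peaks overlapping each feature; may sum to more than 1."""
    if not annotations:
        return {c: 0.0 for c in CATEGORIES}
    n = len(annotations)
    out = {}
    for c in CATEGORIES[:-1]:
        out[c] = sum(c in a.multilabels for a in annotations) / n
    out["intergenic"] = sum(not a.multilabels for a in annotations) / n
    return out


def tss_distance_profile(
    annotations: Sequence[PeakAnnotation],
    window: int = 20_000,
    bin_width: int = 1_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed TSS distances over [-window, +window).

    Returns (bin_edges, counts); unassigned peaks are excluded; bins are
    half-open.  ``bin_width`` must divide ``window``.
    """
    if window % bin_width:
        raise ValueError("bin_width must divide window")
    edges = np.arange(-window, window + bin_width, bin_width)
    dists = [a.distance for a in annotations if a.distance is not None]
    counts, _ = np.histogram(dists, bins=edges)
    return edges, counts


def write_annotations(
    annotations: Iterable[PeakAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "peak_id": a.peak_id,
            "chrom": a.chrom,
            "summit": a.summit,
            "gene_id": a.gene_id if a.gene_id is not None else ".",
            "distance": a.distance if a.distance is not None else ".",
            "category": a.category,
            "multilabels": ",".join(sorted(a.multilabels)) or ".",
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows,
        columns=[
            "peak_id", "chrom", "summit", "gene_id",
            "distance", "category", "multilabels",
        ],
    ).to_csv(path, sep="\t", index=False)
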
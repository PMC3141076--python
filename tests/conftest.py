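"""Shared fixtures: a tiny hand-built genome/gene set and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from choreseq.core_io import GeneModel, GenomeSequence
from choreseq.peaks import CoverageTrack, Peak


@pytest.fixture
def toy_genome() -> GenomeSequence:
    rng = np.random.default_rng(77)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50_000)])
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def plus_gene() -> GeneModel:
    # two exons: [10000,10400) + [10800,11600), CDS [10200,11200)
    return GeneModel(
        gene_id="gplus", chrom="chr1", strand="+",
        tx_start=10_000, tx_end=11_600,
        exons=((10_000, 10_400), (10_800, 11_600)),
        cds_start=10_200, cds_end=11_200,
    )


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel(
        gene_id="gminus", chrom="chr1", strand="-",
        tx_start=30_000, tx_end=33_000,
        exons=((30_000, 30_500), (31_000, 31_500), (32_000, 33_000)),
        cds_start=30_250, cds_end=32_500,
    )


def make_track(chip: np.ndarray, total: int | None = None) -> CoverageTrack:
    arr = np.asarray(chip, dtype=np.int64)
    return CoverageTrack(
        {"chr1": arr}, extension=200,
        total_tags=total if total is not None else max(int(arr.sum()), 1),
    )


def brute_force_peaks(
    chip: np.ndarray,
    inp: np.ndarray,
    chip_total: int,
    input_total: int,
    min_height: int,
    min_ratio: float,
    pseudocount: float,
    merge_gap: int,
    input_smooth: int,
) -> list[Peak]:
    """Independent per-base predicate scan + run merging (the peak oracle)."""
    n = len(chip)
    scale = chip_total / input_total if input_total > 0 else 1.0
    scaled = [float(x) * scale for x in inp]
    denom = []
    half = input_smooth // 2
    for i in range(n):
        if input_smooth <= 1:
            m = scaled[i]
        else:
            lo = max(i - half, 0)
            hi = min(i + half + 1, n)
            m = sum(scaled[lo:hi]) / (hi - lo)
        denom.append(max(m, pseudocount))
    ok = [
        chip[i] >= min_height and chip[i] / denom[i] >= min_ratio
        for i in range(n)
    ]
    runs = []
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        summit = s
        for k in range(s, e):
            if chip[k] > chip[summit]:
                summit = k
        height = int(chip[summit])
        region = max(max(denom[s:e]), pseudocount)
        out.append(Peak("chr1", s, e, summit, height, height / region))
    return out
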
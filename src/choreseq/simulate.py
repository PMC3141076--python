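"""Synthetic genome, binding sites, ChIP/input tags and expression data with
planted ground truth.

The generator emulates the data a ChREBP-style ChIP-seq + expression study
rests on, at toy scale: an iid background genome with non-overlapping
multi-exon genes; ChoRE-like motif instances written into the sequence at
TSS-relative positions; ChIP tags as a mixture of uniform background and
site-derived fragments whose midpoints are Normal(site centre, sd =
fragment_length / 4); an input library that is pure background; and a
two-condition expression matrix (six replicates per condition) in which a
configurable fraction of bound genes is up-regulated and the rest
down-regulated under the second (high-glucose-like) condition.

Every operation is deterministic under the configured seed, and the planted
truth (site coordinates, bound genes, direction of regulation) is exposed in
machine-readable form so downstream stages can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    GenomeSequence,
    TagAlignment,
    tss_of,
    write_expression,
    write_gene_models,
    write_tags,
)
from .motifs import PWM, ALPHABET

# Default planted element: the ChoRE-like tandem E-box consensus
# (perfect E-box, 5-nt spacer, imperfect E-box).
DEFAULT_SITE_SEQUENCE = "CACGTGGCCGGCGCGTG"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults the analysis assumes."""

    seed: int
    # genome / genes
    genome_size: int = 1_000_000
    chrom_count: int = 1
    gc: float = 0.5
    gene_count: int = 100
    gene_length_min: int = 2_000
    gene_length_max: int = 5_000
    intergene_gap: int = 2_000
    # binding sites
    n_sites: int = 20
    site_sequence: str = DEFAULT_SITE_SEQUENCE
    tss_offset_mean: float = -500.0
    tss_offset_sd: float = 200.0
    intergenic_fraction: float = 0.0
    occupancy: float = 1.0
    plant_strand: str = "random"  # 'plus' or 'random'
    # sequencing
    fragment_length: int = 200
    read_length: int = 36
    n_chip_tags: int = 100_000
    n_input_tags: int = 100_000
    chip_enrichment: float = 0.10  # fraction of ChIP tags that are site-derived
    # expression
    replicates: int = 6
    effect_size: float = 2.0  # log2 shift of regulated genes in condition 2
    fraction_up: float = 0.5
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    indep_de_fraction: float = 0.02  # binding-independent DE among unbound genes

    def __post_init__(self):
        for name in (
            "genome_size", "chrom_count", "fragment_length",
            "read_length", "replicates",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gene_count < 0:
            raise ValueError("gene_count must be non-negative")
        for name in ("fraction_up", "intergenic_fraction", "chip_enrichment", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_sites < 0 or self.n_chip_tags < 0 or self.n_input_tags < 0:
            raise ValueError("counts must be non-negative")
        if not np.isfinite(self.occupancy) or self.occupancy <= 0:
            raise ValueError("occupancy must be a positive finite weight")


@dataclass(frozen=True)
class PlantedSite:
    """A motif instance written into the genome, optionally tied to a gene."""

    chrom: str
    position: int  # 0-based start of the planted sequence
    strand: str
    sequence: str  # as planted on the forward strand
    linked_gene_id: str | None
    occupancy: float

    @property
    def center(self) -> int:
        return self.position + len(self.sequence) // 2


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng([stage, config.seed])


def make_genome_and_genes(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Iid background genome plus non-overlapping >= 2-exon genes.

    Genes are laid out with at least ``intergene_gap`` bp between them (room
    for promoters and planted sites); if they cannot be placed the error
    suggests a larger genome.
    """
    rng = _rng_for(config, 1)
    per_chrom = config.genome_size // config.chrom_count
    probs = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    sequences = {}
    for c in range(config.chrom_count):
        draws = rng.choice(4, size=per_chrom, p=probs)
        sequences[f"chr{c + 1}"] = "".join(ALPHABET[i] for i in draws)
    genome = GenomeSequence(sequences)

    genes: list[GeneModel] = []
    if config.gene_count:
        chrom_names = list(sequences)
        lengths = rng.integers(
            config.gene_length_min, config.gene_length_max + 1, config.gene_count
        )
        per = int(np.ceil(config.gene_count / config.chrom_count))
        gi = 0
        for cname in chrom_names:
            n_here = min(per, config.gene_count - gi)
            if n_here <= 0:
                break
            L = len(sequences[cname])
            need = int(lengths[gi: gi + n_here].sum()) + (n_here + 1) * config.intergene_gap
            if need > L:
                raise ValueError(
                    f"cannot place {n_here} genes in {L} bp without overlap; "
                    "use a larger genome"
                )
            # random non-overlapping layout: distribute the slack among gaps
            slack = L - need
            cuts = np.sort(rng.integers(0, slack + 1, n_here + 1))
            extra = np.diff(np.concatenate([[0], cuts]))
            pos = config.intergene_gap + extra[0]
            for k in range(n_here):
                glen = int(lengths[gi])
                genes.append(
                    _random_gene(
                        rng, f"g{gi + 1:04d}", cname, pos, pos + glen
                    )
                )
                pos += glen + config.intergene_gap + int(extra[k + 1] if k + 1 < extra.size else 0)
                gi += 1
    return genome, genes


def _random_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int, end: int
) -> GeneModel:
    """A gene with 2-4 exons and a CDS nested inside the outer exons."""
    n_exons = int(rng.integers(2, 5))
    length = end - start
    n_seg = 2 * n_exons - 1  # exon, intron, exon, ...
    w = rng.dirichlet(np.ones(n_seg))
    seg = np.maximum((w * length).astype(int), 50)
    seg[-1] = length - int(seg[:-1].sum())
    if seg[-1] < 50:  # fall back to an even split
        seg = np.full(n_seg, length // n_seg)
        seg[-1] = length - int(seg[:-1].sum())
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    exons = tuple(
        (int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)
    )
    strand = "+" if rng.random() < 0.5 else "-"
    cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
    cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
    if cds_start >= cds_end:
        cds_start, cds_end = exons[0][0], exons[-1][1]
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        tx_start=start, tx_end=end, exons=exons,
        cds_start=cds_start, cds_end=cds_end,
    )


def plant_binding_sites(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    pwm_or_consensus: PWM | str,
    config: SimulationConfig,
    max_retries: int = 50,
) -> tuple[GenomeSequence, list[PlantedSite]]:
    """Write motif instances into the genome at TSS-relative positions.

    The TSS offset of each gene-linked site is Normal(tss_offset_mean,
    tss_offset_sd), interpreted in the gene's orientation (negative =
    upstream); a ``intergenic_fraction`` of sites is placed uniformly instead
    and linked to no gene.  Returns the modified genome and the planted truth.
    A site that would overrun its chromosome is resampled; persistent failure
    raises.
    """
    rng = _rng_for(config, 2)
    n_sites = config.n_sites
    if n_sites == 0:
        return genome, []
    n_intergenic = int(round(n_sites * config.intergenic_fraction))
    n_linked = n_sites - n_intergenic
    if n_linked > len(genes):
        raise ValueError(
            f"cannot link {n_linked} sites to {len(genes)} genes without reuse"
        )
    chosen = rng.choice(len(genes), size=n_linked, replace=False)
    buffers = {c: bytearray(genome[c], "ascii") for c in genome.sequences}
    sites: list[PlantedSite] = []

    def sample_sequence() -> str:
        if isinstance(pwm_or_consensus, str):
            return pwm_or_consensus.upper()
        m = pwm_or_consensus.matrix
        return "".join(
            ALPHABET[rng.choice(4, p=m[:, j])] for j in range(m.shape[1])
        )

    for gidx in sorted(chosen):
        gene = genes[gidx]
        seq = sample_sequence()
        w = len(seq)
        L = len(genome[gene.chrom])
        pos = None
        for _ in range(max_retries):
            offset = int(round(rng.normal(config.tss_offset_mean, config.tss_offset_sd)))
            tss = tss_of(gene)
            cand = tss + offset if gene.strand == "+" else tss - offset - (w - 1)
            if 0 <= cand and cand + w <= L:
                pos = cand
                break
        if pos is None:
            raise ValueError(
                f"could not place site near {gene.gene_id} within bounds"
            )
        strand = (
            "+"
            if config.plant_strand == "plus" or rng.random() < 0.5
            else "-"
        )
        planted = seq if strand == "+" else _revcomp(seq)
        buffers[gene.chrom][pos: pos + w] = planted.encode("ascii")
        sites.append(
            PlantedSite(
                chrom=gene.chrom, position=pos, strand=strand,
                sequence=planted, linked_gene_id=gene.gene_id,
                occupancy=config.occupancy,
            )
        )
    chrom_names = list(genome.sequences)
    chrom_lens = np.array([len(genome[c]) for c in chrom_names], dtype=float)
    for _ in range(n_intergenic):
        seq = sample_sequence()
        w = len(seq)
        ci = rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum())
        chrom = chrom_names[ci]
        pos = int(rng.integers(0, len(genome[chrom]) - w))
        strand = (
            "+"
            if config.plant_strand == "plus" or rng.random() < 0.5
            else "-"
        )
        planted = seq if strand == "+" else _revcomp(seq)
        buffers[chrom][pos: pos + w] = planted.encode("ascii")
        sites.append(
            PlantedSite(
                chrom=chrom, position=pos, strand=strand, sequence=planted,
                linked_gene_id=None, occupancy=config.occupancy,
            )
        )
    new_genome = GenomeSequence(
        {c: b.decode("ascii") for c, b in buffers.items()}
    )
    return new_genome, sites


def simulate_tag_arrays(
    chrom_lengths: dict[str, int],
    sites: Sequence[PlantedSite],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray],
           dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Array-form tag simulation: (chip_starts, chip_fwd, input_starts, input_fwd).

    Fragments are ``fragment_length`` bp; each is reported as a
    ``read_length`` tag from the fragment's 5' end on a Bernoulli(0.5) strand.
    Input midpoints are uniform; ChIP midpoints mix the same background with
    Normal(site centre, fragment_length / 4) site-derived fragments weighted
    by occupancy.
    """
    if rng is None:
        rng = _rng_for(config, 3)
    names = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], dtype=np.int64)
    fl, rl = config.fragment_length, config.read_length

    def background(n: int) -> tuple[np.ndarray, np.ndarray]:
        ci = rng.choice(len(names), size=n, p=lens / lens.sum())
        mids = rng.integers(0, lens[ci])
        return ci, mids

    def to_tags(ci, mids, L=lens):
        fwd = rng.random(ci.size) < 0.5
        frag_start = mids - fl // 2
        frag_end = frag_start + fl
        starts = np.where(fwd, frag_start, frag_end - rl)
        starts = np.clip(starts, 0, L[ci] - rl)
        return starts, fwd

    # input library: pure background
    n_in = config.n_input_tags
    ci_in, mids_in = background(n_in)
    in_starts, in_fwd = to_tags(ci_in, mids_in)
    # ChIP library
    n_chip = config.n_chip_tags
    weights = np.array([s.occupancy for s in sites], dtype=float)
    n_site = (
        int(round(config.chip_enrichment * n_chip)) if sites else 0
    )
    n_bg = n_chip - n_site
    ci_bg, mids_bg = background(n_bg)
    if n_site:
        site_idx = rng.choice(len(sites), size=n_site, p=weights / weights.sum())
        centers = np.array([s.center for s in sites], dtype=float)
        chrom_of_site = np.array(
            [names.index(s.chrom) for s in sites], dtype=np.int64
        )
        mids_site = np.round(
            rng.normal(centers[site_idx], fl / 4.0)
        ).astype(np.int64)
        ci_site = chrom_of_site[site_idx]
        mids_site = np.clip(mids_site, 0, lens[ci_site] - 1)
        ci_chip = np.concatenate([ci_bg, ci_site])
        mids_chip = np.concatenate([mids_bg, mids_site])
    else:
        ci_chip, mids_chip = ci_bg, mids_bg
    chip_starts, chip_fwd = to_tags(ci_chip, mids_chip)

    def group(ci, starts, fwd):
        s_by = {}
        f_by = {}
        for k, c in enumerate(names):
            m = ci == k
            s_by[c] = starts[m]
            f_by[c] = fwd[m]
        return s_by, f_by

    cs, cf = group(ci_chip, chip_starts, chip_fwd)
    is_, if_ = group(ci_in, in_starts, in_fwd)
    return cs, cf, is_, if_


def simulate_tags(
    genome: GenomeSequence,
    sites: Sequence[PlantedSite],
    config: SimulationConfig,
) -> tuple[list[TagAlignment], list[TagAlignment]]:
    """ChIP and input tag lists (see ``simulate_tag_arrays`` for the model)."""
    cs, cf, is_, if_ = simulate_tag_arrays(genome.lengths, sites, config)
    rl = config.read_length

    def to_list(starts_by, fwd_by):
        out = []
        for chrom in starts_by:
            for s, f in zip(starts_by[chrom], fwd_by[chrom]):
                out.append(TagAlignment(chrom, int(s), "+" if f else "-", rl))
        return out

    return to_list(cs, cf), to_list(is_, if_)


def simulate_expression(
    genes: Sequence[GeneModel],
    bound_gene_ids: Iterable[str],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Two-condition log2 expression matrix with planted regulation.

    A ``fraction_up`` share of bound genes gains ``effect_size`` log2 units in
    condition 2 ("high"), the rest loses it; a small fraction of unbound
    genes is differentially expressed independently of binding.  Returns
    (matrix, per-column condition labels, truth table with columns bound /
    direction / true_effect).
    """
    if config.replicates < 2:
        raise ValueError("need >= 2 replicates per condition (variance undefined)")
    gene_ids = [g.gene_id for g in genes]
    bound = set(bound_gene_ids)
    unknown = bound - set(gene_ids)
    if unknown:
        raise ValueError(f"bound genes not in gene list: {sorted(unknown)[:5]}")
    rng = _rng_for(config, 4)
    n = len(gene_ids)
    r = config.replicates
    mu = rng.normal(config.baseline_mean, config.baseline_sd, n)
    effect = np.zeros(n)
    direction = np.array(["none"] * n, dtype=object)
    bound_idx = [i for i, g in enumerate(gene_ids) if g in bound]
    if bound_idx:
        n_up = int(round(config.fraction_up * len(bound_idx)))
        up_pick = rng.choice(len(bound_idx), size=n_up, replace=False)
        is_up = np.zeros(len(bound_idx), dtype=bool)
        is_up[up_pick] = True
        for k, i in enumerate(bound_idx):
            effect[i] = config.effect_size if is_up[k] else -config.effect_size
            direction[i] = "up" if is_up[k] else "down"
    unbound_idx = np.array(
        [i for i, g in enumerate(gene_ids) if g not in bound], dtype=int
    )
    n_indep = int(round(config.indep_de_fraction * unbound_idx.size))
    if n_indep:
        pick = rng.choice(unbound_idx, size=n_indep, replace=False)
        signs = np.where(rng.random(n_indep) < 0.5, 1.0, -1.0)
        effect[pick] = signs * config.effect_size
        direction[pick] = np.where(signs > 0, "up", "down")
    cond1 = rng.normal(mu[:, None], config.noise_sd, (n, r))
    cond2 = rng.normal((mu + effect)[:, None], config.noise_sd, (n, r))
    cols = [f"low_{k + 1}" for k in range(r)] + [f"high_{k + 1}" for k in range(r)]
    matrix = pd.DataFrame(
        np.hstack([cond1, cond2]), index=pd.Index(gene_ids, name="gene_id"),
        columns=cols,
    )
    conditions = ["low"] * r + ["high"] * r
    truth = pd.DataFrame(
        {
            "bound": [g in bound for g in gene_ids],
            "direction": direction,
            "true_effect": effect,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return matrix, conditions, truth


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produced, plus its ground truth."""

    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    sites: list[PlantedSite]
    chip_tags: list[TagAlignment]
    input_tags: list[TagAlignment]
    expression: pd.DataFrame
    conditions: list[str]
    truth: pd.DataFrame

    @property
    def bound_gene_ids(self) -> list[str]:
        return sorted(
            {s.linked_gene_id for s in self.sites if s.linked_gene_id}
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        write_gene_models(self.genes, outdir / "genes.bed")
        write_tags(self.chip_tags, outdir / "chip.bed")
        write_tags(self.input_tags, outdir / "input.bed")
        write_expression(self.expression, outdir / "expression.tsv")
        write_sites(self.sites, outdir / "sites.tsv")
        self.truth.to_csv(outdir / "bound_genes.tsv", sep="\t")


def write_sites(sites: Iterable[PlantedSite], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom, "position": s.position, "strand": s.strand,
                "sequence": s.sequence,
                "linked_gene_id": s.linked_gene_id or ".",
                "occupancy": s.occupancy,
            }
            for s in sites
        ],
        columns=[
            "chrom", "position", "strand", "sequence",
            "linked_gene_id", "occupancy",
        ],
    ).to_csv(path, sep="\t", index=False)


def simulate_study(
    config: SimulationConfig, decouple_expression: bool = False
) -> SimulatedStudy:
    """Run the whole generator: genome, genes, sites, tags, expression.

    ``decouple_expression=True`` breaks the binding-to-regulation link (the
    null for the integration stage): the planted DE genes are drawn from the
    unbound genes instead of the bound ones.
    """
    genome, genes = make_genome_and_genes(config)
    genome, sites = plant_binding_sites(
        genome, genes, config.site_sequence, config
    )
    chip, inp = simulate_tags(genome, sites, config)
    bound = sorted({s.linked_gene_id for s in sites if s.linked_gene_id})
    if decouple_expression:
        rng = _rng_for(config, 5)
        pool = [g.gene_id for g in genes if g.gene_id not in set(bound)]
        fake = sorted(
            rng.choice(pool, size=min(len(bound), len(pool)), replace=False)
        )
        matrix, conditions, truth = simulate_expression(genes, fake, config)
    else:
        matrix, conditions, truth = simulate_expression(genes, bound, config)
    return SimulatedStudy(
        config=config, genome=genome, genes=genes, sites=sites,
        chip_tags=chip, input_tags=inp, expression=matrix,
        conditions=conditions, truth=truth,
    )
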
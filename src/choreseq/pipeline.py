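"""End-to-end pipeline: simulate (or load) -> coverage -> peaks -> annotation
-> motifs -> differential expression -> KS integration.

A single structured YAML config drives every stage; each run writes a report
bundle (BED/TSV outputs, a JSON summary and a text summary) into the output
directory.  Outputs carry the seed and a hash of the config, and a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import annotate as annotate_mod
from . import core_io, expression, integrate, motifs, peaks, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters plus either a simulation block or input file paths."""

    seed: int
    outdir: str = "choreseq_out"
    # inputs: either simulate=True (SimulationConfig fields in `simulation`)
    # or explicit paths
    simulate: bool = True
    simulation: dict = field(default_factory=dict)
    genome_fasta: str | None = None
    genes_bed: str | None = None
    chip_bed: str | None = None
    input_bed: str | None = None
    expression_tsv: str | None = None
    gene_sets_gmt: str | None = None
    # peak calling
    extension_length: int = 200
    min_height: int = 8
    min_ratio: float = 5.0
    pseudocount: float = 1.0
    merge_gap: int = 100
    # annotation
    max_tss_distance: int = 20_000
    # motifs
    ebox_consensus: str = "CAYGNG"
    chore_spacer: int = 5
    site_alpha: float = 0.002
    # the degenerate E-box family PWM has 8/4096 = 0.00195 consensus mass, so
    # the scan threshold cannot be tighter than that
    scan_alpha: float = 0.002
    discover_width: int = 17
    discover_n_starts: int = 3
    discover_max_iter: int = 200
    run_discovery: bool = True
    # differential expression
    ppde_cutoff: float = 0.95
    # integration
    n_perm: int = 10_000

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded,
        so the same analysis hashes identically wherever it is written)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _simulation_config(config: PipelineConfig) -> simulate.SimulationConfig:
    kwargs = dict(config.simulation)
    kwargs.setdefault("seed", config.seed)
    return simulate.SimulationConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage in order and write the report bundle.

    Returns the JSON-style summary dictionary.  Any stage failure raises with
    the stage name prepended.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    stage = "simulate/load"
    try:
        if config.simulate:
            sim_cfg = _simulation_config(config)
            study = simulate.simulate_study(sim_cfg)
            study.write(outdir / "simulated")
            genome = study.genome
            genes = study.genes
            chip_tags = study.chip_tags
            input_tags = study.input_tags
            matrix, conditions = study.expression, study.conditions
            truth_sites = study.sites
            bound_truth = study.bound_gene_ids
        else:
            for name in ("genome_fasta", "genes_bed", "chip_bed", "input_bed",
                         "expression_tsv"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input {name}: {p}")
            genome = core_io.GenomeSequence.from_fasta(config.genome_fasta)
            genes = core_io.read_gene_models(config.genes_bed)
            chip_tags = core_io.read_tags(config.chip_bed, genome)
            input_tags = core_io.read_tags(config.input_bed, genome)
            matrix, conditions = core_io.read_expression(config.expression_tsv)
            truth_sites = None
            bound_truth = None
        summary["n_chip_tags"] = len(chip_tags)
        summary["n_input_tags"] = len(input_tags)
        summary["n_genes"] = len(genes)

        stage = "coverage"
        chrom_lengths = genome.lengths
        chip_cov = peaks.build_coverage(
            chip_tags, config.extension_length, chrom_lengths
        )
        input_cov = peaks.build_coverage(
            input_tags, config.extension_length, chrom_lengths
        )
        summary["input_scale"] = (
            chip_cov.total_tags / input_cov.total_tags
            if input_cov.total_tags
            else None
        )

        stage = "peaks"
        called = peaks.call_peaks(
            chip_cov, input_cov,
            min_height=config.min_height, min_ratio=config.min_ratio,
            pseudocount=config.pseudocount, merge_gap=config.merge_gap,
        )
        peaks.write_peaks_bed(called, outdir / "peaks.bed")
        pk_summary = peaks.summarize_peaks(called)
        summary["n_peaks"] = pk_summary.count
        summary["mean_peak_width"] = pk_summary.mean_width
        summary["median_peak_width"] = pk_summary.median_width
        if truth_sites:
            recov = site_recovery(called, truth_sites)
            summary["site_recovery_fraction"] = recov["recovered_fraction"]
            summary["median_summit_error_bp"] = recov["median_summit_error"]

        stage = "annotate"
        annotations = annotate_mod.annotate_peaks(
            called, genes, config.max_tss_distance
        )
        annotate_mod.write_annotations(annotations, outdir / "annotations.tsv")
        summary["category_fractions"] = annotate_mod.category_fractions(annotations)
        edges, counts = annotate_mod.tss_distance_profile(annotations)
        np.savetxt(
            outdir / "tss_distance_profile.tsv",
            np.column_stack([edges[:-1], edges[1:], counts]),
            fmt="%d", delimiter="\t",
            header="bin_start\tbin_end\tcount", comments="",
        )
        target_genes = sorted(
            {a.gene_id for a in annotations if a.gene_id is not None}
        )
        summary["n_target_genes"] = len(target_genes)

        stage = "motifs"
        peak_seqs = {
            f"peak_{k + 1}": genome.fetch(p.chrom, p.start, p.end)
            for k, p in enumerate(called)
        }
        ebox = motifs.PWM.from_consensus(config.ebox_consensus)
        motif_summary = {}
        if peak_seqs:
            hits, hit_counts = motifs.scan_sequences(
                peak_seqs, ebox, config.scan_alpha
            )
            _write_hits(hits, outdir / "motif_hits.tsv")
            motif_summary["fraction_peaks_with_ebox"] = float(
                np.mean([c > 0 for c in hit_counts.values()])
            )
            motif_summary["hit_count_histogram"] = motifs.hit_count_histogram(
                hit_counts
            )
            all_pairs = []
            for sid, seq in peak_seqs.items():
                all_pairs.extend(
                    motifs.find_chore_pairs(
                        seq, ebox, config.chore_spacer, config.site_alpha, sid
                    )
                )
            _write_pairs(all_pairs, outdir / "chore_pairs.tsv")
            motif_summary["fraction_peaks_with_chore"] = float(
                np.mean(
                    [
                        any(p.seq_id == sid for p in all_pairs)
                        for sid in peak_seqs
                    ]
                )
            )
            if config.run_discovery and len(peak_seqs) >= 5:
                disc = motifs.discover_motif_em(
                    peak_seqs, config.discover_width,
                    n_starts=config.discover_n_starts, seed=config.seed,
                    max_iter=config.discover_max_iter,
                )
                disc.pwm.to_meme(outdir / "discovered_motif.meme", "discovered")
                motif_summary["discovered_consensus"] = disc.pwm.consensus()
                motif_summary["discovered_relative_entropy"] = disc.relative_entropy
        summary["motifs"] = motif_summary

        stage = "expression"
        de = expression.moderated_t_ppde(matrix, conditions)
        de.to_tsv(outdir / "differential_expression.tsv")
        up, down = expression.de_gene_list(de, config.ppde_cutoff)
        summary["n_de_genes"] = len(up) + len(down)
        summary["bum_lambda"] = de.bum.lambda_

        stage = "integrate"
        ranked = expression.rank_genes(de, "ppde")
        in_list = [g for g in target_genes if g in set(ranked)]
        if in_list and len(in_list) < len(ranked):
            enr = integrate.ks_enrichment(ranked, in_list)
            enr = integrate.ks_significance(
                enr, n_perm=config.n_perm, seed=config.seed
            )
            enr.profile_frame().to_csv(
                outdir / "running_sum.tsv", sep="\t", index=False
            )
            summary["ks"] = {
                "N": enr.N, "Nh": enr.Nh, "es": enr.es,
                "p_perm": enr.p_perm, "p_exact": enr.p_exact,
                "n_leading_edge": len(enr.leading_edge),
            }
            n_up, n_down, _, _ = integrate.split_targets_by_direction(
                in_list, de, config.ppde_cutoff
            )
            summary["targets_up"] = n_up
            summary["targets_down"] = n_down
        else:
            summary["ks"] = None
        if config.gene_sets_gmt:
            sets = core_io.read_gmt(config.gene_sets_gmt)
            table = integrate.ora_hypergeometric(
                target_genes, sets, [g.gene_id for g in genes]
            )
            table.to_csv(outdir / "ora.tsv", sep="\t", index=False)
        if bound_truth is not None:
            summary["bound_truth_n"] = len(bound_truth)
            summary["targets_matching_truth"] = len(
                set(target_genes) & set(bound_truth)
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    (outdir / "summary.txt").write_text(_text_summary(summary))
    return summary


def site_recovery(
    called: list[peaks.Peak],
    sites: list[simulate.PlantedSite],
    summit_tolerance: int = 50,
) -> dict[str, Any]:
    """Score called peaks against planted sites: fraction of sites inside a
    peak and summit-to-site-centre distances."""
    recovered = 0
    errors = []
    for s in sites:
        hit = None
        for p in called:
            if p.chrom == s.chrom and p.start <= s.center < p.end:
                hit = p
                break
        if hit is not None:
            recovered += 1
            errors.append(abs(hit.summit - s.center))
    return {
        "n_sites": len(sites),
        "n_recovered": recovered,
        "recovered_fraction": recovered / len(sites) if sites else None,
        "median_summit_error": float(np.median(errors)) if errors else None,
        "n_within_tolerance": int(
            sum(e <= summit_tolerance for e in errors)
        ),
    }


def _write_hits(hits, path):
    with open(path, "w") as fh:
        fh.write("seq_id\toffset\tstrand\tscore\tlog_odds\tpvalue\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.offset}\t{h.strand}\t{h.score:.4f}\t"
                f"{h.log_odds:.4f}\t{h.pvalue:.3g}\n"
            )


def _write_pairs(pairs, path):
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tspacer\torientation\tscore\n")
        for p in pairs:
            fh.write(
                f"{p.seq_id}\t{p.start}\t{p.spacer}\t{p.orientation}\t"
                f"{p.score:.4f}\n"
            )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def _text_summary(summary: dict[str, Any]) -> str:
    lines = [
        "choreseq pipeline summary",
        f"  seed: {summary['seed']}   config: {summary['config_hash']}",
        f"  tags: ChIP {summary.get('n_chip_tags')} / input {summary.get('n_input_tags')}"
        f" (scale {summary.get('input_scale'):.4g})"
        if summary.get("input_scale")
        else f"  tags: ChIP {summary.get('n_chip_tags')} / input {summary.get('n_input_tags')}",
        f"  peaks: {summary.get('n_peaks')}"
        + (
            f" (mean width {summary['mean_peak_width']:.1f} bp)"
            if summary.get("mean_peak_width")
            else ""
        ),
    ]
    if summary.get("site_recovery_fraction") is not None:
        lines.append(
            f"  planted-site recovery: {100 * summary['site_recovery_fraction']:.1f}%"
        )
    if summary.get("category_fractions"):
        frac = summary["category_fractions"]
        lines.append(
            "  peak categories: "
            + ", ".join(f"{k} {100 * v:.0f}%" for k, v in frac.items() if v)
        )
    if summary.get("motifs"):
        m = summary["motifs"]
        if "fraction_peaks_with_chore" in m:
            lines.append(
                f"  peaks with ChoRE pair: {100 * m['fraction_peaks_with_chore']:.1f}%"
            )
    if summary.get("ks"):
        ks = summary["ks"]
        lines.append(
            f"  KS enrichment: ES = {ks['es']:.3f}, Nh/N = {ks['Nh']}/{ks['N']}, "
            f"p_perm = {ks['p_perm']:.3g}"
        )
    if "targets_up" in summary:
        lines.append(
            f"  bound DE genes: {summary['targets_up']} up / "
            f"{summary['targets_down']} down"
        )
    return "\n".join(lines) + "\n"
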
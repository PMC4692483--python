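"""End-to-end orchestration: scan -> background -> clusters -> filters ->
annotation -> (optional) orthology -> ranked report.

Every stage's intermediate is persisted under the run directory with a
fixed name, and the log reconciles counts entering and leaving each
filter so nothing disappears silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import annotation as ann
from .background import build_ensembles
from .clusters import FILTER_NAMES, Cluster, detect_clusters
from .config import PipelineConfig
from .genome import read_fasta, scan_sites, softmask_intervals, write_sites_bed
from .pwm import enumerate_vocabulary, load_matrix

log = logging.getLogger(__name__)


def run_scan(config: PipelineConfig, out_dir: Path | None = None):
    """Vocabulary construction plus the native genome scan."""
    if config.genome is None or config.matrix is None:
        raise FileNotFoundError("run_scan needs both a genome FASTA and a matrix file")
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pwm = load_matrix(config.matrix, format=config.matrix_format, civ_min=config.civ_core_min)
    vocab = enumerate_vocabulary(pwm, min_mss=config.min_mss, concordance_positions=config.concordance_positions)
    genome = read_fasta(config.genome, softmask_as_repeat=config.softmask_as_repeat)
    sites = scan_sites(genome, vocab)
    vocab.write_tsv(out / "vocabulary.tsv")
    write_sites_bed(sites, out / "sites.bed")
    per_chrom = {c: sum(1 for s in sites if s.chrom == c) for c in genome.chromosomes}
    log.info("scan: %d sites (%d sense k-mers in vocabulary); per chromosome: %s", len(sites), len(vocab), per_chrom)
    return genome, pwm, vocab, sites


def run_full(config: PipelineConfig) -> list[Cluster]:
    """The whole cascade; returns the ranked reported clusters."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, pwm, vocab, sites = run_scan(config, out)

    rng = np.random.default_rng(config.seed)
    ensembles = build_ensembles(
        genome,
        sites,
        vocab,
        rng,
        model=config.background_model,
        n_raw=config.n_raw,
        n_replicates=config.n_replicates,
    )
    for chrom, ens in ensembles.items():
        ens.write_tsv(out / f"ensemble_{chrom}.tsv")

    exons = ann.read_bed(config.exons_bed, "exons") if config.exons_bed else None
    repeats = ann.read_bed(config.repeats_bed, "repeats") if config.repeats_bed else None
    if config.refflat and exons is None:
        exons = ann.exon_interval_set(ann.read_refflat(config.refflat))
    if config.softmask_as_repeat:
        soft = ann.IntervalSet("softmask", softmask_intervals(genome))
        repeats = soft if repeats is None else ann.IntervalSet(
            "repeats+softmask", repeats.intervals + soft.intervals
        )

    windows, reported = detect_clusters(sites, ensembles, config.cluster, exons=exons, repeats=repeats)
    _write_windows(windows, out / "windows.tsv")

    if config.lifted_bed:
        lifted = ann.read_bed(config.lifted_bed, "lifted")
        before = len(reported)
        reported = ann.ortholog_overlap_filter(reported, lifted)
        log.info("orthology filter: %d -> %d clusters", before, len(reported))
    else:
        log.info("orthology filter skipped: no lifted cluster BED configured")

    models = ann.read_refflat(config.refflat) if config.refflat else []
    ctcf = ann.read_bed(config.ctcf_bed, "ctcf") if config.ctcf_bed else None
    _write_report(reported, models, ctcf, out / "clusters.tsv")
    ann.write_bed([(c.chrom, c.start, c.end) for c in reported], out / "clusters.bed")
    _write_manifest(config, windows, reported, out / "manifest.json")
    return reported


def _write_windows(windows: list[Cluster], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_sites\tspan\tavg_mss\tmax_mss\texpected\tcc\tsite_fraction\t" + "\t".join(f"pass_{f}" for f in FILTER_NAMES) + "\n")
        for c in windows:
            flags = "\t".join(str(int(c.flags.get(f, True))) for f in FILTER_NAMES)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.n_sites}\t{c.span}\t{c.avg_mss:.3f}\t{c.max_mss:.3f}"
                f"\t{c.expected_sites:.4f}\t{c.cc:.3f}\t{c.site_bp_fraction:.4f}\t{flags}\n"
            )


def _write_report(reported: list[Cluster], models, ctcf, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("coords\tn_sites\tavg_mss\tmax_mss\texpected\tcc\tnearest_gene\tdistance\tfeature\tctcf_distance\tsite_kmers\n")
        for c in reported:
            if models:
                a = ann.annotate_site((c.chrom, c.start, c.end), models, ctcf)
                gene, dist, feat, cd = a.gene, a.distance, a.feature, a.ctcf_distance
            else:
                gene = dist = feat = cd = None
            kmers = ",".join(f"{s.kmer}@{s.start}{s.strand}" for s in c.sites)
            fh.write(
                f"{c.display_coords()}\t{c.n_sites}\t{c.avg_mss:.3f}\t{c.max_mss:.3f}"
                f"\t{c.expected_sites:.4f}\t{c.cc:.3f}\t{gene}\t{dist}\t{feat}\t{cd}\t{kmers}\n"
            )


def _write_manifest(config: PipelineConfig, windows, reported, path: Path) -> None:
    failures = {name: sum(1 for c in windows if not c.flags.get(name, True)) for name in FILTER_NAMES}
    manifest = {
        "seed": config.seed,
        "background_model": config.background_model,
        "n_raw": config.n_raw,
        "n_replicates": config.n_replicates,
        "n_candidate_windows": len(windows),
        "n_passing_windows": sum(1 for c in windows if c.passed),
        "n_reported_clusters": len(reported),
        "filter_failures": failures,
    }
    path.write_text(json.dumps(manifest, indent=2) + "\n")
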
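"""Replicated simulation suites exercising the caller's core behaviors.

Each suite builds synthetic datasets at desk scale, runs the full pipeline
(simulate → filter → assemble → call → evaluate) and reports summary
statistics.  The suites correspond to the properties the method is designed
around: exact homozygous indel recovery, heterozygote retention through
relaxed graph simplification, the coverage-drop false-deletion guard, and
the benefit of adding low-coverage long reads to reduced-coverage linked
reads.
"""

from __future__ import annotations

import logging
import shutil
import tempfile

import numpy as np

from .evaluate import match_calls
from .io import read_vcf_calls, write_fasta
from .model import Config
from .pipeline import run_pipeline
from .simulate import (SimConfig, simulate_genome_with_svs,
                       simulate_long_reads, simulate_slr_reads)

log = logging.getLogger(__name__)

#: homozygous-exactness study conditions
HOM_LENGTHS = [60, 300, 1000, 5000, 9500]


def _rep_seed(base_seed: int, index: int) -> int:
    return (base_seed * 100_003 + 7919 * index) % (1 << 31)


def _run_once(sim: SimConfig, config: Config, hybrid: bool = False,
              workdir: str | None = None):
    """Simulate one dataset and run the caller; returns (calls, truth,
    MatchResult)."""
    d = tempfile.mkdtemp(prefix="lasv_bench_", dir=workdir)
    try:
        ref, haps, truths = simulate_genome_with_svs(
            sim, truth_vcf=f"{d}/truth.vcf")
        write_fasta(ref, f"{d}/ref.fa")
        simulate_slr_reads(haps, sim, ref, truths, f"{d}/slr.bam")
        long_bam = None
        if hybrid:
            simulate_long_reads(haps, sim, ref, truths, f"{d}/long.bam")
            long_bam = f"{d}/long.bam"
        vcf, _ = run_pipeline(f"{d}/ref.fa", f"{d}/slr.bam", long_bam,
                              config, f"{d}/run")
        calls = read_vcf_calls(vcf)
        truth = read_vcf_calls(f"{d}/truth.vcf")
        return calls, truth, match_calls(calls, truth, config)
    finally:
        shutil.rmtree(d, ignore_errors=True)


def hom_exactness_suite(n_replicates: int = 20, seed: int = 1,
                        genome_length: int = 1_000_000,
                        n_svs: int = 10) -> dict:
    """Homozygous indels (60 bp - 9.5 kbp) in error-free 40x linked reads:
    every matched call must have exactly the implanted length."""
    reps = []
    svlens: list[int] = []
    for r in range(n_replicates):
        s = _rep_seed(seed, r)
        sim = SimConfig(genome_length=genome_length, n_svs=n_svs,
                        sv_lengths=HOM_LENGTHS, sv_types=["DEL", "INS"],
                        zygosity="hom", slr_coverage=40.0,
                        short_read_error=0.0, seed=s)
        calls, truth, res = _run_once(sim, Config(random_seed=s))
        svlens.extend(c.svlen for c in calls)
        reps.append({
            "precision": res.precision,
            "recall": res.recall,
            "exact": all(c.svlen == t.svlen for c, t in res.true_positives),
        })
        log.info("hom replicate %d: P=%.2f R=%.2f", r, res.precision,
                 res.recall)
    return {
        "replicates": reps,
        "min_precision": min(r["precision"] for r in reps),
        "min_recall": min(r["recall"] for r in reps),
        "mean_precision": float(np.mean([r["precision"] for r in reps])),
        "mean_recall": float(np.mean([r["recall"] for r in reps])),
        "all_exact": all(r["exact"] for r in reps),
        "call_svlens": svlens,
    }


def het_retention_suite(n_replicates: int = 50, seed: int = 2,
                        genome_length: int = 40_000) -> dict:
    """One heterozygous SV per replicate (50-5,000 bp) in diploid 40x
    reads; reports the fraction of replicates where it is called."""
    called = 0
    svlens: list[int] = []
    for r in range(n_replicates):
        s = _rep_seed(seed, r)
        rng = np.random.default_rng(s)
        length = int(rng.integers(50, 5_001))
        sim = SimConfig(genome_length=genome_length, n_svs=1,
                        sv_lengths=[length], zygosity="het",
                        slr_coverage=40.0, seed=s)
        calls, _, res = _run_once(sim, Config(random_seed=s))
        svlens.extend(c.svlen for c in calls)
        called += res.recall == 1.0
    return {
        "n": n_replicates,
        "called": called,
        "retention_rate": called / n_replicates,
        "call_svlens": svlens,
    }


def coverage_gap_suite(n_replicates: int = 50, seed: int = 3,
                       tip_rule_enabled: bool = True) -> dict:
    """SV-free genomes with an interspersed repeat pair and a zero-coverage
    gap between the copies — the configuration where an assembler that
    extends through the repeat junction manufactures a false deletion.
    Reports how many replicates produce any deletion call."""
    with_false_del = 0
    svlens: list[int] = []
    for r in range(n_replicates):
        s = _rep_seed(seed, r)
        rng = np.random.default_rng(s)
        gap_len = int(rng.integers(500, 2_001))
        sim = SimConfig(genome_length=30_000, n_svs=0,
                        repeat_pairs=[(8_000, 11_000, 300)],
                        coverage_gap=(8_700, 8_700 + gap_len),
                        slr_coverage=40.0, seed=s)
        config = Config(random_seed=s, tip_rule_enabled=tip_rule_enabled)
        calls, _, _ = _run_once(sim, config)
        svlens.extend(c.svlen for c in calls)
        dels = [c for c in calls if c.svtype == "DEL"]
        with_false_del += bool(dels)
    return {
        "n": n_replicates,
        "replicates_with_false_deletion": with_false_del,
        "clean_replicates": n_replicates - with_false_del,
        "call_svlens": svlens,
    }


def hybrid_benefit_suite(n_replicates: int = 50, seed: int = 4) -> dict:
    """Paired-seed comparison at deliberately reduced linked-read coverage
    (15x) with vs without 5x long reads; reports how often hybrid recall is
    at least / strictly above SLR-only recall."""
    not_worse = strictly_better = 0
    recalls = []
    svlens: list[int] = []
    for r in range(n_replicates):
        s = _rep_seed(seed, r)
        sim = SimConfig(genome_length=80_000, n_svs=8,
                        sv_lengths=[150, 600, 2_500], zygosity="hom",
                        min_sv_spacing=1_500, slr_coverage=15.0,
                        long_read_coverage=5.0, seed=s)
        calls_s, _, res_slr = _run_once(sim, Config(random_seed=s),
                                        hybrid=False)
        calls_h, _, res_hyb = _run_once(sim, Config(random_seed=s),
                                        hybrid=True)
        svlens.extend(c.svlen for c in calls_s + calls_h)
        not_worse += res_hyb.recall >= res_slr.recall
        strictly_better += res_hyb.recall > res_slr.recall
        recalls.append((res_slr.recall, res_hyb.recall))
    return {
        "n": n_replicates,
        "not_worse": not_worse,
        "strictly_better": strictly_better,
        "mean_slr_recall": float(np.mean([a for a, _ in recalls])),
        "mean_hybrid_recall": float(np.mean([b for _, b in recalls])),
        "call_svlens": svlens,
    }
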
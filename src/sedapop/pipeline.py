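"""End-to-end pipeline driver.

Chains the stages — filter → map → dedup → iterative consensus → damage
profiling → transversion-only variants → haplogroup consensus splitting →
replicated allele proportions → linked-window haplotype counting — over one
or more samples against a seed organellar genome, writing every stage
output plus a machine-readable summary.  One master seed drives labelled
substreams per stochastic stage, so identical seed + inputs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path
from typing import Mapping

import numpy as np

from . import io as sio
from .align import (build_pileup, map_reads, mean_coverage,
                    remove_coordinate_duplicates, remove_exact_duplicates,
                    _ReferenceIndex)
from .config import PipelineConfig
from .consensus import iterate_consensus
from .damage import damage_profile
from .filtering import filter_reads
from .linkage import (find_linked_windows, score_sample, summarize_haplotypes,
                      windows_to_tsv)
from .variants import (allele_proportions, apply_variant_consensus,
                       call_variants, damage_restricted_recall,
                       half_mean_coverage, restrict_transversions,
                       split_high_low)

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("sedapop")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _substream(master: int, *labels: int) -> int:
    return int(np.random.SeedSequence((master, *labels)).generate_state(1)[0]
               % (2 ** 31))


def _log(stage: str, msg: str) -> None:
    if not logger.handlers and not logging.getLogger().handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s [%(name)s:%(stage)s] %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    logger.info(msg, extra={"stage": stage})


def _variant_table(sites) -> str:
    lines = ["pos\tcomposite\talleles\tcounts\tproportions\tqual\tdepth"
             "\ttransversion\trare_removed"]
    for s in sites:
        bases = ",".join(b for b, _, _ in s.alleles)
        counts = ",".join(str(c) for _, c, _ in s.alleles)
        props = ",".join(f"{p:.4f}" for _, _, p in s.alleles)
        lines.append(
            f"{s.pos + 1}\t{s.composite_base}\t{bases}\t{counts}\t{props}"
            f"\t{s.qual:.1f}\t{s.depth}\t{int(s.is_transversion)}"
            f"\t{','.join(s.rare_removed) or '.'}")
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: PipelineConfig,
    reads: str | Path | Mapping[str, str | Path],
    seed_reference: str | Path,
    out_dir: str | Path,
) -> dict[str, object]:
    """Run the full analysis chain and write stage outputs under ``out_dir``.

    ``reads`` is one FASTQ path or a mapping of sample-id to FASTQ path.
    Returns the summary dictionary also written to ``summary.tsv``.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(reads, Mapping):
        reads = {"sample1": reads}
    for sample, path in reads.items():
        if not Path(path).exists():
            raise PipelineError("input", f"reads file not found: {path}")
    ref_path = Path(seed_reference)
    if not ref_path.exists():
        raise PipelineError("input", f"seed reference not found: {ref_path}")
    seed_ref = next(iter(sio.read_fasta(ref_path).values()))
    cfg = config
    summary: dict[str, object] = {"rng_seed": cfg.rng_seed}

    # ---- filter -----------------------------------------------------------
    filtered: dict[str, list[sio.FastqRead]] = {}
    for sample, path in sorted(reads.items()):
        raw = sio.read_fastq(path)
        kept, report = filter_reads(raw, cfg)
        filtered[sample] = kept
        (out / f"{sample}.filter_report.tsv").write_text(report.to_tsv())
        summary[f"{sample}.n_input"] = report.n_input
        summary[f"{sample}.n_retained"] = report.n_retained
        _log("filter", f"{sample}: {report.n_retained}/{report.n_input} retained")
    combined = [r for s in sorted(filtered) for r in filtered[s]]
    if not combined:
        raise PipelineError("filter", "no reads survive filtering")

    # ---- iterative composite consensus (samples pooled) -------------------
    cons = iterate_consensus(combined, seed_ref, cfg)
    composite = cons.sequence
    sio.write_fasta({"composite": composite}, out / "composite.fasta")
    with open(out / "consensus_iterations.tsv", "w") as fh:
        fh.write("iteration\tedits\n")
        for i, e in enumerate(cons.edits_per_iteration):
            fh.write(f"{i + 1}\t{e}\n")
    with open(out / "coverage_gaps.bed", "w") as fh:
        for a, b in cons.gap_intervals:
            fh.write(f"composite\t{a}\t{b}\tgap\n")
        for a, b in cons.low_intervals:
            fh.write(f"composite\t{a}\t{b}\tlow\n")
    summary["consensus.iterations"] = cons.n_iterations
    summary["consensus.converged"] = int(cons.converged)
    summary["consensus.mean_coverage"] = round(cons.mean_coverage, 2)
    summary["consensus.n_gaps"] = len(cons.gap_intervals)
    _log("consensus", f"{cons.n_iterations} iteration(s), "
         f"mean coverage {cons.mean_coverage:.1f}x")

    comp_index = _ReferenceIndex(composite)
    pooled_tv_sites = []
    per_sample_mapped: dict[str, list] = {}
    per_sample_dmg = {}

    for sample in sorted(filtered):
        # ---- map + dedup --------------------------------------------------
        mapped = map_reads(filtered[sample], composite, cfg.max_mismatch_rate,
                           sample_id=sample, index=comp_index)
        mapped = remove_coordinate_duplicates(mapped)
        if not mapped:
            raise PipelineError("map", f"{sample}: no reads map to the composite")
        per_sample_mapped[sample] = mapped
        sio.write_sam(mapped, "composite", len(composite),
                      out / f"{sample}.composite.sam")
        pile = build_pileup(mapped, composite)
        summary[f"{sample}.mean_coverage"] = round(mean_coverage(pile), 2)

        # ---- damage profile ----------------------------------------------
        prof = damage_profile(mapped, composite,
                              length_cap=cfg.profile_length_cap)
        (out / f"{sample}.damage_profile.tsv").write_text(prof.to_tsv())
        ct0 = prof.ct5[0] if len(prof.ct5) else float("nan")
        summary[f"{sample}.ct5_terminal"] = (
            round(float(ct0), 4) if np.isfinite(ct0) else "NA")
        per_sample_dmg[sample] = prof

        # ---- variants -----------------------------------------------------
        min_cov = half_mean_coverage(pile, cfg.var_cov_fraction)
        sites = call_variants(pile, composite, cfg.var_min_qual, min_cov)
        tv = restrict_transversions(sites, cfg.rare_allele_floor)
        (out / f"{sample}.variants.tsv").write_text(_variant_table(tv))
        summary[f"{sample}.n_variants"] = len(sites)
        summary[f"{sample}.n_transversion_variants"] = len(tv)
        pooled_tv_sites.extend(tv)
        _log("variants", f"{sample}: {len(tv)} transversion-only site(s)")

        # ---- haplogroup consensus pair ------------------------------------
        high, low, flagged = split_high_low(tv, composite)
        high_seq = apply_variant_consensus(composite, high)
        low_seq = apply_variant_consensus(composite, low)
        sio.write_fasta({f"{sample}_high": high_seq, f"{sample}_low": low_seq},
                        out / f"{sample}.haplogroups.fasta")
        n_groups = 2 if low else 1
        summary[f"{sample}.n_haplogroups"] = n_groups
        summary[f"{sample}.n_flagged_sites"] = len(flagged)

        # ---- replicated allele proportions -------------------------------
        merged = (map_reads(filtered[sample], high_seq, cfg.max_mismatch_rate,
                            sample_id=sample)
                  + map_reads(filtered[sample], low_seq, cfg.max_mismatch_rate,
                              sample_id=sample))
        prop = allele_proportions(merged, composite, cfg, seed=cfg.rng_seed)
        with open(out / f"{sample}.proportions.tsv", "w") as fh:
            fh.write("replicate\tmean_alt_proportion\tn_sites\n")
            for rep in prop.replicates:
                fh.write(f"{rep.replicate}\t{rep.mean_alt:.4f}"
                         f"\t{len(rep.per_site_alt)}\n")
        summary[f"{sample}.mean_alt_proportion"] = round(
            float(np.mean(prop.mean_alt_per_replicate)), 4)

        # ---- damage-restricted validation --------------------------------
        recall = damage_restricted_recall(tv, mapped, composite, cfg)
        summary[f"{sample}.damage_restricted_recall"] = round(recall, 4)

    # ---- linked-window haplotype counting (sites pooled, scored per sample)
    dedup = {s.pos: s for s in sorted(pooled_tv_sites, key=lambda s: s.pos)}
    clusters = find_linked_windows(list(dedup.values()), cfg.window_span)
    windows_per_sample = {}
    est_overall = 0
    for si, sample in enumerate(sorted(per_sample_mapped)):
        reps = []
        for rep in range(cfg.n_dedup_replicates):
            sub = _substream(cfg.rng_seed, 202, si, rep)
            dd = remove_coordinate_duplicates(
                remove_exact_duplicates(per_sample_mapped[sample], sub))
            reps.append(score_sample(clusters, dd, cfg.hap_min_reads,
                                     cfg.hap_min_fraction))
        windows_per_sample[sample] = reps[0]
        rep_estimates = [max((w.count for w in ws), default=0) for ws in reps]
        summary[f"{sample}.hap_estimate_per_replicate"] = ",".join(
            str(e) for e in rep_estimates)
        est_overall = max(est_overall, *rep_estimates)
    if clusters:
        hap = summarize_haplotypes(windows_per_sample)
        (out / "linked_windows.tsv").write_text(
            windows_to_tsv(windows_per_sample))
        for sample, mean in sorted(hap.per_sample_mean.items()):
            summary[f"{sample}.hap_window_mean"] = (
                round(mean, 4) if np.isfinite(mean) else "NA")
    summary["n_linked_windows"] = len(clusters)
    summary["min_haplotype_estimate"] = est_overall
    _log("haplotypes", f"minimum haplotype estimate {est_overall} over "
         f"{len(clusters)} window(s) in {time.time() - t0:.1f}s")

    lines = [f"{k}\t{summary[k]}" for k in sorted(summary)]
    (out / "summary.tsv").write_text("\n".join(lines) + "\n")
    return summary
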
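"""End-to-end pipeline: simulate (or load) -> call -> analyses -> manifest.

A run is fully determined by its RunConfig (including the seed): rerunning
with the same config produces byte-identical outputs, which the manifest
records as SHA-256 digests alongside per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .caller import call_unique_mutations
from .indels import (
    deletion_context_table,
    detect_dinucleotides,
    insertion_context_table,
    intermutation_distances,
)
from .io import (
    read_fasta,
    read_pileup_tsv,
    sort_mutations,
    write_fasta,
    write_spectrum_tsv,
    write_triplet_table,
    write_vcf,
)
from .reversion import reversion_summary
from .simulate import SimConfig, simulate_cohort
from .spectra import count_spectrum, normalize_rates, triplet_occurrences
from .types import CallerParams, ReversionParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode must be set: a synthetic cohort (``sim``) or
    real inputs (``pileup_path`` + ``reference_path`` + sample ids).
    """

    outdir: str | Path = "clonemut_run"
    seed: int = 0
    sim: SimConfig | None = None
    pileup_path: str | Path | None = None
    reference_path: str | Path | None = None
    sample_ids: list[str] | None = None
    params: CallerParams = field(default_factory=CallerParams)
    reversion: ReversionParams = field(default_factory=ReversionParams)
    write_pileup: bool = False  # pileup TSV is large; opt in for small genomes
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.sim is None and self.pileup_path is None:
            raise ValueError("config needs either a SimConfig or real input paths")
        if self.sim is not None and self.pileup_path is not None:
            raise ValueError("choose one input mode: simulation or real pileup")
        if self.sim is not None:
            self.sim.seed = self.seed


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the output manifest (also written).

    On stage failure the partial manifest (with the failing stage named) is
    preserved in the output directory before the exception propagates.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "clonemut",
        "version": __version__,
        "seed": config.seed,
        "caller_params": asdict(config.params),
        "stages": {},
        "outputs": {},
    }

    def fail(stage: str, exc: Exception):
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise exc

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    # --- stage: inputs -----------------------------------------------------
    try:
        if config.sim is not None:
            reference, truth, pileup = simulate_cohort(config.sim)
            samples = config.sim.sample_ids
            truth_muts = sort_mutations(truth.all_unique() + truth.germline)
            truth_vcf = outdir / "truth.vcf"
            write_vcf(truth_muts, reference, truth_vcf)
            record("truth_vcf", truth_vcf)
            ref_fa = outdir / "reference.fa"
            write_fasta(reference, ref_fa)
            record("reference_fasta", ref_fa)
            if config.write_pileup:
                pu = outdir / "pileup.tsv"
                pileup.write_tsv(pu)
                record("pileup_tsv", pu)
            manifest["stages"]["inputs"] = {
                "mode": "simulate",
                "n_samples": len(samples),
                "n_implanted_unique": len(truth.all_unique()),
                "n_germline": len(truth.germline),
            }
        else:
            reference = read_fasta(config.reference_path)
            samples = config.sample_ids
            pileup = read_pileup_tsv(config.pileup_path, samples)
            truth = None
            manifest["stages"]["inputs"] = {"mode": "files", "pileup": str(config.pileup_path)}
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        fail("inputs", exc)

    # --- stage: call -------------------------------------------------------
    try:
        calls = call_unique_mutations(pileup, reference, config.params, samples)
        calls_vcf = outdir / "calls.vcf"
        write_vcf(sort_mutations(calls), reference, calls_vcf)
        record("calls_vcf", calls_vcf)
        per_sample = {sid: 0 for sid in samples}
        for m in calls:
            per_sample[m.sample_id] += 1
        stage: dict = {"n_calls": len(calls), "per_sample": per_sample}
        if truth is not None:
            # calls are left-aligned; canonicalise truth the same way
            from .caller import left_align_indel

            true_set = {
                (t.sample_id, t.chrom, t.pos, t.ref_allele, t.alt_allele)
                for t in (
                    left_align_indel(reference, m) if m.is_indel else m
                    for m in truth.all_unique()
                )
            }
            germ_pos = {(m.chrom, m.pos) for m in truth.germline}
            recovered = sum(
                (m.sample_id, m.chrom, m.pos, m.ref_allele, m.alt_allele) in true_set
                for m in calls
            )
            stage["n_true_recovered"] = recovered
            stage["n_calls_at_germline_sites"] = sum(
                (m.chrom, m.pos) in germ_pos for m in calls
            )
        manifest["stages"]["call"] = stage
    except Exception as exc:  # noqa: BLE001
        fail("call", exc)

    # --- stage: spectra ----------------------------------------------------
    try:
        snvs = [m for m in calls if m.mut_class == "SNV"]
        result = count_spectrum(snvs, reference)
        spec_tsv = outdir / "spectrum_counts.tsv"
        write_spectrum_tsv(result.spectrum, spec_tsv, "count")
        record("spectrum_counts", spec_tsv)
        occ = triplet_occurrences(reference)
        occ_tsv = outdir / "triplet_occurrences.tsv"
        write_triplet_table(occ, occ_tsv)
        record("triplet_occurrences", occ_tsv)
        if result.spectrum.total() > 0:
            rates = normalize_rates(result.spectrum, occ)
            rates_tsv = outdir / "spectrum_rates.tsv"
            write_spectrum_tsv(rates, rates_tsv, "rate_per_triplet")
            record("spectrum_rates", rates_tsv)
        manifest["stages"]["spectra"] = {
            "n_snvs": len(snvs),
            "n_unassignable": result.n_unassignable,
            "six_class": dict(zip(
                ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"),
                [int(x) for x in result.six_class],
            )),
        }
    except Exception as exc:  # noqa: BLE001
        fail("spectra", exc)

    # --- stage: indels -----------------------------------------------------
    try:
        dnv = detect_dinucleotides(snvs)
        ins_tab = insertion_context_table(reference, calls)
        del_tab = deletion_context_table(reference, calls)
        rain = intermutation_distances(sort_mutations(snvs))
        rain_tsv = outdir / "rainfall.tsv"
        with open(rain_tsv, "w") as fh:
            fh.write("sample\tchrom\tpos\tdistance\n")
            for m, d in rain:
                fh.write(f"{m.sample_id}\t{m.chrom}\t{m.pos}\t{d}\n")
        record("rainfall", rain_tsv)
        ctx_tsv = outdir / "indel_contexts.tsv"
        with open(ctx_tsv, "w") as fh:
            fh.write("kind\tpreceding\tbase\tfollowing\tcount\n")
            for (pre, b, fol), n in sorted(ins_tab.items()):
                fh.write(f"INS\t{pre}\t{b}\t{fol}\t{n}\n")
            for (pre, b, fol), n in sorted(del_tab.items()):
                fh.write(f"DEL\t{pre}\t{b}\t{fol}\t{n}\n")
        record("indel_contexts", ctx_tsv)
        manifest["stages"]["indels"] = {
            "n_dnv": len(dnv.dnvs),
            "n_multi_runs": len(dnv.multi_runs),
            "n_isolated_snvs": len(dnv.isolated),
            "n_ins_classified": int(sum(ins_tab.values())),
            "n_del_classified": int(sum(del_tab.values())),
        }
    except Exception as exc:  # noqa: BLE001
        fail("indels", exc)

    # --- stage: reversion --------------------------------------------------
    try:
        summary = reversion_summary(config.reversion)
        manifest["stages"]["reversion"] = {
            "indel_events_for_half_chance": summary.indel_events,
            "snv_events_for_half_chance": summary.snv_events,
            "cells_for_half_chance_indel": summary.cells_indel,
            "cells_for_half_chance_snv": summary.cells_snv,
            "cells_for_half_chance_combined": summary.cells_combined,
        }
    except Exception as exc:  # noqa: BLE001
        fail("reversion", exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
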
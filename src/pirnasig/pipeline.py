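"""End-to-end orchestration: simulate -> quantify -> signatures -> calls,
emitting a machine-readable JSON report plus TSVs.

The JSON report contains no wall-clock or host data, so identical configs
and seeds yield byte-identical reports; timestamps live in the log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bias import nucleotide_bias
from .errors import PipelineStageError
from .quant import abundance_frame, quantify
from .signatures import distance_spectrum, overlap_z, phasing_periodogram, pingpong
from .simulate import (
    SyntheticConfig,
    make_abundance_triplets,
    make_pingpong_reads,
    make_pirna_reads,
    make_rpf_reads,
    make_transcriptome,
    write_bed6,
    write_bed12,
)
from .stats import call_uppl, partial_correlation
from .transcripts import filter_reads, write_fasta, write_reads_tsv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Defaults reproduce the published analysis parameters: window 50,
    ping-pong max overlap 50, uppl thresholds (100 ppm, 0.90, 1 ppm),
    trim 0.10, pseudocount 0.001."""

    seed: int = 0
    out_dir: str = "pirnasig-out"
    preset: str = "uppl"
    n_transcripts: int = 30
    n_pirna: int = 20000
    n_rpf_orf: int = 10000
    n_rpf_utr3: int = 10000
    n_pingpong: int = 2000
    window: int = 50
    max_overlap: int = 50
    trim: float = 0.10
    pseudocount: float = 0.001
    uppl_thresholds: dict = field(
        default_factory=lambda: {"ppm": 100.0, "frac": 0.90, "rpf_ppm": 1.0}
    )
    synthetic: SyntheticConfig | None = None

    def resolved_synthetic(self) -> SyntheticConfig:
        if self.synthetic is not None:
            return self.synthetic
        return SyntheticConfig(seed=self.seed, n_transcripts=self.n_transcripts, preset=self.preset)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the synthetic end-to-end analysis and write report + TSV files.

    Stages run in dependency order; any failure raises PipelineStageError
    naming the stage, leaving completed stages' files in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = config.resolved_synthetic()
    # out_dir is a filesystem detail, not part of the analysis; excluding it
    # keeps reports byte-identical across output locations
    config_dict = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config": _jsonable(config_dict),
        }
    }

    def stage(name):
        def deco(fn):
            try:
                logger.info("pipeline stage: %s", name)
                return fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineStageError(name, exc) from exc

        return deco

    @stage("simulate")
    def artifacts():
        txome = make_transcriptome(syn)
        pirna = make_pirna_reads(syn, txome, n_reads=config.n_pirna)
        rpf = make_rpf_reads(
            syn, txome, pirna, n_orf=config.n_rpf_orf, n_utr3=config.n_rpf_utr3
        )
        pp_plus, pp_minus = make_pingpong_reads(
            syn, n_plus=config.n_pingpong, n_minus=config.n_pingpong
        )
        triplets = make_abundance_triplets(syn)
        write_bed12(txome.models, out / "transcripts.bed")
        write_fasta(txome.transcript_seqs, out / "transcripts.fa")
        write_fasta(txome.genome_seqs, out / "genome.fa")
        if txome.te_intervals:
            write_bed6(txome.te_intervals, out / "te.bed")
        write_reads_tsv(pirna, out / "pirna_reads.tsv")
        write_reads_tsv(rpf, out / "rpf_reads.tsv")
        write_reads_tsv(pp_plus, out / "pingpong_plus.tsv")
        write_reads_tsv(pp_minus, out / "pingpong_minus.tsv")
        triplets.to_csv(out / "abundance_triplets.tsv", sep="\t", index=False)
        return txome, pirna, rpf, pp_plus, pp_minus, triplets

    txome, pirna, rpf, pp_plus, pp_minus, triplets = artifacts

    @stage("filter-normalize")
    def filtered():
        pirna_f = filter_reads(pirna, preset="piRNA")
        rpf_f = filter_reads(rpf, preset="RPF")
        pirna_f.norm_denominator = float(pirna_f.total_count)
        rpf_f.norm_denominator = float(rpf_f.total_count)
        return pirna_f, rpf_f

    pirna_f, rpf_f = filtered

    @stage("quantify")
    def abundances():
        pirna_ab = quantify(pirna_f, txome.models, pseudocount=config.pseudocount)
        rpf_ab = quantify(rpf_f, txome.models, pseudocount=config.pseudocount)
        abundance_frame(pirna_ab).to_csv(out / "pirna_abundance.tsv", sep="\t", index=False)
        abundance_frame(rpf_ab).to_csv(out / "rpf_abundance.tsv", sep="\t", index=False)
        return pirna_ab, rpf_ab

    pirna_ab, rpf_ab = abundances

    by_id = {m.transcript_id: m for m in txome.models}

    @stage("overlap-spectrum")
    def overlap():
        rpf_utr3 = rpf_f.subset(
            lambda r: r.ref_id in by_id and r.five_prime >= by_id[r.ref_id].cds_end_t,
            label="RPF-3UTR",
        )
        pirna_utr3 = pirna_f.subset(
            lambda r: r.ref_id in by_id and r.five_prime >= by_id[r.ref_id].cds_end_t,
            label="piRNA-3UTR",
        )
        spec = distance_spectrum(rpf_utr3, pirna_utr3, window=config.window)
        spec.to_frame().to_csv(out / "overlap_spectrum.tsv", sep="\t", index=False)
        oz = overlap_z(spec)
        return {
            "comparison": "RPF-3UTR vs piRNA-3UTR",
            "z": oz.z,
            "p_one_sided": oz.p_one_sided,
            "focal_value": oz.focal_value,
            "spectrum_mass": spec.total_mass,
        }

    report["overlap"] = overlap

    @stage("periodogram")
    def phasing():
        rpf_orf = rpf_f.subset(
            lambda r: r.ref_id in by_id
            and by_id[r.ref_id].cds_start_t <= r.five_prime < by_id[r.ref_id].cds_end_t,
            label="RPF-ORF",
        )
        pg = phasing_periodogram(rpf_orf, window=config.window)
        pg.to_frame().to_csv(out / "orf_periodogram.tsv", sep="\t", index=False)
        return {
            "comparison": "RPF-ORF self spectrum",
            "peak_frequency": pg.peak_frequency,
            "peak_period_nt": pg.peak_period,
            "is_constant": pg.is_constant,
        }

    report["periodogram"] = phasing

    @stage("pingpong")
    def pp():
        result = pingpong(pp_plus, pp_minus, max_overlap=config.max_overlap)
        result.to_frame().to_csv(out / "pingpong_spectrum.tsv", sep="\t", index=False)
        return {
            "z10": result.z10,
            "p_one_sided": result.p_one_sided,
            "argmax_overlap": result.argmax_overlap,
        }

    report["pingpong"] = pp

    @stage("bias")
    def bias_summary():
        bm = nucleotide_bias(pirna_f, txome.transcript_seqs, k=10)
        bm.to_frame().to_csv(out / "pirna_bias.tsv", sep="\t", index=False)
        return {
            "p1_freq_U": bm.freq_at("p1", "U"),
            "p1_bits": bm.info_at("p1"),
        }

    report["bias"] = bias_summary

    @stage("coupling")
    def coupling():
        pc = partial_correlation(
            np.log10(triplets["pirna"] + config.pseudocount),
            np.log10(triplets["rpf"] + config.pseudocount),
            np.log10(triplets["rna"] + config.pseudocount),
        )
        return {"r": pc.r, "p": pc.p, "n": pc.n, "transform": "log10+pseudocount"}

    report["partial_correlation"] = coupling

    @stage("call-uppl")
    def calls():
        out_calls = call_uppl(pirna_ab, rpf_ab, txome.models, thresholds=config.uppl_thresholds)
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "transcript_id": c.transcript_id,
                    "pirna_ppm": c.pirna_ppm,
                    "frac_utr3": c.frac_utr3,
                    "rpf_orf_ppm": c.rpf_orf_ppm,
                    "is_uppl": c.is_uppl,
                    "failed_criteria": ";".join(c.failed_criteria),
                }
                for c in out_calls
            ]
        ).to_csv(out / "uppl_calls.tsv", sep="\t", index=False)
        return {
            "n_transcripts": len(out_calls),
            "n_uppl": sum(c.is_uppl for c in out_calls),
        }

    report["uppl_calls"] = calls

    report_json = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report_json
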
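"""End-to-end orchestration of the analysis stages from one config.

Stages run in dependency order (simulate? -> kmer -> spacing -> features
-> linkage -> dosage -> signal); a stage is skipped simply by omitting
its block from the config.  Outputs go to a fresh versioned run
directory, and a machine-readable :class:`RunReport` records per-stage
input digests, parameters, output paths, warning tallies and wall time.
All seeds are explicit in the config; reruns with identical config and
seeds produce identical output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import (
    feature_enrichment,
    io_core,
    kmer_context,
    linkage_dosage,
    signal_shift,
    spacing_periodicity,
    synthetic_data,
)
from .io_core import ConfigError, ModTable

STAGE_ORDER = ("simulate", "kmer", "spacing", "features", "linkage",
               "dosage", "signal")


@dataclass
class StageRecord:
    name: str
    parameters: dict
    input_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    warnings: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    status: str = "ok"
    error: Optional[str] = None


@dataclass
class RunReport:
    run_dir: str
    seed: int
    stages: list = field(default_factory=list)

    def to_json(self, path) -> None:
        obj = {"run_dir": self.run_dir, "seed": self.seed,
               "stages": [vars(s) for s in self.stages]}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(cfg: dict, key: str, stage: str):
    if key not in cfg:
        raise ConfigError(f"stage {stage!r}: missing required key {key!r}")
    return cfg[key]


def _next_run_dir(outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    i = 1
    while (outdir / f"run_{i:03d}").exists():
        i += 1
    run_dir = outdir / f"run_{i:03d}"
    run_dir.mkdir()
    return run_dir


def run_pipeline(config, outdir=None) -> RunReport:
    """Run the configured stages; ``config`` is a dict or a YAML path."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if outdir is None:
        outdir = config.get("outdir", "modscape_out")
    run_dir = _next_run_dir(Path(outdir))
    seed = int(config.get("seed", 0))
    report = RunReport(str(run_dir), seed)

    # resolved in-memory inputs, filled by simulate or loaded from paths
    data: dict = {}
    inputs_cfg = config.get("inputs", {})

    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        cfg = config[stage] or {}
        rec = StageRecord(stage, cfg)
        t0 = time.time()
        try:
            outs = _run_stage(stage, cfg, config, data, run_dir, seed, rec)
            rec.outputs = [str(p) for p in outs]
        except Exception as exc:  # record failure, keep partial results
            rec.status = "failed"
            rec.error = f"{type(exc).__name__}: {exc}"
            rec.wall_time_s = time.time() - t0
            report.stages.append(rec)
            report.to_json(run_dir / "run_report.json")
            raise
        rec.wall_time_s = time.time() - t0
        for kind, path in inputs_cfg.items():
            if Path(path).exists():
                rec.input_digests[kind] = _digest(path)
        report.stages.append(rec)

    report.to_json(run_dir / "run_report.json")
    return report


def _run_stage(stage: str, cfg: dict, config: dict, data: dict,
               run_dir: Path, seed: int, rec: StageRecord) -> list[Path]:
    outs: list[Path] = []

    def out(name: str) -> Path:
        p = run_dir / name
        outs.append(p)
        return p

    if stage == "simulate":
        _stage_simulate(cfg, data, out, seed)
    elif stage == "kmer":
        genome = data.get("genome") or _load_or_fail("genome", config, data)
        mods = data.get("mods") or _load_or_fail("mods", config, data)
        mod_class = cfg.get("mod_class", "6mA")
        k = int(cfg.get("k", 3))
        offset = int(cfg.get("offset", 1))
        base = io_core.MOD_CLASS_BASE[mod_class]
        bg = kmer_context.background_kmer_counts(genome, k, base, offset)
        obs = kmer_context.modified_kmer_counts(mods, genome, k, offset,
                                                mod_class)
        rec.warnings["dropped_contexts"] = obs.dropped
        res = kmer_context.standardized_residuals(obs, bg)
        res.to_frame().to_csv(out("kmer_enrichment.tsv"), sep="\t",
                              index=False)
        # 7-mer PWM with the modified base at offset 2 (position 3)
        top_n = int(cfg.get("top_n", 500))
        bg7 = kmer_context.background_kmer_counts(genome, 7, base, 2)
        obs7 = kmer_context.modified_kmer_counts(mods, genome, 7, 2,
                                                 mod_class)
        res7 = kmer_context.standardized_residuals(obs7, bg7)
        top = kmer_context.select_enriched_kmers(res7, "top_n", top_n)
        if top:
            pwm = kmer_context.build_pwm(
                top, weights=[res7.obs[w] for w in top])
            pwm.to_frame().to_csv(out("pwm_7mer.tsv"), sep="\t")
    elif stage == "spacing":
        genome = data.get("genome") or _load_or_fail("genome", config, data)
        mods = data.get("mods") or _load_or_fail("mods", config, data)
        mod_class = cfg.get("mod_class", "6mA")
        strand_mode = cfg.get("strand_mode", "same_strand")
        max_d = int(cfg.get("max_d", 200))
        n_controls = int(cfg.get("controls", 100))
        dists = spacing_periodicity.adjacent_distances(mods, mod_class,
                                                       strand_mode)
        hist = spacing_periodicity.histogram(dists, max_d, strand_mode)
        ctrl = spacing_periodicity.control_distances(
            genome, mods, mod_class, n_controls, seed, strand_mode)
        ctrl_hists = [spacing_periodicity.histogram(d, max_d, strand_mode)
                      for d in ctrl]
        pg = spacing_periodicity.periodogram(hist)
        peak = spacing_periodicity.nucleosome_peak(hist, ctrl_hists)
        np.savetxt(out("distance_histogram.tsv"),
                   np.column_stack([np.arange(1, max_d + 1), hist.counts]),
                   fmt="%d", delimiter="\t", header="distance\tcount")
        np.savetxt(out("periodogram.tsv"),
                   np.column_stack([pg.periods, pg.power]),
                   delimiter="\t", header="period_bp\tpower")
        with open(out("spacing_summary.json"), "w") as fh:
            json.dump({"dominant_period_bp": pg.dominant_period,
                       "nucleosome_peak_bp": peak.peak_distance,
                       "nucleosome_enrichment": peak.enrichment,
                       "n_pairs": hist.n_pairs}, fh, indent=1)
    elif stage == "features":
        genome = data.get("genome") or _load_or_fail("genome", config, data)
        mods = data.get("mods") or _load_or_fail("mods", config, data)
        features = data.get("features") or _load_or_fail("features", config,
                                                         data)
        mod_class = cfg.get("mod_class", "6mA")
        table = feature_enrichment.feature_class_table(mods, genome,
                                                       features, mod_class)
        table.to_csv(out("feature_enrichment.tsv"), sep="\t", index=False)
        repeats = features.of_type("repeat")
        if len(repeats):
            fam, excluded = feature_enrichment.per_family_fold(
                mods, genome, repeats, mod_class,
                min_eligible=int(cfg.get("min_eligible", 100)))
            fam.to_csv(out("repeat_family_fold.tsv"), sep="\t", index=False)
            rec.warnings["families_below_min_eligible"] = len(excluded)
    elif stage == "linkage":
        genome = data.get("genome") or _load_or_fail("genome", config, data)
        coverage = data.get("coverage") or _load_or_fail("coverage", config,
                                                         data)
        window = int(cfg.get("window", 10_000))
        profiles = linkage_dosage.coverage_profile(coverage, genome, window)
        peak = linkage_dosage.estimate_diploid_peak(profiles)
        call = linkage_dosage.classify_contigs(
            profiles, peak, threshold=float(cfg.get("threshold", 0.8)))
        data["linkage"] = call
        with open(out("linkage.tsv"), "w") as fh:
            fh.write("contig\tclass\tfraction_in_haploid_band\n")
            for contig, cls in call.calls.items():
                fh.write(f"{contig}\t{cls}\t{call.fractions[contig]:.4f}\n")
        with open(out("linkage_summary.json"), "w") as fh:
            json.dump({"diploid_peak": call.diploid_peak,
                       "haploid_band": list(call.haploid_band),
                       "threshold": call.threshold}, fh, indent=1)
    elif stage == "dosage":
        expression = data.get("expression") or _load_or_fail("expression",
                                                             config, data)
        if "linkage" in data:
            gene_link = linkage_dosage.gene_linkage_from_contigs(
                expression, data["linkage"].calls)
        elif "gene_linkage" in data:
            gene_link = data["gene_linkage"]
        else:
            raise ConfigError("stage 'dosage': missing key 'linkage' "
                              "(run the linkage stage or supply one)")
        res = linkage_dosage.dosage_ratios(
            expression, gene_link,
            pseudocount=float(cfg.get("pseudocount", 1.0)),
            min_abundance=float(cfg.get("min_abundance", 1.0)))
        with open(out("dosage_summary.json"), "w") as fh:
            json.dump({"median_log2_ratio": res.medians,
                       "rank_sum_p": res.p, "ks_p": res.ks_p,
                       "n_excluded": res.n_excluded,
                       "skipped": res.skipped}, fh, indent=1)
    elif stage == "signal":
        model = data.get("model") or _load_or_fail("model", config, data)
        events = data.get("events") or _load_or_fail("events", config, data)
        results = signal_shift.kmer_shift_stats(
            events, model, min_events=int(cfg.get("min_events", 50)))
        shifted = signal_shift.shifted_kmer_set(
            results, alpha=float(cfg.get("alpha", 0.01)),
            min_abs_shift=float(cfg.get("min_shift", 1.0)))
        with open(out("kmer_shift.tsv"), "w") as fh:
            fh.write("kmer\tn_events\tdelta_mean\tz\tks_stat\tp\tq\tflagged\n")
            for r in results:
                fh.write(f"{r.kmer}\t{r.n_events}\t{r.delta_mean:.4f}\t"
                         f"{r.z:.4f}\t{r.ks_stat:.4f}\t{r.p:.4g}\t"
                         f"{r.q if r.q is not None else ''}\t"
                         f"{int(r.flagged)}\n")
        sub = signal_shift.submotif_enrichment(shifted, sorted(model.table),
                                               m=int(cfg.get("m", 3)))
        if sub is not None:
            sub.to_frame().to_csv(out("submotif_enrichment.tsv"), sep="\t",
                                  index=False)
    else:
        raise ConfigError(f"unknown stage {stage!r}")
    return outs


def _load_or_fail(kind: str, config: dict, data: dict):
    inputs_cfg = config.get("inputs", {})
    if kind not in inputs_cfg:
        raise ConfigError(f"missing input {kind!r}: provide inputs.{kind} "
                          "or run the simulate stage")
    if kind == "genome":
        data[kind] = io_core.read_genome(inputs_cfg[kind])
    elif kind == "mods":
        data[kind] = io_core.read_modcalls(inputs_cfg[kind],
                                           genome=data.get("genome"))
    elif kind == "features":
        data[kind] = io_core.read_intervals(inputs_cfg[kind])
    elif kind == "coverage":
        data[kind] = io_core.read_coverage(inputs_cfg[kind])
    elif kind == "expression":
        data[kind] = io_core.read_expression(inputs_cfg[kind])
    elif kind == "model":
        data[kind] = io_core.read_kmer_model(inputs_cfg[kind])
    elif kind == "events":
        data[kind] = io_core.read_events(inputs_cfg[kind])
    else:
        raise ConfigError(f"unknown input kind {kind!r}")
    return data[kind]


def _stage_simulate(cfg: dict, data: dict, out, seed: int) -> None:
    """Generate the full synthetic study and write every artifact."""
    genome = synthetic_data.gen_genome(
        int(cfg.get("genome_length", 500_000)),
        gc=float(cfg.get("gc", 0.38)),
        n_contigs=int(cfg.get("n_contigs", 4)), seed=seed)
    truth = synthetic_data.SimTruth()

    periodic_cfg = cfg.get("periodic")
    if periodic_cfg:
        pspec = synthetic_data.PeriodicSpec(
            helical_period=int(periodic_cfg.get("helical_period", 10)),
            nucleosome_repeat=int(periodic_cfg.get("nucleosome_repeat", 175)),
            jitter_sd=float(periodic_cfg.get("jitter_sd", 1.0)))
        per_mods, per_truth = synthetic_data.plant_periodic_mods(
            genome, pspec, int(cfg.get("n_arrays", 200)), seed=seed + 1)
        truth = truth.merge(per_truth)
    else:
        per_mods = ModTable([])

    motif_specs = [synthetic_data.MotifSpec(
        m["motif"], int(m.get("offset", 0)), m.get("mod_class", "6mA"),
        float(m.get("prob", 0.3))) for m in cfg.get("motifs", [])]
    motif_mods, motif_truth = synthetic_data.plant_motif_mods(
        genome, motif_specs, float(cfg.get("background_rate", 0.0)),
        seed=seed + 2)
    truth = truth.merge(motif_truth)

    merged: dict[tuple, io_core.ModCall] = {}
    for c in list(per_mods) + list(motif_mods):
        merged.setdefault((c.contig, c.pos, c.strand, c.mod_class), c)
    mods = ModTable(merged.values())

    features = synthetic_data.gen_features(genome, seed=seed + 3)

    ploidy_cfg = cfg.get("ploidy", {})
    n_contigs = len(genome)
    n_hap = int(ploidy_cfg.get("n_haploid", max(1, n_contigs // 5)))
    pspec2 = synthetic_data.PloidySpec(
        haploid_depth=float(ploidy_cfg.get("haploid_depth", 20.0)),
        n_haploid_contigs=n_hap, n_diploid_contigs=n_contigs - n_hap,
        dispersion=float(ploidy_cfg.get("dispersion", np.inf)))
    contigs = [(n, length) for n, length in genome.lengths.items()]
    coverage, cov_truth = synthetic_data.gen_coverage(
        contigs, pspec2, window=int(ploidy_cfg.get("window", 1000)),
        seed=seed + 4)
    truth = truth.merge(cov_truth)

    expr_cfg = cfg.get("expression", {})
    espec = synthetic_data.ExpressionSpec(
        n_genes=int(expr_cfg.get("n_genes", 1000)),
        x_fraction=float(expr_cfg.get("x_fraction", 0.2)),
        compensated=bool(expr_cfg.get("compensated", True)),
        biological_cv=float(expr_cfg.get("cv", 0.2)))
    hap = [c for c, p in cov_truth.contig_ploidy.items() if p == "haploid"]
    dip = [c for c, p in cov_truth.contig_ploidy.items() if p == "diploid"]
    expression, expr_truth = synthetic_data.gen_expression(
        espec, seed=seed + 5, x_contig=hap[0], autosome_contig=dip[0])
    truth = truth.merge(expr_truth)

    model = synthetic_data.gen_pore_model(seed=seed + 6)
    sig_cfg = cfg.get("signal", {})
    shifted = synthetic_data.kmers_containing(sig_cfg.get("submotif", "GAG"))
    sspec = synthetic_data.SignalSpec(
        shift=float(sig_cfg.get("shift", 2.0)), shifted_kmers=shifted,
        events_per_kmer=int(sig_cfg.get("events_per_kmer", 100)))
    events, sig_truth = synthetic_data.gen_events(model, sspec, seed=seed + 7)
    truth = truth.merge(sig_truth)

    io_core.write_genome(genome, out("genome.fasta"))
    io_core.write_modcalls(mods, out("mods.gff3"))
    io_core.write_intervals(features, out("features.bed"))
    io_core.write_coverage(coverage, out("coverage.bedgraph"))
    io_core.write_expression(expression, out("expression.tsv"))
    io_core.write_kmer_model(model, out("model.tsv"))
    io_core.write_events(events, out("events.tsv"))
    truth.to_json(out("truth.json"))

    data.update({"genome": genome, "mods": mods, "features": features,
                 "coverage": coverage, "expression": expression,
                 "model": model, "events": events, "truth": truth})
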
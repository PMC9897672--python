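"""End-to-end synthetic scenario: configuration, stages, and the report.

A scenario is one fully specified synthetic experiment — chromosome layout,
decay model, boundary strengths and weakenings, peak class plan, expression
plan, FISH conditions, spike-in design, and every analysis threshold — run
deterministically from a single seed.  Each stage writes plain-text tables or
tracks plus a JSON summary; the final report aggregates planted-truth recovery
metrics across stages.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_boundary, expression, fish, insulation, occupancy, spikein
from . import formats, synthetic

SCHEMA_VERSION = 1

STAGE_ORDER = ("simulate", "insulation", "boundaries", "diff", "occupancy",
               "expression", "fish", "spikein", "report")


@dataclass
class ScenarioConfig:
    """Versioned scenario configuration; defaults are the package's reference
    study conditions (20-Mb chromosome at 10-kb bins, boundaries of strength
    0.7, ten weakened to 0.7 * 0.2 in the depletion)."""

    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    chromosome: dict = field(default_factory=lambda: {
        "chrom": "chrS", "bin_size": 10_000, "n_bins": 2_000})
    decay: dict = field(default_factory=lambda: {
        "amplitude": 2000.0, "alpha": 0.75, "diagonal_level": 2.0})
    boundaries: dict = field(default_factory=lambda: {
        "n": 99, "strength": 0.7,
        "weakened": {str(i): 0.8 for i in range(4, 99, 10)}})
    peaks: dict = field(default_factory=lambda: {
        "jitter_sd": 1000.0, "n_background": 50,
        "classes": [["BEAF-32", "CP190"],
                    ["BEAF-32", "Su(Hw)", "CP190"],
                    ["BEAF-32", "CTCF", "Su(Hw)", "CP190"],
                    ["CP190"],
                    ["CTCF", "CP190"],
                    ["Su(Hw)"],
                    ["BEAF-32"]]})
    expression: dict = field(default_factory=lambda: {
        "genes_per_tad": 3, "noise_sd": 0.1, "maternal_fraction": 0.3,
        "hijack_log2fc": 1.5})
    fish: dict = field(default_factory=lambda: {
        "n_alleles": 400,
        "conditions": {
            "wt": {"contact_prob": 0.12, "mu_contact": 120.0,
                   "sigma_contact": 90.0, "mu_open": 650.0, "sigma_open": 280.0},
            "depleted": {"contact_prob": 0.31, "mu_contact": 120.0,
                         "sigma_contact": 90.0, "mu_open": 650.0,
                         "sigma_open": 280.0}}})
    spikein: dict = field(default_factory=lambda: {
        "bin_size": 100, "background": 2.0, "peak_amplitude": 100.0,
        "depletion": 1.0, "depth_wt": 1.0, "depth_dep": 0.6,
        "n_peaks": 60})
    thresholds: dict = field(default_factory=lambda: {
        "windows": [50_000, 100_000], "delta_min": 0.05, "q": 0.1,
        "cutoff_lenient": -0.1, "cutoff_stringent": -0.2, "snr_min": 5.0,
        "top_k": 10, "n_stable": 40, "lfc_min": 0.7, "q_max": 0.05,
        "promoter_flank": 500, "near_nm": 250.0, "far_nm": 600.0,
        "kernel_radius": 8, "kernel_s_ref": 0.5,
        "coloc_radius": 200, "boundary_window": 10_000})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        if cfg.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported scenario schema version "
                             f"{cfg.schema_version} (expected {SCHEMA_VERSION})")
        return cfg

    # -- derived objects ----------------------------------------------------

    def layout(self) -> synthetic.TadLayout:
        b = self.boundaries
        weakened = {int(k): float(v) for k, v in b.get("weakened", {}).items()}
        return synthetic.evenly_spaced_layout(
            n_boundaries=b["n"], strength=b["strength"], weakened=weakened,
            n_bins=self.chromosome["n_bins"],
            bin_size=self.chromosome["bin_size"],
            chrom=self.chromosome["chrom"])

    def decay_model(self) -> synthetic.DecayModel:
        return synthetic.DecayModel(**self.decay)

    def class_assignment(self, layout: synthetic.TadLayout) -> dict:
        classes = self.peaks["classes"]
        return {int(b): frozenset(classes[i % len(classes)])
                for i, b in enumerate(layout.boundary_bins)}


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing artifact '{name}' in {outdir}; "
                f"run the producing stage first")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: ScenarioConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    layout = cfg.layout()
    decay = cfg.decay_model()
    wt, dep = synthetic.gen_depletion_pair(layout, decay, seed=cfg.seed)
    formats.write_matrix(wt, outdir / "matrix_wt.txt", dialect="triplet")
    formats.write_matrix(dep, outdir / "matrix_dep.txt", dialect="triplet")

    assignment = cfg.class_assignment(layout)
    peaksets = synthetic.gen_peaks(layout, assignment,
                                   jitter_sd=cfg.peaks["jitter_sd"],
                                   n_background=cfg.peaks["n_background"],
                                   seed=cfg.seed + 1)
    for factor, ps in peaksets.items():
        safe = factor.replace("(", "").replace(")", "")
        formats.write_peaks(ps, outdir / f"peaks_{safe}.narrowPeak")

    weakened_idx = sorted(int(k) for k in cfg.boundaries.get("weakened", {}))
    bbins = layout.boundary_bins
    hijack_plan = [(synthetic.gene_id(i + 1, 0), int(bbins[i]),
                    cfg.expression["hijack_log2fc"])
                   for i in weakened_idx]
    genes = synthetic.gen_expression(
        layout, genes_per_tad=cfg.expression["genes_per_tad"],
        hijack_plan=hijack_plan, noise_sd=cfg.expression["noise_sd"],
        maternal_fraction=cfg.expression["maternal_fraction"],
        seed=cfg.seed + 2)
    formats.write_genes(genes, outdir / "genes.tsv")

    fish_rows = []
    for ci, (name, params) in enumerate(sorted(cfg.fish["conditions"].items())):
        cond = synthetic.FishCondition(label=name, **params)
        sample = synthetic.gen_fish_sample(cond, cfg.fish["n_alleles"],
                                           seed=cfg.seed + 10 + ci)
        for k, d in enumerate(sample.distances):
            fish_rows.append({"condition": name, "embryo": k % sample.n_embryos,
                              "allele": k, "distance_nm": round(float(d), 3)})
    pd.DataFrame(fish_rows).to_csv(outdir / "fish_distances.tsv", sep="\t",
                                   index=False)

    depleted_factor = "CP190"
    ref_peaks = peaksets[depleted_factor]
    sub = formats.PeakSet(factor=depleted_factor,
                          peaks=list(ref_peaks)[: cfg.spikein["n_peaks"]])
    tracks = synthetic.gen_spikein_pair(
        sub, chrom=layout.chrom, chrom_length=layout.chrom_length,
        bin_size=cfg.spikein["bin_size"], background=cfg.spikein["background"],
        peak_amplitude=cfg.spikein["peak_amplitude"],
        depletion=cfg.spikein["depletion"],
        depth_wt=cfg.spikein["depth_wt"], depth_dep=cfg.spikein["depth_dep"],
        seed=cfg.seed + 20)
    formats.write_bedgraph(tracks["wt"], outdir / "cnt_wt.bedgraph")
    formats.write_bedgraph(tracks["dep"], outdir / "cnt_dep.bedgraph")
    formats.write_peaks(sub, outdir / "cnt_reference_peaks.narrowPeak")

    truth = {
        "boundary_bins": [int(b) for b in bbins],
        "boundary_positions": [int(p) for p in layout.boundary_positions],
        "weakened_bins": [int(bbins[i]) for i in weakened_idx],
        "classes": {str(b): sorted(assignment[int(b)]) for b in bbins},
        "hijack_genes": sorted(g for g, _, _ in hijack_plan),
        "fish_conditions": cfg.fish["conditions"],
        "spike_reads": {"wt": tracks["spike_wt"], "dep": tracks["spike_dep"]},
        "tads_bp": [[int(a), int(b)] for a, b in layout.tads],
    }
    _dump_json(truth, outdir / "truth.json")


def stage_insulation(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "insulation", "matrix_wt.txt", "matrix_dep.txt")
    windows = cfg.thresholds["windows"]
    for label in ("wt", "dep"):
        m = formats.read_matrix(outdir / f"matrix_{label}.txt")
        track = insulation.separation_score(m, windows)
        formats.write_bedgraph(track.as_binned_track(),
                               outdir / f"insulation_{label}.bedgraph",
                               valid=track.valid)


def stage_boundaries(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "boundaries", "matrix_wt.txt")
    m = formats.read_matrix(outdir / "matrix_wt.txt")
    calls = insulation.call_boundaries(m, windows=cfg.thresholds["windows"],
                                       delta_min=cfg.thresholds["delta_min"],
                                       q_threshold=cfg.thresholds["q"])
    with open(outdir / "boundaries_wt.bed", "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.window[0]}\t{c.window[1]}\t"
                     f"boundary_{c.bin}\t{c.sep_score:.6g}\t.\t{c.qvalue:.6g}\n")
    _dump_json({"n_boundaries": len(calls),
                "bins": [c.bin for c in calls]},
               outdir / "boundaries_summary.json")


def _read_calls(outdir: Path, bin_size: int) -> list[insulation.BoundaryCall]:
    calls = []
    with open(outdir / "boundaries_wt.bed") as fh:
        for ln in fh:
            chrom, start, end, name, score, _, q = ln.split("\t")
            b = int(name.split("_")[1])
            calls.append(insulation.BoundaryCall(
                chrom=chrom, bin=b, position=b * bin_size,
                sep_score=float(score), prominence=float("nan"),
                pvalue=float("nan"), qvalue=float(q)))
    return calls


def stage_diff(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "diff", "matrix_wt.txt", "matrix_dep.txt", "boundaries_wt.bed")
    wt = formats.read_matrix(outdir / "matrix_wt.txt")
    dep = formats.read_matrix(outdir / "matrix_dep.txt")
    calls = _read_calls(outdir, wt.bin_size)
    kernel = diff_boundary.make_border_kernel(
        cfg.decay_model(), s_ref=cfg.thresholds["kernel_s_ref"],
        r=cfg.thresholds["kernel_radius"])
    results = diff_boundary.differential_scores(
        wt, dep, calls, kernel, snr_min=cfg.thresholds["snr_min"],
        seed=cfg.seed + 30)
    rows = [{"chrom": r.boundary.chrom, "position": r.boundary.position,
             "bin": r.boundary.bin,
             "score_wt": round(r.score_wt, 6), "score_dep": round(r.score_dep, 6),
             "diff_score": round(r.diff_score, 6), "snr": round(r.snr, 6),
             "affected_0.1": r.diff_score < cfg.thresholds["cutoff_lenient"],
             "affected_0.2": r.diff_score < cfg.thresholds["cutoff_stringent"]}
            for r in results]
    pd.DataFrame(rows).to_csv(outdir / "diff_boundaries.tsv", sep="\t", index=False)
    top, stable = diff_boundary.stratify(results,
                                         top_k=cfg.thresholds["top_k"],
                                         n_stable=cfg.thresholds["n_stable"])
    _dump_json({"top_bins": [r.boundary.bin for r in top],
                "stable_bins": sorted(r.boundary.bin for r in stable),
                "n_affected_lenient": sum(
                    r.diff_score < cfg.thresholds["cutoff_lenient"] for r in results),
                "n_affected_stringent": sum(
                    r.diff_score < cfg.thresholds["cutoff_stringent"] for r in results)},
               outdir / "diff_summary.json")


def _load_peaksets(cfg: ScenarioConfig, outdir: Path) -> dict[str, formats.PeakSet]:
    out = {}
    for factor in synthetic.INSULATOR_FACTORS:
        safe = factor.replace("(", "").replace(")", "")
        path = outdir / f"peaks_{safe}.narrowPeak"
        if path.exists():
            out[factor] = formats.read_peaks(path, factor=factor)
    if not out:
        raise FileNotFoundError("stage 'occupancy' needs missing artifact "
                                "'peaks_*.narrowPeak'; run simulate first")
    return out


def stage_occupancy(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "occupancy", "boundaries_wt.bed", "matrix_wt.txt")
    peaksets = _load_peaksets(cfg, outdir)
    bin_size = cfg.chromosome["bin_size"]
    calls = _read_calls(outdir, bin_size)
    groups = occupancy.colocalize_summits(peaksets,
                                          radius=cfg.thresholds["coloc_radius"])
    occupancy.upset_counts(groups).to_csv(outdir / "upset_genomewide.tsv",
                                          sep="\t", index=False)
    occ = occupancy.boundary_occupancy(calls, peaksets,
                                       window=cfg.thresholds["boundary_window"])
    occ.to_csv(outdir / "boundary_occupancy.tsv", sep="\t", index=False)


def stage_expression(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "expression", "genes.tsv", "diff_summary.json", "truth.json")
    genes = formats.read_genes(outdir / "genes.tsv")
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    zygotic = expression.filter_zygotic(genes)
    degs = expression.call_degs(zygotic, lfc_min=cfg.thresholds["lfc_min"],
                                q_max=cfg.thresholds["q_max"],
                                contrast="depletion_vs_wt")
    degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
    with open(outdir / "diff_summary.json") as fh:
        diff_summary = json.load(fh)
    bin_size = cfg.chromosome["bin_size"]
    truth_positions = set(truth["boundary_positions"])
    disrupted = sorted(b * bin_size for b in diff_summary["top_bins"]
                       if b * bin_size in truth_positions)
    candidates = expression.hijack_candidates(degs, disrupted, truth["tads_bp"])
    pd.DataFrame([{"gene_id": c.gene_id, "boundary": c.boundary_position,
                   "side": c.side, "log2fc": round(c.log2fc, 6)}
                  for c in candidates]
                 ).to_csv(outdir / "hijack_candidates.tsv", sep="\t", index=False)


def stage_fish(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "fish", "fish_distances.tsv")
    table = pd.read_csv(outdir / "fish_distances.tsv", sep="\t")
    samples = {}
    for name, grp in table.groupby("condition"):
        samples[name] = synthetic.DistanceSample(
            distances=grp["distance_nm"].to_numpy(), condition=str(name))
    summary = {}
    for name, sample in sorted(samples.items()):
        fr = fish.threshold_fractions(sample, near=cfg.thresholds["near_nm"],
                                      far=cfg.thresholds["far_nm"])
        summary[name] = {"pct_near": round(fr.pct_near, 3),
                         "pct_far": round(fr.pct_far, 3),
                         "n_alleles": fr.n_alleles}
    names = sorted(samples)
    if len(names) == 2:
        ks = fish.compare_conditions(samples[names[0]], samples[names[1]])
        summary["ks"] = {"statistic": round(ks.statistic, 6),
                         "pvalue": float(f"{ks.pvalue:.6g}")}
    _dump_json(summary, outdir / "fish_summary.json")


def stage_spikein(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "spikein", "cnt_wt.bedgraph", "cnt_dep.bedgraph",
             "cnt_reference_peaks.narrowPeak", "truth.json")
    bin_size = cfg.spikein["bin_size"]
    n_bins = cfg.chromosome["n_bins"] * cfg.chromosome["bin_size"] // bin_size
    wt = formats.read_bedgraph(outdir / "cnt_wt.bedgraph", bin_size, n_bins, fill=0.0)
    dep = formats.read_bedgraph(outdir / "cnt_dep.bedgraph", bin_size, n_bins, fill=0.0)
    peaks = formats.read_peaks(outdir / "cnt_reference_peaks.narrowPeak",
                               factor="CP190")
    with open(outdir / "truth.json") as fh:
        spike = json.load(fh)["spike_reads"]
    ratios = spikein.peak_signal_loss(wt, dep, peaks,
                                      spike_wt=spike["wt"], spike_dep=spike["dep"])
    ratios.round(6).to_csv(outdir / "spikein_ratios.tsv", sep="\t", index=False)


def stage_report(cfg: ScenarioConfig, outdir: Path) -> None:
    _require(outdir, "report", "truth.json", "boundaries_summary.json",
             "diff_boundaries.tsv", "boundary_occupancy.tsv", "degs.tsv",
             "hijack_candidates.tsv", "fish_summary.json", "spikein_ratios.tsv",
             "insulation_wt.bedgraph", "insulation_dep.bedgraph")
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    with open(outdir / "boundaries_summary.json") as fh:
        bsum = json.load(fh)
    planted = np.array(truth["boundary_bins"])
    called = np.array(bsum["bins"], dtype=int)
    recovered = [int(np.min(np.abs(called - b))) <= 1 if called.size else False
                 for b in planted]
    false_calls = [int(c) for c in called
                   if planted.size == 0 or np.min(np.abs(planted - c)) > 1]

    diff_table = pd.read_csv(outdir / "diff_boundaries.tsv", sep="\t")
    weakened = set(truth["weakened_bins"])
    diff_table["is_weakened"] = diff_table["bin"].map(
        lambda b: int(np.min(np.abs(np.array(sorted(weakened)) - b))) <= 1
        if weakened else False)
    k = len(weakened)
    topk = set(diff_table.nsmallest(k, "diff_score")["bin"]) if k else set()
    diff_detection = (sum(diff_table.loc[diff_table["bin"].isin(topk),
                                         "is_weakened"]) / k if k else float("nan"))

    occ = pd.read_csv(outdir / "boundary_occupancy.tsv", sep="\t",
                      keep_default_na=False)
    class_truth = {int(b): "+".join(sorted(v)) for b, v in truth["classes"].items()}
    matches, total = 0, 0
    for _, row in occ.iterrows():
        b = int(row["bin"])
        near = [cb for cb in class_truth if abs(cb - b) <= 1]
        if near:
            total += 1
            matches += int(row["label"] == class_truth[near[0]])
    occ_recovery = matches / total if total else float("nan")

    degs = pd.read_csv(outdir / "degs.tsv", sep="\t")
    hijack = pd.read_csv(outdir / "hijack_candidates.tsv", sep="\t")
    found = set(hijack["gene_id"]) if len(hijack) else set()
    planted_h = set(truth["hijack_genes"])
    precision = len(found & planted_h) / len(found) if found else float("nan")
    recall = len(found & planted_h) / len(planted_h) if planted_h else float("nan")

    with open(outdir / "fish_summary.json") as fh:
        fish_summary = json.load(fh)
    ratios = pd.read_csv(outdir / "spikein_ratios.tsv", sep="\t")

    bin_size = cfg.chromosome["bin_size"]
    n_bins = cfg.chromosome["n_bins"]
    ins_wt = formats.read_bedgraph(outdir / "insulation_wt.bedgraph",
                                   bin_size, n_bins)
    ins_dep = formats.read_bedgraph(outdir / "insulation_dep.bedgraph",
                                    bin_size, n_bins)
    loss = ins_dep.values - ins_wt.values
    weak_bins = np.array(sorted(weakened), dtype=int)
    stable_bins = np.array([b for b in truth["boundary_bins"]
                            if b not in weakened], dtype=int)
    mean_loss_weak = float(np.nanmean(loss[weak_bins])) if weak_bins.size else float("nan")
    mean_loss_stable = float(np.nanmean(loss[stable_bins])) if stable_bins.size else float("nan")

    report = {
        "stages": list(STAGE_ORDER),
        "seed": cfg.seed,
        "thresholds": cfg.thresholds,
        "boundaries": {
            "n_planted": int(planted.size), "n_called": int(called.size),
            "recovery_rate": round(float(np.mean(recovered)), 4),
            "n_false_calls": len(false_calls)},
        "diff": {
            "n_weakened_planted": k,
            "topk_weakened_fraction": round(float(diff_detection), 4),
            "n_affected_lenient": int((diff_table["diff_score"]
                                       < cfg.thresholds["cutoff_lenient"]).sum()),
            "n_affected_stringent": int((diff_table["diff_score"]
                                         < cfg.thresholds["cutoff_stringent"]).sum())},
        "insulation": {
            "mean_loss_weakened": round(mean_loss_weak, 4),
            "mean_loss_stable": round(mean_loss_stable, 4)},
        "occupancy": {"class_recovery_rate": round(float(occ_recovery), 4)},
        "expression": {"n_degs": int(len(degs)),
                       "hijack_precision": round(float(precision), 4),
                       "hijack_recall": round(float(recall), 4)},
        "fish": fish_summary,
        "spikein": {"median_peak_ratio": round(float(ratios["ratio"].median()), 4)},
    }
    _dump_json(report, outdir / "report.json")


STAGES = {
    "simulate": stage_simulate,
    "insulation": stage_insulation,
    "boundaries": stage_boundaries,
    "diff": stage_diff,
    "occupancy": stage_occupancy,
    "expression": stage_expression,
    "fish": stage_fish,
    "spikein": stage_spikein,
    "report": stage_report,
}


def run_scenario(cfg: ScenarioConfig, outdir, stages=STAGE_ORDER) -> Path:
    """Run the requested stages in pipeline order; returns the report directory."""
    outdir = Path(outdir)
    for name in STAGE_ORDER:
        if name in stages:
            STAGES[name](cfg, outdir)
    return outdir
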
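"""End-to-end orchestration: simulate -> deplete -> merge -> consensus ->
reproducibility -> compare -> quant, with a reproducible run manifest.

A single root seed drives per-stage substreams, so identical configs give
byte-identical artifacts (verified through the manifest's file hashes).
Stage logging records counts in and out of every filtering step.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .assays import ddct_fold_change, delta_psi, psi, SpliceEvent
from .compare import footprint_delta, kmer_enrichment, venn_partition
from .idr import pairwise_group_reproducibility
from .intervals import (
    consensus_footprints, merge, subtract, write_bed, IntervalSet,
)
from .simulate import (
    SyntheticScenario, make_toy_annotation, simulate_background,
    simulate_replicate_peaks, simulate_sequences, simulate_true_sites,
    write_fasta,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("clipfoot")

ALL_STAGES = ("simulate", "footprints", "consensus", "repro", "compare",
              "quant")


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic-data pipeline run."""

    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    n_reps_by_condition: dict[str, int] = field(default_factory=lambda: {
        "naive": 3, "mild": 3, "severe": 4})
    stages: tuple[str, ...] = ALL_STAGES
    min_support: int = 2
    consensus_min_overlap: int = 2
    match_min_overlap: int = 1
    idr_threshold: float = 0.05
    acceptability_bound: float = 2.0
    outdir: str = "clipfoot_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.idr_threshold <= 1.0:
            raise ValueError("idr_threshold must be in (0, 1]")
        if self.min_support < 1 or self.consensus_min_overlap < 1:
            raise ValueError("min_support and consensus_min_overlap must be >= 1")
        if self.acceptability_bound <= 1.0:
            raise ValueError("acceptability_bound must exceed 1")
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("scenario"), dict):
            d["scenario"] = SyntheticScenario.from_dict(d["scenario"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=True)
                if path.suffix in (".yml", ".yaml")
                else json.dumps(self.to_dict(), indent=2, sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = (yaml.safe_load(text) if path.suffix in (".yml", ".yaml")
             else json.loads(text))
        return cls.from_dict(d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order and return the run manifest.

    The manifest records the package version, seed, per-stage counts
    (before/after each filter) and a sha256 hash of every emitted file;
    identical config + seed reproduce identical hashes.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = SyntheticScenario.from_dict(
        {**config.scenario.to_dict(), "seed": config.seed})
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["files"][name] = _sha256(path)

    conditions = sorted(config.n_reps_by_condition)
    raw_peaks: dict[str, list[IntervalSet]] = {}
    footprints: dict[str, list[IntervalSet]] = {}
    consensus: dict[str, list] = {}

    # --- simulate ----------------------------------------------------------
    annotation = make_toy_annotation(scenario)
    true_sites = simulate_true_sites(annotation, scenario)
    background = simulate_background(annotation, scenario)
    for cond in conditions:
        raw_peaks[cond] = simulate_replicate_peaks(
            true_sites, scenario, config.n_reps_by_condition[cond], cond)
    if "simulate" in config.stages:
        emit("scenario.yaml", scenario.save)
        emit("annotation.tsv", annotation.to_tsv)
        emit("true_sites.bed", lambda p: write_bed(true_sites, p))
        emit("background.bed", lambda p: write_bed(background, p))
        for cond in conditions:
            for rep in raw_peaks[cond]:
                emit(f"peaks_{rep.sample_id}.bed",
                     lambda p, rep=rep: write_bed(rep, p))
        manifest["stages"]["simulate"] = {
            "n_true_sites": len(true_sites),
            "n_background": len(background),
            "n_peaks": {cond: [len(r) for r in raw_peaks[cond]]
                        for cond in conditions},
        }
        logger.info("simulate: %d true sites, %d background peaks",
                    len(true_sites), len(background))

    # --- footprints: background depletion + merge --------------------------
    if "footprints" in config.stages:
        stage: dict = {}
        for cond in conditions:
            footprints[cond] = []
            for rep in raw_peaks[cond]:
                depleted = subtract(rep, background)
                merged = merge(depleted)
                merged.sample_id = rep.sample_id
                merged.condition = cond
                footprints[cond].append(merged)
                stage[rep.sample_id] = {
                    "peaks_in": len(rep), "after_depletion": len(depleted),
                    "after_merge": len(merged)}
                emit(f"footprints_{rep.sample_id}.bed",
                     lambda p, m=merged: write_bed(m, p))
                logger.info("footprints %s: %d -> %d -> %d",
                            rep.sample_id, len(rep), len(depleted), len(merged))
        manifest["stages"]["footprints"] = stage

    # --- consensus ---------------------------------------------------------
    if "consensus" in config.stages:
        stage = {}
        for cond in conditions:
            reps = footprints.get(cond) or [
                merge(subtract(r, background)) for r in raw_peaks[cond]]
            fps = consensus_footprints(
                reps, min_support=config.min_support,
                min_overlap=config.consensus_min_overlap,
                annotation=annotation)
            consensus[cond] = fps
            emit(f"consensus_{cond}.bed", lambda p, fps=fps: write_bed(
                IntervalSet([fp.region for fp in fps]), p))
            emit(f"consensus_{cond}.tsv", lambda p, fps=fps: _write_consensus_tsv(
                fps, p))
            stage[cond] = {
                "candidates_retained": len(fps),
                "bound_genes": len({g for fp in fps for g in fp.genes}),
            }
            logger.info("consensus %s: %d footprints, %d bound genes",
                        cond, len(fps), stage[cond]["bound_genes"])
        manifest["stages"]["consensus"] = stage

    # --- reproducibility ---------------------------------------------------
    if "repro" in config.stages:
        stage = {}
        for cond in conditions:
            if config.n_reps_by_condition[cond] < 2:
                continue
            summary = pairwise_group_reproducibility(
                raw_peaks[cond], seed=config.seed,
                threshold=config.idr_threshold,
                min_overlap=config.match_min_overlap)
            rows = []
            for (a, b), rep in summary.reports.items():
                rows.append({
                    "pair": rep.pair_id, "n_t": rep.n_t, "n_p": rep.n_p,
                    "n_1": rep.n_1, "n_2": rep.n_2,
                    "rescue_ratio": rep.rescue_ratio,
                    "self_consistency_ratio": rep.self_consistency_ratio,
                    "acceptable": rep.acceptable})
            emit(f"repro_{cond}.tsv", lambda p, rows=rows: _write_tsv_rows(
                rows, p))
            stage[cond] = {
                "n_pairs": len(summary.reports),
                "n_acceptable": sum(r.acceptable
                                    for r in summary.reports.values()),
                "flagged": summary.flagged}
        manifest["stages"]["repro"] = stage

    # --- compare -----------------------------------------------------------
    if "compare" in config.stages and consensus:
        gene_sets = {cond: {g for fp in consensus[cond] for g in fp.genes}
                     for cond in conditions}
        part = venn_partition(gene_sets)
        compare_out: dict = {
            "venn_counts": {"+".join(k): v for k, v in part.counts.items()},
            "venn_percentages": {"+".join(k): v
                                 for k, v in part.percentages.items()},
            "union_size": part.union_size,
            "unique_gene_counts": {cond: len(gene_sets[cond])
                                   for cond in conditions},
        }
        if len(conditions) >= 2:
            a, b = conditions[0], conditions[-1]
            delta = footprint_delta(consensus[a], consensus[b])
            compare_out["footprint_delta"] = {
                "from": a, "to": b,
                "lost_bp": delta.lost_bases(),
                "gained_bp": delta.gained_bases(),
            }
        seqs = simulate_sequences(
            IntervalSet([fp.region for fp in consensus[conditions[0]]]),
            scenario)
        emit(f"sequences_{conditions[0]}.fasta",
             lambda p: write_fasta(seqs, p))
        enr = kmer_enrichment(seqs, scenario.motif, seed=config.seed)
        compare_out["motif_enrichment"] = {
            "motif": enr.motif, "observed": enr.observed, "z": enr.z,
            "p_empirical": enr.p_empirical}
        emit("compare.json", lambda p: Path(p).write_text(
            json.dumps(compare_out, indent=2, sort_keys=True)))
        manifest["stages"]["compare"] = compare_out

    # --- quant -------------------------------------------------------------
    if "quant" in config.stages:
        from .simulate import simulate_assay_tables
        junctions, ct, bands = simulate_assay_tables(scenario)
        emit("junction_counts.tsv",
             lambda p: junctions.to_csv(p, sep="\t", index=False))
        emit("ct_table.tsv", lambda p: ct.to_csv(p, sep="\t", index=False))
        emit("band_intensities.tsv",
             lambda p: bands.to_csv(p, sep="\t", index=False))
        groups = sorted(scenario.psi_by_group)
        events = {
            g: [SpliceEvent(r.event, r.inclusion, r.skipping,
                            r.inclusion_len, r.skipping_len, g)
                for r in junctions[junctions.group == g].itertuples()]
            for g in groups}
        psi_means = {g: float(sum(psi(e) for e in events[g]) / len(events[g]))
                     for g in groups}
        quant_out: dict = {"psi_by_group": psi_means}
        if len(groups) == 2:
            # control listed first by convention: positive dPSI = higher
            # inclusion in control
            ctrl, case = ("control", "case") if "control" in groups else groups
            quant_out["delta_psi"] = delta_psi(events[ctrl], events[case])
        folds = ddct_fold_change(ct, calibrator_group=groups[0]
                                 if "control" not in groups else "control")
        quant_out["fold_change_by_group"] = {
            g: float(folds[folds.group == g].fold_change.mean())
            for g in groups}
        emit("quant.json", lambda p: Path(p).write_text(
            json.dumps(quant_out, indent=2, sort_keys=True)))
        manifest["stages"]["quant"] = quant_out

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_consensus_tsv(fps, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsupport\tn_replicates\tgenes\tdistance\n")
        for fp in fps:
            fh.write(f"{fp.region.chrom}\t{fp.region.start}\t{fp.region.end}\t"
                     f"{fp.support}\t{fp.n_replicates}\t"
                     f"{','.join(fp.genes) or '.'}\t"
                     f"{fp.distance if fp.distance is not None else '.'}\n")


def _write_tsv_rows(rows: list[dict], path: Path) -> None:
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
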
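"""End-to-end orchestration: simulate -> count hits -> normalize ->
concordance -> composition -> enrichment, as one seeded, logged run
producing a machine-readable report.

A single global seed is fanned out to every stochastic stage through
named sub-streams, so adding a stage never perturbs earlier draws and
identical configurations give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import arraynorm, concord, goenrich, hitcount, seqcomp, synthio
from .exceptions import CnvConcordError
from .io import write_bed, write_fasta, write_json, write_tsv, write_yaml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: synthio.SimConfig = field(default_factory=synthio.SimConfig)
    max_mismatches: int = 0
    call_threshold: float = 0.8
    norm_method: str = "median"
    gc_span: float = 0.3
    apply_gc_normalization: bool = False
    n_permutations: int = 199
    fdr_cutoff: float = 0.05
    go_enrichment_factor: float = 1.0
    outdir: str | None = None

    @property
    def seed(self) -> int:
        return self.sim.seed

    def replace_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(self, sim=dataclasses.replace(self.sim, seed=seed))


def _corr_dict(results: dict) -> dict:
    return {f"{p1}_vs_{p2}": r.as_dict() for (p1, p2), r in results.items()}


def run_full(config: RunConfig) -> dict:
    """Execute every stage on a fresh synthetic dataset; return the report.

    If ``config.outdir`` is set, stage outputs (FASTA/BED/TSV) and the
    JSON report are also written there.
    """
    cfg = config
    report: dict = {"config": {**dataclasses.asdict(cfg)}}
    stage = "simulate"
    try:
        genome_a, genome_b, annotation, truth = synthio.generate_genomes(cfg.sim)
        a_long, a_short = synthio.derive_assemblies(genome_a, truth, cfg.sim)
        b_long, b_short = synthio.derive_assemblies(genome_b, truth, cfg.sim)
        probeset = synthio.design_probes(genome_a, annotation, cfg.sim)
        signals = synthio.simulate_hybridization(probeset, truth, cfg.sim)
        go_annotation, enriched_terms = synthio.generate_go_annotation(
            annotation, truth, cfg.sim, enrichment_factor=cfg.go_enrichment_factor
        )

        stage = "count-hits"
        assemblies = {"a_long": a_long, "a_short": a_short, "b_long": b_long, "b_short": b_short}
        params = hitcount.MatchParams(cfg.max_mismatches)
        hit_table = hitcount.build_hit_table(probeset, assemblies, params)
        universal = hitcount.filter_universal(hit_table)
        single_ids, multi_ids = hitcount.classify_multicopy(universal)
        report["counts"] = {
            "n_probes": int(len(probeset)),
            "per_assembly_total_hits": {a: int(hit_table[a].sum()) for a in hitcount.ASSEMBLY_IDS},
            "n_universal": int(len(universal)),
            "n_singlecopy": int(len(single_ids)),
            "n_multicopy": int(len(multi_ids)),
        }

        stage = "normalize"
        gc = probeset.set_index("probe_id")["gc"]
        per_array, acgh = arraynorm.process_signals(
            signals,
            gc=gc,
            method=cfg.norm_method,
            gc_span=cfg.gc_span,
            apply_gc=cfg.apply_gc_normalization,
        )
        calls = arraynorm.call_acgh(acgh, cfg.call_threshold)

        stage = "concordance"
        ratio_table = concord.build_ratio_table(universal, acgh)
        multic = ratio_table.loc[ratio_table.index.intersection(multi_ids)]
        report["correlations"] = {}
        for mode in ("all_multicopy", "nonneutral_pair"):
            try:
                report["correlations"][mode] = _corr_dict(
                    concord.concordance_matrix(multic, mode=mode, threshold=cfg.call_threshold)
                )
            except CnvConcordError as exc:
                report["correlations"][mode] = {"error": str(exc)}
        call_sets = concord.build_call_sets(multic, cfg.call_threshold)
        genic_ids = set(probeset.loc[probeset["klass"] == "genic", "probe_id"])
        probe_to_gene = dict(zip(probeset["probe_id"], probeset["gene_id"]))
        report["euler"] = concord.intersect_sets(
            call_sets, genic_ids=genic_ids, probe_to_gene=probe_to_gene
        )
        multi_hits = universal.loc[universal.index.intersection(multi_ids)]
        groups = (
            [multi_hits[a].to_numpy() for a in hitcount.ASSEMBLY_IDS] if len(multi_hits) else []
        )
        if groups and all(len(g) for g in groups):
            h, df_kw, p_kw = concord.kruskal_wallis(groups)
            report["kruskal_wallis_hits"] = {"H": h, "df": df_kw, "p": p_kw}
        report["platform_bias_anova"] = _fig2_anovas(multic)

        stage = "composition"
        report["composition"] = _composition_stage(
            probeset, call_sets, cfg.n_permutations, cfg.seed
        )

        stage = "enrich"
        gene_sets = concord.gene_calls(call_sets, probe_to_gene)
        by_species = {
            direction: {p: gene_sets[p][direction] for p in concord.PLATFORMS}
            for direction in ("a", "b")
        }
        contrasts = goenrich.build_contrasts(by_species, annotation["gene_id"])
        enrichment = goenrich.run_contrasts(contrasts, go_annotation, fdr_cutoff=cfg.fdr_cutoff)
        report["enrichment"] = {
            name: {
                "n_terms_tested": int(len(tab)),
                "n_significant": int(tab["significant"].sum()) if len(tab) else 0,
                "top_terms": tab.head(3)[["term_id", "fdr"]].to_dict("records") if len(tab) else [],
            }
            for name, tab in enrichment.items()
        }

        stage = "truth-recovery"
        report["truth_recovery"] = _truth_recovery(
            probeset, truth, acgh, ratio_table, cfg.call_threshold
        )
    except CnvConcordError as exc:
        raise CnvConcordError(f"stage {stage!r} failed: {exc}") from exc

    if cfg.outdir:
        _write_outputs(
            Path(cfg.outdir), cfg, genome_a, genome_b, assemblies, annotation, truth,
            probeset, signals, go_annotation, hit_table, per_array, acgh, calls,
            ratio_table, report,
        )
    return report


def _fig2_anovas(ratio_table: pd.DataFrame) -> dict:
    """aCGH ratio distributions of platform-biased probe subsets vs all probes.

    The "all" group enters as its own group alongside the long-read- and
    short-read-biased subsets (overlap accepted by design).
    """
    out = {}
    for species in ("a", "b"):
        ip = ratio_table[f"interplatform_{species}"]
        groups = {
            "all": ratio_table["acgh"].to_numpy(),
            "longread_biased": ratio_table.loc[ip > 0, "acgh"].to_numpy(),
            "shortread_biased": ratio_table.loc[ip < 0, "acgh"].to_numpy(),
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            out[species] = {"error": "insufficient biased probes"}
            continue
        res = concord.anova_tukey(groups)
        out[species] = {
            "F": res["F"],
            "p": res["p"],
            "group_means": {k: float(np.mean(v)) for k, v in groups.items()},
            "tukey": res["tukey"].to_dict("records"),
        }
    return out


def _composition_stage(
    probeset: pd.DataFrame, call_sets: dict, n_permutations: int, seed: int
) -> dict:
    """PERMANOVA + PCA over platform-exclusive probe sets (both directions pooled)."""
    seq_by_probe = dict(zip(probeset["probe_id"], probeset["seq"]))
    exclusive: dict[str, set] = {p: set() for p in concord.PLATFORMS}
    for direction in ("a", "b"):
        regions = concord.venn_sets(call_sets, direction)
        exclusive["acgh"] |= regions["acgh_only"]
        exclusive["longread"] |= regions["longread_only"]
        exclusive["shortread"] |= regions["shortread_only"]
    labels, seqs = [], []
    for platform, probes in exclusive.items():
        for p in sorted(probes):
            labels.append(platform)
            seqs.append(seq_by_probe[p])
    sizes = {p: labels.count(p) for p in concord.PLATFORMS}
    usable = [p for p, n in sizes.items() if n >= 2]
    out: dict = {"set_sizes": sizes}
    if len(usable) < 2:
        out["note"] = "fewer than two platform-exclusive sets with >= 2 probes"
        return out
    keep = [i for i, l in enumerate(labels) if l in usable]
    X = seqcomp.composition_matrix([seqs[i] for i in keep])
    lab = np.asarray([labels[i] for i in keep])
    pw = seqcomp.pairwise_permanova(X, lab, n_permutations=n_permutations, seed=seed)
    out["pairwise_permanova"] = pw.to_dict("records")
    res = seqcomp.pca(X)
    out["pca_variance_pct"] = [round(float(100 * v), 3) for v in res.explained_variance_ratio[:3]]
    return out


def _truth_recovery(
    probeset: pd.DataFrame,
    truth: pd.DataFrame,
    acgh: pd.Series,
    ratio_table: pd.DataFrame,
    threshold: float,
) -> dict:
    """Score calls against the planted truth.

    Truth calls are the planted log2 copy ratios thresholded at the same
    magnitude used for the aCGH calls. Collapse detection compares
    long-read-biased probes (inter-platform ratio > 0) with the probes
    of families flagged as collapsed in the short-read assembly.
    """
    pt = synthio.probe_truth(probeset, truth)
    common = acgh.index.intersection(pt.index)
    true_ratio = pt.loc[common, "true_log2_ratio"]
    truth_call = np.where(
        true_ratio > threshold, "gain", np.where(true_ratio < -threshold, "loss", "neutral")
    )
    obs_call = arraynorm.call_acgh(acgh.loc[common], threshold).to_numpy()
    pos = truth_call != "neutral"
    out: dict = {}
    out["call_sensitivity"] = float((obs_call[pos] == truth_call[pos]).mean()) if pos.any() else 1.0
    out["call_specificity"] = (
        float((obs_call[~pos] == "neutral").mean()) if (~pos).any() else 1.0
    )
    by_gene = truth.set_index("gene_id")
    for species, col, flag in (("a", "interplatform_a", "collapsed_a"), ("b", "interplatform_b", "collapsed_b")):
        in_table = ratio_table.index
        collapsed_genes = set(by_gene.index[by_gene[flag]])
        truth_set = {
            p for p, g in zip(probeset["probe_id"], probeset["gene_id"])
            if g in collapsed_genes and p in in_table
        }
        pred_set = set(ratio_table.index[ratio_table[col] > 0])
        tp = len(truth_set & pred_set)
        out[f"collapse_precision_{species}"] = tp / len(pred_set) if pred_set else 1.0
        out[f"collapse_recall_{species}"] = tp / len(truth_set) if truth_set else 1.0
    return out


def _write_outputs(
    outdir, cfg, genome_a, genome_b, assemblies, annotation, truth, probeset,
    signals, go_annotation, hit_table, per_array, acgh, calls, ratio_table, report
):
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome_a.records(), outdir / "speciesA.genome.fa")
    write_fasta(genome_b.records(), outdir / "speciesB.genome.fa")
    for name, asm in assemblies.items():
        write_fasta(asm.records(), outdir / f"{name}.fa")
    write_bed(annotation[["gene_id", "start", "end"]], outdir / "genes.bed")
    write_bed(probeset[["probe_id", "start", "end"]], outdir / "probes.bed")
    write_tsv(probeset[["probe_id", "gene_id", "klass", "gc", "seq"]], outdir / "probes.tsv")
    write_tsv(truth, outdir / "truth.tsv")
    write_tsv(signals, outdir / "signals.tsv")
    write_tsv(go_annotation, outdir / "go_annotation.tsv")
    write_tsv(hit_table.reset_index(), outdir / "hit_table.tsv")
    write_tsv(per_array.reset_index(), outdir / "ratios_per_array.tsv")
    agg = acgh.reset_index()
    agg.columns = ["probe_id", "acgh_ratio"]
    agg["call"] = calls.to_numpy()
    write_tsv(agg, outdir / "acgh_calls.tsv")
    write_tsv(ratio_table.reset_index(), outdir / "ratio_table.tsv")
    write_yaml(dataclasses.asdict(cfg), outdir / "config.yaml")
    report["outputs"] = str(outdir)
    write_json(report, outdir / "report.json")


def validate_inputs(
    probeset: pd.DataFrame | None = None,
    signals: pd.DataFrame | None = None,
    assemblies: dict | None = None,
) -> list[dict]:
    """Structural consistency diagnostics; returns [{level, message}, ...]
    without raising."""
    diags: list[dict] = []
    if probeset is not None:
        dup = probeset["probe_id"][probeset["probe_id"].duplicated()]
        if len(dup):
            diags.append({"level": "error", "message": f"duplicate probe id {dup.iloc[0]!r}"})
        bad = probeset[~probeset["seq"].str.fullmatch("[ACGTN]+")]
        if len(bad):
            diags.append(
                {"level": "error", "message": f"non-DNA probe sequence for {bad['probe_id'].iloc[0]!r}"}
            )
    if signals is not None and probeset is not None:
        probes = set(probeset["probe_id"])
        for array_id, sub in signals.groupby("array_id"):
            missing = probes - set(sub["probe_id"])
            if missing:
                diags.append(
                    {
                        "level": "error",
                        "message": f"array {array_id!r} missing probe(s) {sorted(missing)[:3]}",
                    }
                )
        if (signals[["test_intensity", "ref_intensity"]] <= 0).any().any():
            diags.append({"level": "error", "message": "non-positive intensities present"})
    if assemblies is not None:
        for a in hitcount.ASSEMBLY_IDS:
            if a not in assemblies:
                diags.append({"level": "error", "message": f"assembly {a!r} missing"})
    return diags
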
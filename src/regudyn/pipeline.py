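"""Pipeline orchestration: run every analysis stage over a dataset
directory with one validated configuration, producing TSV stage outputs and
a machine-readable JSON run report.

Stages run in dependency order: annotate -> cluster -> switch -> peaks ->
cis -> trans. With a fixed configuration (including the master seed) a
rerun is bit-identical. When the dataset carries planted truth labels
(synthetic data), the report additionally contains recovery metrics
against them.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bedio import read_bed, read_bedgraph
from .cislogic import (
    CisCall,
    align_stages,
    classify_sync_repression,
    early_opening_calls,
    enhancer_switch_pairs,
    gradual_increase_filter,
    half_max_stage,
    null_promoter_rhos,
)
from .elements import (
    Element,
    accessibility_variability,
    assign_nearest_gene,
    categorize_elements,
    conservation_overlap,
    elements_table,
    filter_and_merge_peaks,
    length_matched_null_test,
)
from .expression import (
    assign_memberships,
    expressed_filter,
    fuzzy_cmeans,
    order_clusters_by_peak_stage,
    zscore,
)
from .gff3 import read_gff3
from .models import StageMatrix, replicate_mean
from .pwm import read_pwm_file
from .switching import events_table, find_switching_genes
from .translogic import (
    call_pioneer_tfs,
    motif_deviation,
    opening_index,
    scan_motifs,
    track_background_density,
)

DEFAULT_THRESHOLDS: dict[str, float | int] = {
    # expression
    "min_tpm": 1.0,
    "n_clusters": 30,
    "fuzzifier": 1.25,
    "membership_cutoff": 0.3,
    "n_restarts": 20,
    # switching
    "switch_threshold": 0.6,
    "gene_floor": 1.0,
    # elements
    "min_neglog_q": 7.0,
    "promoter_upstream": -1000,
    "promoter_downstream": 500,
    "fold_pseudocount": 1.0,
    "fold_lo": 2.0,
    "fold_hi": 5.0,
    "null_repeats": 200,
    # cis logic
    "rho_hi": 0.8,
    "rho_lo": -0.8,
    "neg_corr_cutoff": 0.0,
    "f_test_cutoff": 0.1,
    "half_max_fraction": 0.5,
    "rho_min": 0.7,
    "p_max": 0.1,
    "n_null_pairs": 1000,
    "min_shared_stages": 5,
    # trans logic
    "score_fraction": 0.8,
    "pwm_tolerance": 1e-6,
    "pwm_pseudocount": 0.008,
    "opening_min": 2.5,
    "deviation_min": 10.0,
    "tpm_min": 5.0,
    "flank": 200,
    "n_background": 50,
    "min_hits": 10,
    # annotation
    "lncrna_min_length": 200,
    "junction_support_hi": 500,
}

CIS_PRECEDENCE = ("enh_switch", "early_open", "sync", "repression")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise PipelineConfigError(
                f"unknown threshold key(s): {sorted(unknown)}"
            )
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"input_dir", "output_dir", "seed", "thresholds"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input missing: {path}")
    return path


@dataclass
class PipelineState:
    """In-memory results handed between stages."""

    models: object = None
    gene_rep1: StageMatrix | None = None
    gene_rep2: StageMatrix | None = None
    clustering: object = None
    elements: list[Element] | None = None
    acc_mean: StageMatrix | None = None
    cis_calls: list[CisCall] | None = None
    element_primary: dict[str, str] | None = None


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.indir = Path(config.input_dir)
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.t = config.thresholds
        self.state = PipelineState()
        self.report: dict = {
            "version": __version__,
            "seed": config.seed,
            "thresholds": dict(sorted(self.t.items())),
            "stages": {},
        }
        manifest = self.indir / "manifest.json"
        self.manifest = json.loads(manifest.read_text()) if manifest.exists() else {}
        truth_path = self.indir / "truth.json"
        self.truth = None
        if truth_path.exists():
            from .synth import TruthLabels

            self.truth = TruthLabels.load(truth_path)

    # -- validation ---------------------------------------------------------
    REQUIRED = [
        "annotation.gff3",
        "genome.tsv",
        "expr_tx_rep1.tsv",
        "expr_tx_rep2.tsv",
        "expr_gene_rep1.tsv",
        "expr_gene_rep2.tsv",
        "acc_rep1.tsv",
        "acc_rep2.tsv",
        "conserved.bed",
    ]

    def validate_inputs(self) -> None:
        """Fail fast before any stage runs."""
        for name in self.REQUIRED:
            _require(self.indir / name)
        self.report["input_hashes"] = {
            name: _hash_file(self.indir / name) for name in self.REQUIRED
        }

    # -- stages -------------------------------------------------------------
    def stage_annotate(self) -> None:
        models = read_gff3(self.indir / "annotation.gff3")
        self.state.models = models
        genes = models.genes()
        n_junctions = sum(max(0, len(t.exons) - 1) for t in models)
        self.report["stages"]["annotate"] = {
            "n_genes": len(genes),
            "n_transcripts": len(models),
            "n_junctions": n_junctions,
            "n_multi_isoform_genes": sum(1 for ts in genes.values() if len(ts) > 1),
        }

    def stage_cluster(self) -> None:
        rep1 = StageMatrix.read_tsv(self.indir / "expr_gene_rep1.tsv")
        rep2 = StageMatrix.read_tsv(self.indir / "expr_gene_rep2.tsv")
        self.state.gene_rep1, self.state.gene_rep2 = rep1, rep2
        expressed = expressed_filter(rep1, rep2, min_tpm=self.t["min_tpm"])
        mean = replicate_mean(rep1.subset(expressed), rep2.subset(expressed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z = zscore(mean)
        clustering = fuzzy_cmeans(
            z,
            k=int(self.t["n_clusters"]),
            m=float(self.t["fuzzifier"]),
            seed=self.config.seed,
            n_restarts=int(self.t["n_restarts"]),
        )
        self.state.clustering = clustering
        assignment = assign_memberships(clustering, cutoff=self.t["membership_cutoff"])
        order = order_clusters_by_peak_stage(clustering)
        clustering.memberships.round(6).to_csv(
            self.outdir / "memberships.tsv", sep="\t"
        )
        pd.DataFrame(
            {
                "gene": list(assignment.clusters),
                "clusters": [
                    ",".join(map(str, v)) for v in assignment.clusters.values()
                ],
            }
        ).to_csv(self.outdir / "cluster_assignments.tsv", sep="\t", index=False)
        frac0, frac1, frac2 = assignment.fractions
        self.report["stages"]["cluster"] = {
            "n_expressed": len(expressed),
            "n_clusters": clustering.k,
            "converged": bool(clustering.converged),
            "fraction_unassigned": round(frac0, 4),
            "fraction_single": round(frac1, 4),
            "fraction_multi": round(frac2, 4),
            "cluster_order": order,
        }
        if self.truth is not None:
            from sklearn.metrics import adjusted_rand_score

            labels = self.state.clustering.hard_labels()
            truth_labels = {
                g: c for g, c in self.truth.gene_cluster.items() if c >= 0
            }
            shared = [g for g in labels.index if g in truth_labels]
            if shared:
                ari = adjusted_rand_score(
                    [truth_labels[g] for g in shared], labels.loc[shared]
                )
                self.report["stages"]["cluster"]["truth_ari"] = round(float(ari), 4)

    def stage_switch(self) -> None:
        rep1 = StageMatrix.read_tsv(self.indir / "expr_tx_rep1.tsv")
        rep2 = StageMatrix.read_tsv(self.indir / "expr_tx_rep2.tsv")
        mean = replicate_mean(rep1, rep2)
        gene_map = self.state.models.transcript_to_gene()
        events, switching, considered = find_switching_genes(
            mean,
            gene_map,
            min_tpm=self.t["min_tpm"],
            threshold=self.t["switch_threshold"],
            gene_floor=self.t["gene_floor"],
        )
        events_table(events).to_csv(
            self.outdir / "switch_events.tsv", sep="\t", index=False
        )
        entry = {
            "n_multi_isoform_expressed": len(considered),
            "n_switching_genes": len(switching),
            "n_events": len(events),
        }
        if self.truth is not None:
            true_set = {g for g, f in self.truth.gene_switch.items() if f}
            called = set(switching)
            tp = len(called & true_set)
            entry["switch_precision"] = round(tp / len(called), 4) if called else 1.0
            entry["switch_recall"] = round(tp / len(true_set), 4) if true_set else 1.0
        self.report["stages"]["switch"] = entry

    def stage_peaks(self) -> None:
        stage_peaks = {}
        atac_stages = self.manifest.get("atac_stages")
        if atac_stages is None:
            atac_stages = sorted(
                p.stem.split("peaks_")[1] for p in self.indir.glob("peaks_*.bed")
            )
        for st in atac_stages:
            stage_peaks[st] = read_bed(_require(self.indir / f"peaks_{st}.bed"))
        elements = filter_and_merge_peaks(
            stage_peaks, min_neglog_q=self.t["min_neglog_q"]
        )
        elements = assign_nearest_gene(elements, self.state.models)
        elements = categorize_elements(
            elements,
            self.state.models,
            promoter_window=(
                int(self.t["promoter_upstream"]),
                int(self.t["promoter_downstream"]),
            ),
        )
        acc1 = StageMatrix.read_tsv(self.indir / "acc_rep1.tsv")
        acc2 = StageMatrix.read_tsv(self.indir / "acc_rep2.tsv")
        acc = replicate_mean(acc1, acc2)
        if len(elements) != len(acc.entities):
            raise ValueError(
                f"merged elements ({len(elements)}) disagree with accessibility "
                f"matrix rows ({len(acc.entities)})"
            )
        fold, flag2, flag5 = accessibility_variability(
            acc, pseudocount=self.t["fold_pseudocount"]
        )
        constrained = read_bed(self.indir / "conserved.bed")
        elements = conservation_overlap(elements, constrained)
        genome = pd.read_csv(self.indir / "genome.tsv", sep="\t")
        genome_lengths = dict(zip(genome["chrom"], genome["length"]))
        test = length_matched_null_test(
            elements,
            genome_lengths,
            constrained,
            n_repeats=int(self.t["null_repeats"]),
            seed=self.config.seed,
        )
        self.state.elements = elements
        self.state.acc_mean = acc
        table = elements_table(elements)
        table["fold_change"] = fold
        table.to_csv(self.outdir / "elements.tsv", sep="\t", index=False)
        cats = table["category"].value_counts().to_dict()
        self.report["stages"]["peaks"] = {
            "n_elements": len(elements),
            "category_counts": {k: int(v) for k, v in sorted(cats.items())},
            "fraction_over_2x": round(float(flag2.mean()), 4),
            "fraction_over_5x": round(float(flag5.mean()), 4),
            "conserved_fraction": round(test.observed_conserved_fraction, 4),
            "null_conserved_fraction": round(
                float(test.null_conserved_fraction.mean()), 4
            ),
            "ks_statistic": round(test.ks_statistic, 4),
            "ks_p_value": float(test.p_value),
        }

    def _paired_profiles(self):
        """Replicate-mean expression and accessibility over shared stages."""
        stage_map = self.manifest.get("stage_map")
        acc = self.state.acc_mean
        expr = replicate_mean(self.state.gene_rep1, self.state.gene_rep2)
        if stage_map is None:
            stage_map = {s: s for s in acc.stages if s in expr.stages}
        pairs = align_stages(expr.stages, acc.stages, stage_map,
                             min_shared=int(self.t["min_shared_stages"]))
        atac_sel = [a for a, _ in pairs]
        rna_sel = [r for _, r in pairs]
        return expr.data[rna_sel], acc.data[atac_sel], tuple(atac_sel)

    def stage_cis(self) -> None:
        expr_df, acc_df, stages = self._paired_profiles()
        elements = self.state.elements
        by_gene: dict[str, list[Element]] = {}
        for el in elements:
            if el.nearest_gene is not None and el.nearest_gene in expr_df.index:
                by_gene.setdefault(el.nearest_gene, []).append(el)

        calls: list[CisCall] = []
        primary: dict[str, str] = {el.element_id: "null" for el in elements}

        def promote(eid: str, label: str) -> None:
            cur = primary[eid]
            order = {t: i for i, t in enumerate(CIS_PRECEDENCE)}
            if cur == "null" or order.get(label, 99) < order.get(cur, 99):
                primary[eid] = label

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # correlation calls + enhancer switching per gene
            for gid, els in sorted(by_gene.items()):
                g_prof = expr_df.loc[gid].to_numpy()
                profiles = {
                    el.element_id: acc_df.loc[el.element_id].to_numpy() for el in els
                }
                for el in els:
                    call = classify_sync_repression(
                        profiles[el.element_id], g_prof, el.element_id, gid, stages,
                        hi=self.t["rho_hi"], lo=self.t["rho_lo"],
                    )
                    calls.append(call)
                    if call.call_type == "synchronization":
                        promote(el.element_id, "sync")
                    elif call.call_type == "repression":
                        promote(el.element_id, "repression")
                if len(els) >= 2:
                    pair_calls = enhancer_switch_pairs(
                        profiles, g_prof, gid, stages,
                        neg_corr_cutoff=self.t["neg_corr_cutoff"],
                        f_test_cutoff=self.t["f_test_cutoff"],
                    )
                    calls.extend(pair_calls)
                    for c in pair_calls:
                        for eid in c.element_ids:
                            promote(eid, "enh_switch")

            # gradual-increase filter on promoter elements, then early opening
            promoter_profiles, promoter_genes = [], []
            for gid, els in sorted(by_gene.items()):
                proms = [el for el in els if el.category == "promoter"]
                if proms:
                    promoter_profiles.append(
                        acc_df.loc[proms[0].element_id].to_numpy()
                    )
                    promoter_genes.append(gid)
            gene_profiles_list = [expr_df.loc[g].to_numpy() for g in sorted(by_gene)]
            null = null_promoter_rhos(
                promoter_profiles, gene_profiles_list,
                n_pairs=int(self.t["n_null_pairs"]), seed=self.config.seed,
            ) if promoter_profiles else np.array([])

            retained = []
            for prof, gid in zip(promoter_profiles, promoter_genes):
                ok, rho, p = gradual_increase_filter(
                    prof, expr_df.loc[gid].to_numpy(), null,
                    rho_min=self.t["rho_min"], p_max=self.t["p_max"],
                )
                if ok:
                    retained.append(gid)
            for gid in retained:
                els = by_gene[gid]
                profiles = {
                    el.element_id: acc_df.loc[el.element_id].to_numpy() for el in els
                }
                eo = early_opening_calls(
                    profiles, expr_df.loc[gid].to_numpy(), gid, stages
                )
                calls.extend(eo)
                for c in eo:
                    promote(c.element_ids[0], "early_open")

        self.state.cis_calls = calls
        self.state.element_primary = primary
        rows = [
            {
                "elements": ",".join(c.element_ids),
                "gene": c.gene_id,
                "type": c.call_type,
                "statistic": c.statistic,
            }
            for c in calls
        ]
        pd.DataFrame(rows, columns=["elements", "gene", "type", "statistic"]).to_csv(
            self.outdir / "cis_calls.tsv", sep="\t", index=False
        )
        counts = pd.Series(
            [c.call_type for c in calls if c.call_type != "unclassified"]
        ).value_counts().to_dict()
        entry = {
            "call_counts": {k: int(v) for k, v in sorted(counts.items())},
            "n_retained_gradual": len(retained),
        }
        if self.truth is not None:
            types = sorted(set(self.truth.element_type.values()) | {"null"})
            confusion = pd.DataFrame(0, index=types, columns=types)
            for eid, t_true in self.truth.element_type.items():
                if eid in primary:
                    confusion.loc[t_true, primary[eid]] += 1
            entry["confusion"] = {
                t: {u: int(confusion.loc[t, u]) for u in types} for t in types
            }
            off_diag = int(confusion.to_numpy().sum() - np.diag(confusion).sum())
            entry["confusion_off_diagonal"] = off_diag
        self.report["stages"]["cis"] = entry

    def stage_trans(self) -> None:
        from .translogic import footprint_profile  # noqa: F401 (re-export site)

        seq_path = self.indir / "elements.fa"
        motif_dir = self.indir / "motifs"
        if not seq_path.exists() or not motif_dir.exists():
            self.report["stages"]["trans"] = {"skipped": "no sequences or motifs"}
            return
        sequences = _read_fasta(seq_path)
        pwms = [
            read_pwm_file(p, tolerance=self.t["pwm_tolerance"],
                          pseudocount=self.t["pwm_pseudocount"])
            for p in sorted(motif_dir.glob("*.txt"))
        ]
        acc = self.state.acc_mean
        el_coords = {
            el.element_id: (el.chrom, el.start) for el in self.state.elements
        }
        hits_by_motif = {}
        indicator = pd.DataFrame(
            False, index=acc.entities, columns=[p.motif_id for p in pwms]
        )
        for pwm in pwms:
            hits = scan_motifs(sequences, pwm,
                               score_fraction=self.t["score_fraction"])
            hits_by_motif[pwm.motif_id] = hits
            for h in hits:
                if h.seq_id in indicator.index:
                    indicator.loc[h.seq_id, pwm.motif_id] = True

        deviation = motif_deviation(
            acc.data, indicator, n_background=int(self.t["n_background"]),
            seed=self.config.seed,
        )
        tf_map_path = self.indir / "tf_map.tsv"
        tf_map = {}
        if tf_map_path.exists():
            tf_df = pd.read_csv(tf_map_path, sep="\t")
            tf_map = dict(zip(tf_df["motif"], tf_df["tf_gene"]))
        expr = replicate_mean(self.state.gene_rep1, self.state.gene_rep2).data

        element_intervals = [
            (el.chrom, el.start, el.end) for el in self.state.elements
        ]
        rows = []
        for st in acc.stages:
            track = read_bedgraph(self.indir / f"cutsites_{st}.bedGraph")
            bg = track_background_density(track, element_intervals)
            for pwm in pwms:
                positions = [
                    (el_coords[h.seq_id][0], el_coords[h.seq_id][1] + h.start)
                    for h in hits_by_motif[pwm.motif_id]
                    if h.seq_id in el_coords
                ]
                oi = opening_index(
                    track, positions, len(pwm), bg,
                    flank=int(self.t["flank"]), min_hits=int(self.t["min_hits"]),
                )
                gene = tf_map.get(pwm.motif_id)
                tpm = (
                    float(expr.loc[gene, st])
                    if gene in expr.index and st in expr.columns
                    else np.nan
                )
                z = deviation.z.loc[pwm.motif_id, st]
                rows.append(
                    {
                        "tf": pwm.motif_id,
                        "tf_gene": gene,
                        "stage": st,
                        "opening": oi if oi is not None else np.nan,
                        "deviation_z": z,
                        "tpm": tpm,
                    }
                )
        scores = pd.DataFrame(rows)
        scored = call_pioneer_tfs(
            scores,
            opening_min=self.t["opening_min"],
            deviation_min=self.t["deviation_min"],
            tpm_min=self.t["tpm_min"],
        )
        scored.round(6).to_csv(self.outdir / "tf_scores.tsv", sep="\t", index=False)
        pioneers = scored[scored["pioneer"]]
        entry = {
            "n_motifs": len(pwms),
            "pioneer_calls": [
                {"tf": r["tf"], "stage": r["stage"]}
                for _, r in pioneers.iterrows()
            ],
        }
        if self.truth is not None:
            planted = {
                (m, st)
                for m, st in self.truth.pioneer_stage.items()
                if self.truth.motif_pioneer.get(m)
            }
            called = {(r["tf"], r["stage"]) for _, r in pioneers.iterrows()}
            entry["pioneer_truth_recovered"] = bool(planted <= called)
            entry["pioneer_false_calls"] = len(called - planted)
        self.report["stages"]["trans"] = entry

    # -- driver -------------------------------------------------------------
    def run(self) -> dict:
        self.validate_inputs()
        self.stage_annotate()
        self.stage_cluster()
        self.stage_switch()
        self.stage_peaks()
        self.stage_cis()
        self.stage_trans()
        report_path = self.outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(self.report, fh, indent=1, sort_keys=True)
        return self.report


def _read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    return Pipeline(config).run()
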
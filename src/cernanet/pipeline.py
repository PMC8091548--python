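"""End-to-end orchestration of the ceRNA inference stages.

The pipeline runs, in order: simulation (or loading of user inputs), small-RNA
preprocessing (filter, count, TPM), FPKM quantification, lncRNA
identification, target prediction, differential expression for the three RNA
classes, and shared-miRNA ceRNA pair calling; a machine-readable report
records per-stage record counts and the thresholds used.  Identical config
and seed give identical outputs.

The hexamer scorer used in lncRNA identification needs labelled training
sequences.  When none are supplied the pipeline bootstraps them from the
annotation itself: transcripts with a reading frame of at least 300 nt train
the coding class, transcripts with no frame over 100 nt train the noncoding
class.  This self-training shortcut works because frame length alone is a
high-precision (if incomplete) label.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
import pandas as pd

from . import cerna, diffexpr, lncrna, preprocess, qpcr, targets
from .io import (
    ExpressionMatrix,
    export_network,
    write_annotation,
    write_fasta,
)
from .simulate import SimulationConfig, generate_small_rna_reads, simulate_study

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Every stage threshold in one place; defaults are the study values."""

    output_dir: str = "cernanet_out"
    seed: int = 0
    simulate: bool = True
    groups: tuple[str, str] = ("TC", "CH")
    # read filtering
    min_read_len: int = 18
    max_read_len: int = 30
    max_n_fraction: float = 0.10
    # lncRNA identification
    lncrna_min_length: int = 200
    lncrna_min_exons: int = 2
    lncrna_min_fpkm: float = 0.1
    # target prediction
    min_site_type: str = "7mer-A1"
    cis_window: int = 100_000
    trans_alpha: float = 0.05
    # differential expression
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    # ceRNA calling
    cerna_p_threshold: float = 0.01
    cerna_fdr_threshold: float = 0.01
    cerna_min_shared: int = 1
    cerna_universe: str | int = "de"
    # optional qPCR stage
    ct_table: str | None = None
    control_group: str = "CH"
    simulation: SimulationConfig | None = None

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return self.simulation
        return SimulationConfig(seed=self.seed, groups=self.groups)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON).

    On a stage failure the partially written output directory receives a
    ``.partial`` marker file and the error is re-raised as
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("pipeline in progress\n")
    report: dict = {"stages": {}, "thresholds": _threshold_dict(config), "seed": config.seed}
    t_start = time.time()
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        if not config.simulate:
            raise NotImplementedError(
                "external-input mode expects pre-quantified matrices; use the "
                "library functions directly, or simulate=True"
            )
        sim_cfg = config.resolved_simulation()
        annotation, mats, truth = simulate_study(sim_cfg)
        write_annotation(annotation.transcripts, out / "annotation.gtf")
        write_fasta(annotation.transcript_sequences(), out / "transcripts.fa")
        write_fasta(annotation.mirna_sequences, out / "mirnas.fa")
        _write_truth(truth, out)
        report["stages"]["simulate"] = {
            "records": len(annotation.transcripts) + len(annotation.mirna_sequences),
            "transcripts": len(annotation.transcripts),
            "mirnas": len(annotation.mirna_sequences),
            "planted_triplets": len(truth.triplets),
            "seconds": round(time.time() - t0, 3),
        }

        # ------------------------------------------------------------------
        stage = "preprocess"
        t0 = time.time()
        samples = [f"{g}{i + 1}" for g in sim_cfg.groups for i in range(sim_cfg.replicates_per_group)]
        mirna_true = mats["mirna"].values
        reads_by_sample = {}
        n_input = 0
        filter_reports = {}
        for s in samples:
            reads, _read_truth = generate_small_rna_reads(
                sim_cfg, annotation.mirna_sequences, mirna_true[s].astype(int).to_dict(), sample=s
            )
            kept, rep = preprocess.filter_small_rna_reads(
                reads,
                adapter=sim_cfg.adapter,
                min_len=config.min_read_len,
                max_len=config.max_read_len,
                max_n_frac=config.max_n_fraction,
            )
            n_input += rep.input_reads
            filter_reports[s] = rep.__dict__
            reads_by_sample[s] = kept
        mirna_counts, _unmatched = preprocess.count_mirna_reads(
            reads_by_sample, annotation.mirna_sequences
        )
        mirna_tpm = preprocess.compute_tpm(mirna_counts)
        mirna_counts.to_tsv(out / "mirna_counts.tsv")
        mirna_tpm.to_tsv(out / "mirna_tpm.tsv")
        report["stages"]["preprocess"] = {
            "records": int(mirna_counts.values.to_numpy().sum()),
            "input_reads": n_input,
            "per_sample": filter_reports,
            "seconds": round(time.time() - t0, 3),
        }

        # ------------------------------------------------------------------
        stage = "quantify"
        t0 = time.time()
        lengths = {t.transcript_id: t.spliced_length for t in annotation.transcripts}
        fpkm_mrna = preprocess.compute_fpkm(mats["mrna"], lengths)
        fpkm_lnc = preprocess.compute_fpkm(mats["lncrna"], lengths)
        fpkm_mrna.to_tsv(out / "mrna_fpkm.tsv")
        fpkm_lnc.to_tsv(out / "lncrna_fpkm.tsv")
        mats["mrna"].to_tsv(out / "mrna_counts.tsv")
        mats["lncrna"].to_tsv(out / "lncrna_counts.tsv")
        report["stages"]["quantify"] = {
            "records": fpkm_mrna.shape[0] + fpkm_lnc.shape[0],
            "seconds": round(time.time() - t0, 3),
        }

        # ------------------------------------------------------------------
        stage = "lncrna_id"
        t0 = time.time()
        seqs = annotation.transcript_sequences()
        coding_train = [s for s in seqs.values() if lncrna.find_longest_orf(s).length >= 300]
        noncoding_train = [s for s in seqs.values() if lncrna.find_longest_orf(s).length <= 100]
        table = lncrna.train_hexamer_model(coding_train, noncoding_train)
        votes = {
            tid: lncrna.coding_potential_vote(tid, seq, table) for tid, seq in seqs.items()
        }
        candidates = lncrna.filter_lncrna_candidates(
            [t for t in annotation.transcripts if t.biotype != "mRNA"],
            fpkm_lnc,
            votes,
            min_length=config.lncrna_min_length,
            min_exons=config.lncrna_min_exons,
            min_fpkm=config.lncrna_min_fpkm,
        )
        coding_index = lncrna.index_by_contig(
            [t for t in annotation.transcripts if t.biotype == "mRNA"],
            contigs=annotation.contigs,
        )
        classes = {
            t.transcript_id: lncrna.classify_lncrna_position(t, coding_index)
            for t in candidates
        }
        pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in candidates],
                "class": [classes[t.transcript_id] for t in candidates],
                "votes_noncoding": [votes[t.transcript_id].votes_noncoding for t in candidates],
                "orf_length": [votes[t.transcript_id].orf_length for t in candidates],
                "hexamer_score": [votes[t.transcript_id].hexamer_score for t in candidates],
            }
        ).to_csv(out / "lncrna_candidates.tsv", sep="\t", index=False)
        report["stages"]["lncrna_id"] = {
            "records": len(candidates),
            "classes": {c: sum(1 for v in classes.values() if v == c) for c in lncrna.LNCRNA_CLASSES},
            "seconds": round(time.time() - t0, 3),
        }
        lnc_ids = [t.transcript_id for t in candidates]

        # ------------------------------------------------------------------
        stage = "targets"
        t0 = time.time()
        interactions = targets.predict_mirna_targets(
            annotation.mirna_sequences, seqs, min_site_type=config.min_site_type
        )
        cis = targets.lncrna_cis_targets(
            candidates,
            [t for t in annotation.transcripts if t.biotype == "mRNA"],
            window=config.cis_window,
        )
        trans = targets.lncrna_trans_targets(
            ExpressionMatrix(fpkm_lnc.values.loc[lnc_ids], layer="FPKM"),
            fpkm_mrna,
            alpha=config.trans_alpha,
        )
        _write_interactions(interactions + cis + trans, out / "interactions.tsv")
        report["stages"]["targets"] = {
            "records": len(interactions) + len(cis) + len(trans),
            "seed": len(interactions),
            "cis": len(cis),
            "trans": len(trans),
            "seconds": round(time.time() - t0, 3),
        }

        # ------------------------------------------------------------------
        stage = "diffexpr"
        t0 = time.time()
        design = pd.DataFrame(
            {"sample": samples, "group": [s.rstrip("0123456789") for s in samples]}
        )
        de_tables = {}
        for cls, mat in (("mrna", mats["mrna"]), ("lncrna", mats["lncrna"]), ("mirna", mirna_counts)):
            de_tables[cls] = diffexpr.de_test(
                mat,
                design,
                groups=config.groups,
                lfc_threshold=config.lfc_threshold,
                p_threshold=config.p_threshold,
            )
            de_tables[cls].to_csv(out / f"de_{cls}.tsv", sep="\t")
        de_sets = {cls: set(t.index[t["called"]]) for cls, t in de_tables.items()}
        report["stages"]["diffexpr"] = {
            "records": sum(len(t) for t in de_tables.values()),
            "called": {cls: len(s) for cls, s in de_sets.items()},
            "seconds": round(time.time() - t0, 3),
        }

        # ------------------------------------------------------------------
        stage = "cerna_network"
        t0 = time.time()
        universe = config.cerna_universe
        universe_n = None if universe == "de" else (
            len(annotation.mirna_sequences) if universe == "all" else int(universe)
        )
        directions = {}
        for t_ in de_tables.values():
            for fid, row in t_[t_["called"]].iterrows():
                directions[fid] = row["direction"]
        model = cerna.CeRNANetworkModel(
            interactions,
            de_sets["lncrna"],
            de_sets["mrna"],
            de_sets["mirna"],
            fpkm_lnc,
            fpkm_mrna,
        )
        results = model.fit(
            directions=directions,
            alpha_corr=config.trans_alpha,
            p_threshold=config.cerna_p_threshold,
            fdr_threshold=config.cerna_fdr_threshold,
            min_shared=config.cerna_min_shared,
            universe=universe_n,
        )
        results.table.to_csv(out / "cerna_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(results.triplets, columns=["lncrna_id", "mirna_id", "mrna_id"]).to_csv(
            out / "cerna_triplets.tsv", sep="\t", index=False
        )
        export_network(results.graph, out / "cerna_network.sif", fmt="sif")
        export_network(results.graph, out / "cerna_network.edges.tsv", fmt="edge-tsv")
        report["stages"]["cerna_network"] = {
            "records": len(results.pairs),
            "called_pairs": len(results.called),
            "triplets": len(results.triplets),
            "seconds": round(time.time() - t0, 3),
        }

        # ------------------------------------------------------------------
        if config.ct_table:
            stage = "qpcr"
            t0 = time.time()
            ct = pd.read_csv(config.ct_table, sep="\t")
            qres = qpcr.delta_delta_ct(ct, control_group=config.control_group)
            qpcr.results_to_frame(qres).to_csv(out / "qpcr_results.tsv", sep="\t", index=False)
            report["stages"]["qpcr"] = {
                "records": len(qres),
                "seconds": round(time.time() - t0, 3),
            }
    except Exception as exc:  # noqa: BLE001 - stage name is the added value
        raise PipelineError(stage, exc) from exc

    report["total_seconds"] = round(time.time() - t_start, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    marker.unlink(missing_ok=True)
    return report


def _threshold_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d.pop("simulation", None)
    return d


def _write_truth(truth, out: Path) -> None:
    rows = []
    for cls, feats in truth.de_features.items():
        rows.extend({"class": cls, "feature_id": f, "log2fc": l} for f, l in feats)
    pd.DataFrame(rows, columns=["class", "feature_id", "log2fc"]).to_csv(
        out / "truth_de.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth.triplets, columns=["lncrna_id", "mirna_id", "mrna_id"]).to_csv(
        out / "truth_triplets.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"mirna_id": s.mirna_id, "transcript_id": s.transcript_id, "start": s.start, "site_type": s.site_type}
            for s in truth.planted_sites
        ],
        columns=["mirna_id", "transcript_id", "start", "site_type"],
    ).to_csv(out / "truth_sites.tsv", sep="\t", index=False)


def _write_interactions(interactions, path: Path) -> None:
    pd.DataFrame(
        [
            {
                "source_id": it.source_id,
                "target_id": it.target_id,
                "mode": it.mode,
                "site_count": it.site_count if it.site_count is not None else "",
                "best_site_type": it.best_site_type or "",
                "distance": it.distance if it.distance is not None else "",
                "r": it.r if it.r is not None else "",
                "p_value": it.p_value if it.p_value is not None else "",
            }
            for it in interactions
        ],
        columns=["source_id", "target_id", "mode", "site_count", "best_site_type", "distance", "r", "p_value"],
    ).to_csv(path, sep="\t", index=False)
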
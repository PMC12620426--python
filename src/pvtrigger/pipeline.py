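"""End-to-end orchestration of the trigger-discovery framework.

:func:`run_all` executes the full chain on a synthetic study with planted
ground truth — report simulation, deduplication, descriptives, four-algorithm
signal detection with a co-medication sensitivity rerun, Weibull time-to-onset
fits for flagged drugs, molecular featurization, the three risk models with
consensus scoring, bulk ssGSEA and single-cell module-score enrichment, and a
drug-disease target overlap — writing every stage's output as TSV/JSON under
the output directory together with a manifest of seeds and parameters.

The demo study plants one fully-loaded drug (relative risk, learnable
structural motif, enriched expression signature); the pipeline's final hit
list should recover exactly that drug.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from . import pharmacovigilance as pv
from . import signature as sig
from . import synthetic, tto
from .mol_features import featurize_table
from .overlap import overlap_analysis
from .risk_models import (compute_auc, consensus, split_dataset, train_dmpnn,
                          train_gcn, train_svm)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "default_exclusion_list"]


def default_exclusion_list() -> list[str]:
    """The shipped co-medication exclusion list (NSAIDs, DMARDs,
    glucocorticoids, biologics, immunosuppressants)."""
    ref = (importlib.resources.files("pvtrigger.data")
           / "comedication_exclusions.txt")
    return [ln.strip() for ln in ref.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]


@dataclass
class PipelineConfig:
    """Single configuration for :func:`run_all` (YAML-loadable)."""

    out_dir: str = "pvtrigger_run"
    seed: int = 0
    target_event: str = "JUVENILE IDIOPATHIC ARTHRITIS"
    consensus_threshold: float = 0.60
    # report simulation
    n_reports: int = 30000
    n_decoy_drugs: int = 7
    background_rate: float = 0.01
    planted_rr: float = 10.0
    secondary_rr: float = 6.0
    tto_scale: float = 60.0
    tto_shape: float = 0.6
    dup_fraction: float = 0.05
    comed_fraction: float = 0.2
    # molecule training set
    n_pos: int = 60
    n_neg: int = 60
    model_epochs: int = 250
    search_budget: int = 3
    # expression simulation
    n_bulk_samples: int = 60
    n_cells: int = 800
    signature_size: int = 40
    bulk_effect: float = 1.0
    sc_effect: float = 1.0
    qc_fail_fraction: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class _Roster:
    """Candidate drugs of the demo study and their planted properties."""

    drugs: list[str]
    smiles: dict[str, str]
    planted: str = "DRUG01"     # RR + motif + signature
    motif_only: str = "DRUG02"  # motif, no reporting signal
    signal_only: str = "DRUG03"  # reporting signal, no motif


def _build_roster(cfg: PipelineConfig) -> _Roster:
    lib = synthetic.load_smiles_library()
    motif = lib[lib["has_motif"] == 1]["smiles"].tolist()
    plain = lib[lib["has_motif"] == 0]["smiles"].tolist()
    drugs = [f"DRUG{i + 1:02d}" for i in range(3 + cfg.n_decoy_drugs)]
    smiles = {"DRUG01": motif[0], "DRUG02": motif[1]}
    for i, d in enumerate(drugs[2:]):
        smiles[d] = plain[i]
    return _Roster(drugs=drugs, smiles=smiles)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    event = config.target_event
    roster = _build_roster(config)
    sig_genes = [f"SIG{i:03d}" for i in range(config.signature_size)]
    null_genes = [f"GENE{i:05d}" for i in range(config.signature_size)]
    manifest: dict = {"version": __version__, "seed": seed,
                      "config": asdict(config), "stages": {}}

    # ---- stage 1: synthetic study data -------------------------------------
    logger.info("stage 1: simulate study data")
    events = [event, "NAUSEA", "RASH", "HEADACHE", "PYREXIA"]
    sim = synthetic.SimConfig(
        n_reports=config.n_reports, drugs=roster.drugs, events=events,
        background_rate=config.background_rate,
        planted_signals={(roster.planted, event): config.planted_rr,
                         (roster.signal_only, event): config.secondary_rr},
        tto_params={roster.planted: (config.tto_scale, config.tto_shape)},
        dup_fraction=config.dup_fraction,
        comed_fraction=config.comed_fraction, seed=seed)
    reports = synthetic.generate_reports(sim)
    io.write_reports(reports, out / "reports.tsv")

    mols = synthetic.generate_molecule_set(config.n_pos, config.n_neg,
                                           seed=seed + 1)
    io.write_molecules(mols, out / "molecules_train.tsv")
    cand = pd.DataFrame({"cid": roster.drugs, "drugname": roster.drugs,
                         "smiles": [roster.smiles[d] for d in roster.drugs]})
    io.write_molecules(cand, out / "molecules_candidates.tsv")

    bulk = synthetic.generate_expression(
        "bulk", config.n_bulk_samples, ["sJIA", "nonsJIA", "control"],
        sig_genes, config.bulk_effect, seed=seed + 2, enriched_group="sJIA")
    cells = synthetic.generate_expression(
        "single_cell", config.n_cells, ["monocyte", "T", "B", "NK"],
        sig_genes, config.sc_effect, seed=seed + 3,
        enriched_group="monocyte", qc_fail_fraction=config.qc_fail_fraction)
    gene_sets = {f"signature_{roster.planted}": sig_genes,
                 f"signature_{roster.signal_only}": null_genes}
    io.write_gmt(gene_sets, out / "signatures.gmt")

    # ---- stage 2: dedup + descriptives -------------------------------------
    logger.info("stage 2: deduplicate and describe")
    dedup = pv.deduplicate(reports)
    io.write_reports(dedup, out / "reports_dedup.tsv")
    io.write_json(pv.descriptive_summary(dedup), out / "descriptive.json")
    manifest["stages"]["dedup"] = {"n_in": len(reports), "n_out": len(dedup)}

    # ---- stage 3: disproportionality + sensitivity -------------------------
    logger.info("stage 3: disproportionality signals")
    signals = pv.detect_signals(
        pv.disproportionality_table(dedup, event, seed=seed))
    signals.to_csv(out / "signals.tsv", sep="\t", index=False)
    filtered = pv.sensitivity_filter(dedup, default_exclusion_list())
    signals_sens = pv.detect_signals(
        pv.disproportionality_table(filtered, event, seed=seed))
    signals_sens.to_csv(out / "signals_sensitivity.tsv", sep="\t", index=False)
    signal_drugs = set(signals_sens.loc[signals_sens["consensus"], "drug"])
    manifest["stages"]["signals"] = {
        "consensus_drugs": sorted(signal_drugs),
        "n_reports_after_sensitivity": len(filtered)}

    # ---- stage 4: time-to-onset for flagged drugs --------------------------
    logger.info("stage 4: time-to-onset")
    tto_out = {}
    for drug in sorted(signal_drugs):
        sample = tto.compute_tto(dedup, drug=drug)
        if sample.values.size < 10:
            continue
        fit = tto.weibull_mle(sample)
        fit.ks_D, fit.ks_p = tto.ks_test(sample, fit, n_boot=200, seed=seed)
        med, iqr = tto.summarize_tto(sample)
        tto_out[drug] = {"n": fit.n, "median_days": med, "iqr_days": iqr,
                         "alpha": fit.alpha, "beta": fit.beta,
                         "beta_ci95": fit.beta_ci95,
                         "classification": fit.classification,
                         "ks_D": fit.ks_D, "ks_p": fit.ks_p,
                         "excluded": sample.n_excluded}
    io.write_json(tto_out, out / "tto.json")
    manifest["stages"]["tto"] = {d: v["classification"] for d, v in tto_out.items()}

    # ---- stage 5: featurize + train the three risk models ------------------
    logger.info("stage 5: risk models")
    des = featurize_table(mols, "descriptors")
    graphs, gidx = featurize_table(mols, "graph")
    y = (mols.assign(cid=mols["cid"].astype(str)).set_index("cid")
         .loc[des.index, "label"].to_numpy())
    sp = split_dataset(len(des), seed=seed)
    X = des.to_numpy()
    svm, svm_val = train_svm(X[sp.train], y[sp.train], X[sp.val], y[sp.val],
                             seed=seed)
    g_tr = [graphs[i] for i in sp.train]
    g_va = [graphs[i] for i in sp.val]
    g_te = [graphs[i] for i in sp.test]
    gcn, gcn_val = train_gcn(g_tr, y[sp.train], g_va, y[sp.val],
                             budget=config.search_budget,
                             epochs=config.model_epochs, seed=seed)
    dmp, dmp_val = train_dmpnn(g_tr, y[sp.train], g_va, y[sp.val],
                               extra_train=X[sp.train], extra_val=X[sp.val],
                               budget=config.search_budget,
                               epochs=config.model_epochs, seed=seed)
    aucs = {
        "svm_test_auc": compute_auc(svm.score_drugs(X[sp.test]), y[sp.test]),
        "gcn_test_auc": compute_auc(gcn.score_drugs(g_te), y[sp.test]),
        "dmpnn_test_auc": compute_auc(
            dmp.score_drugs(g_te, extra=X[sp.test]), y[sp.test]),
        "svm_val_auc": svm_val, "gcn_val_auc": gcn_val,
        "dmpnn_val_auc": dmp_val,
    }
    manifest["stages"]["models"] = aucs

    # ---- stage 6: score candidates + consensus -----------------------------
    logger.info("stage 6: candidate scoring")
    cand_des = featurize_table(cand, "descriptors")
    cand_graphs, cand_idx = featurize_table(cand, "graph")
    scores = pd.DataFrame({
        "score_svm": svm.score_drugs(cand_des.to_numpy()),
        "score_gcn": gcn.score_drugs(cand_graphs),
        "score_dmpnn": dmp.score_drugs(cand_graphs,
                                       extra=cand_des.to_numpy()),
    }, index=cand_idx)
    scores["model_consensus"] = consensus(
        scores[["score_svm", "score_gcn", "score_dmpnn"]],
        threshold=config.consensus_threshold)
    scores["signal"] = [d in signal_drugs for d in scores.index]
    scores["consensus_highrisk"] = scores["model_consensus"] & scores["signal"]
    scores.rename_axis("drugname").reset_index().to_csv(
        out / "predictions.tsv", sep="\t", index=False)
    manifest["stages"]["consensus"] = sorted(
        scores.index[scores["consensus_highrisk"]])

    # ---- stage 7: signature enrichment -------------------------------------
    logger.info("stage 7: signature scoring")
    bulk_adj = sig.batch_adjust(bulk)
    enrich = {}
    for name, genes in gene_sets.items():
        res = sig.ssgsea(bulk_adj, genes)
        f, p = sig.compare_groups(res.scores, bulk_adj.annotation["group"])
        by_group = res.scores.groupby(bulk_adj.annotation["group"]).mean()
        enrich[name] = {"anova_F": f, "anova_p": p,
                        "group_means": dict(by_group.round(4))}
        res.scores.rename("score").to_csv(out / f"ssgsea_{name}.tsv", sep="\t")
    io.write_json(enrich, out / "ssgsea_tests.json")

    cells_qc = sig.qc_filter_cells(cells)
    ms = sig.add_module_score(cells_qc, sig_genes, seed=seed)
    ms.scores.rename("score").to_csv(out / "module_scores.tsv", sep="\t")
    ct = sig.compare_celltypes(ms.scores, cells_qc.annotation["cell_type"])
    ct.to_csv(out / "celltype_tests.tsv", sep="\t")
    manifest["stages"]["signature"] = {
        "bulk": {k: v["anova_p"] for k, v in enrich.items()},
        "top_cell_type": ct.index[0],
        "n_cells_after_qc": int(cells_qc.matrix.shape[1])}

    # ---- stage 8: target overlap -------------------------------------------
    logger.info("stage 8: target overlap")
    rng = np.random.default_rng(seed + 4)
    universe = [f"GENE{i:05d}" for i in range(2000)]
    shared = list(rng.choice(universe, size=25, replace=False))
    drug_targets = set(shared) | set(rng.choice(universe, 30, replace=False))
    disease = pd.DataFrame({
        "gene": shared + list(rng.choice(universe, 60, replace=False)),
        "score": np.round(rng.uniform(10, 40, size=len(shared) + 60), 2)})
    ov = overlap_analysis(drug_targets, disease, universe=len(universe))
    io.write_json(ov, out / "overlap.json")
    manifest["stages"]["overlap"] = {"overlap": ov["overlap"], "p": ov["p"]}

    # ---- final call ---------------------------------------------------------
    hits = [d for d in manifest["stages"]["consensus"]
            if enrich.get(f"signature_{d}", {}).get("anova_p", 1.0) < 0.05]
    manifest["final_hits"] = hits
    manifest["truth"] = {"planted_drug": roster.planted,
                         "motif_only": roster.motif_only,
                         "signal_only": roster.signal_only}
    io.write_json(manifest, out / "manifest.json")
    logger.info("final hits: %s", hits)
    return manifest
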
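"""Synthetic study-data generators with planted ground truth.

Every downstream stage of the trigger-discovery pipeline (disproportionality,
time-to-onset, structure-based risk models, signature scoring) is exercised on
data produced here, so each generator plants a known effect and exposes it:

* spontaneous-report tables in a FAERS-like layout with planted drug-event
  relative risks, Weibull-distributed onset times, duplicated case ids and
  co-medication confounding;
* labelled SMILES sets drawn from a built-in library in which the positive
  class is enriched for a sulfinyl-benzimidazole structural motif (the
  proton-pump-inhibitor core), so fingerprints and graphs carry learnable
  signal;
* bulk (log-normal) and single-cell (negative-binomial) expression matrices
  with a drug signature shifted in one subtype or cell type, plus named
  mitochondrial / ribosomal / hemoglobin genes and engineered QC-failing cells.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import ExpressionBundle

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "FILLER_EVENT",
    "REPORT_COLUMNS",
    "generate_reports",
    "load_smiles_library",
    "generate_molecule_set",
    "generate_expression",
]

#: event term absorbing the probability mass not assigned to declared events
FILLER_EVENT = "PRODUCT USED FOR UNKNOWN INDICATION"

REPORT_COLUMNS = [
    "CASEID", "FDA_DT", "DRUGNAME", "PT", "SEX", "AGE", "WT",
    "COUNTRY", "OCCP_COD", "OUTC_COD", "START_DT", "EVENT_DT",
]

# categorical sampling tables for report demographics; shares follow the
# FAERS juvenile-arthritis reporting profile (heavily female, school-age,
# North-America dominated, physician-reported)
_SEX = (["F", "M", "unknown"], [0.64, 0.26, 0.10])
_COUNTRY = (
    ["CANADA", "UNITED STATES", "GERMANY", "UNITED KINGDOM", "JAPAN", "OTHER"],
    [0.35, 0.25, 0.10, 0.08, 0.06, 0.16],
)
_REPORTER = (["MD", "CN", "PH", "OT", "unknown"], [0.37, 0.29, 0.20, 0.09, 0.05])
_OUTCOME = (["HO", "DS", "LT", "DE", "OT"], [0.236, 0.073, 0.02, 0.007, 0.664])

_EPOCH = np.datetime64("2004-01-01")
_START_SPAN_DAYS = 7300  # start dates span 2004-01-01 .. ~2023-12


@dataclass
class SimConfig:
    """Parameters of the FAERS-like report simulator.

    ``planted_signals`` maps (drug, event) to a relative-risk multiplier
    (RR >= 1) applied to ``background_rate``; ``tto_params`` maps drug to
    (Weibull scale alpha in days, shape beta) used for the onset-time gap
    between START_DT and EVENT_DT of its planted-event reports.
    """

    n_reports: int
    drugs: list[str]
    events: list[str]
    background_rate: float = 0.01
    planted_signals: dict[tuple[str, str], float] = field(default_factory=dict)
    tto_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    dup_fraction: float = 0.0
    comed_fraction: float = 0.0
    comed_drug: str = "METHOTREXATE"
    default_tto: tuple[float, float] = (90.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if not self.drugs or not self.events:
            raise ValueError("drugs and events must be non-empty")
        if not 0.0 <= self.background_rate <= 1.0:
            raise ValueError("background_rate must be in [0, 1]")
        for frac, name in ((self.dup_fraction, "dup_fraction"),
                           (self.comed_fraction, "comed_fraction")):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for (drug, event), rr in self.planted_signals.items():
            if drug not in self.drugs:
                raise ValueError(f"planted signal references unknown drug {drug!r}")
            if event not in self.events:
                raise ValueError(f"planted signal references unknown event {event!r}")
            if rr < 1.0:
                raise ValueError("planted relative risks must be >= 1")
        for drug, (alpha, beta) in self.tto_params.items():
            if drug not in self.drugs:
                raise ValueError(f"tto_params references unknown drug {drug!r}")
            if alpha <= 0 or beta <= 0:
                raise ValueError("Weibull scale and shape must be > 0")
        rate = self.background_rate * max(
            [sum(self.planted_signals.get((d, e), 1.0) for e in self.events)
             for d in self.drugs]
        )
        if rate > 1.0:
            raise ValueError("background_rate x summed RR exceeds 1 for some drug")

    @property
    def signal_drugs(self) -> set[str]:
        return {d for (d, _e), rr in self.planted_signals.items() if rr > 1.0}


@dataclass
class SyntheticTruth:
    """Planted ground truth assembled across the generators."""

    signal_pairs: set[tuple[str, str]] = field(default_factory=set)
    tto_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    molecule_labels: dict[str, int] = field(default_factory=dict)
    signature_genes: list[str] = field(default_factory=list)
    enriched_group: str | None = None


def _dt_str(days_since_epoch: np.ndarray) -> np.ndarray:
    dates = _EPOCH + days_since_epoch.astype("timedelta64[D]")
    return np.datetime_as_string(dates, unit="D")


def _pick(rng: np.random.Generator, table: tuple[list[str], list[float]],
          n: int) -> np.ndarray:
    values, probs = table
    return rng.choice(np.asarray(values, dtype=object), size=n, p=probs)


def generate_reports(config: SimConfig) -> pd.DataFrame:
    """Emit a FAERS-like report table (one row per report version).

    Per report: the drug is uniform over ``config.drugs``; the event term is
    drawn with P(event e | drug d) = background_rate * RR(d, e), the residual
    mass going to :data:`FILLER_EVENT`; EVENT_DT - START_DT follows the drug's
    Weibull onset model for its planted events and ``default_tto`` otherwise.
    A ``dup_fraction`` of cases is emitted twice with a later receipt date, and
    a ``comed_fraction`` of signal-drug reports also lists ``comed_drug``.
    Every planted signal pair is guaranteed to appear at least once.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = np.asarray(config.drugs, dtype=object)
    events = list(config.events)

    drug_idx = rng.integers(0, len(drugs), size=n)
    drug_col = drugs[drug_idx]

    # per-drug event distribution: declared events + filler remainder
    probs = np.empty((len(drugs), len(events) + 1))
    for i, d in enumerate(drugs):
        p = np.array([config.background_rate *
                      config.planted_signals.get((d, e), 1.0) for e in events])
        probs[i, :-1] = p
        probs[i, -1] = 1.0 - p.sum()
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n)
    event_idx = (u[:, None] > cum[drug_idx]).sum(axis=1)
    event_terms = np.asarray(events + [FILLER_EVENT], dtype=object)
    event_col = event_terms[event_idx]

    # force at least one occurrence of every planted pair
    for j, (d, e) in enumerate(config.planted_signals):
        mask = (drug_col == d) & (event_col == e)
        if not mask.any():
            slot = int(np.flatnonzero(drug_col == d)[0]) if (drug_col == d).any() else j
            drug_col[slot], event_col[slot] = d, e

    # onset gap in days: planted (drug, event) pairs use the drug's Weibull
    alpha = np.full(n, config.default_tto[0])
    beta = np.full(n, config.default_tto[1])
    for (d, e) in config.planted_signals:
        if d in config.tto_params:
            a, b = config.tto_params[d]
            mask = (drug_col == d) & (event_col == e)
            alpha[mask], beta[mask] = a, b
    tto_days = np.maximum(np.rint(alpha * rng.weibull(beta, size=n)), 0).astype(int)

    start = rng.integers(0, _START_SPAN_DAYS, size=n)
    event_dt = start + tto_days
    receipt = event_dt + rng.integers(0, 181, size=n)

    age = np.clip(np.rint(rng.normal(9.5, 4.5, size=n)), 0, 17).astype(int)
    weight = np.round(np.clip(rng.normal(12 + 3.1 * age, 6.0, size=n), 4, 120), 1)

    drug_field = drug_col.copy()
    if config.comed_fraction > 0 and config.signal_drugs:
        sig_rows = np.flatnonzero(np.isin(drug_col, sorted(config.signal_drugs)))
        k = int(np.floor(config.comed_fraction * len(sig_rows)))
        chosen = rng.choice(sig_rows, size=k, replace=False)
        for r in chosen:
            drug_field[r] = f"{drug_field[r]}|{config.comed_drug}"

    df = pd.DataFrame({
        "CASEID": [f"C{i:08d}" for i in range(n)],
        "FDA_DT": _dt_str(receipt),
        "DRUGNAME": drug_field,
        "PT": event_col,
        "SEX": _pick(rng, _SEX, n),
        "AGE": age,
        "WT": weight,
        "COUNTRY": _pick(rng, _COUNTRY, n),
        "OCCP_COD": _pick(rng, _REPORTER, n),
        "OUTC_COD": _pick(rng, _OUTCOME, n),
        "START_DT": _dt_str(start),
        "EVENT_DT": _dt_str(event_dt),
    })

    n_dup = int(np.floor(config.dup_fraction * n))
    if n_dup:
        dup_rows = rng.choice(n, size=n_dup, replace=False)
        dups = df.iloc[dup_rows].copy()
        later = receipt[dup_rows] + rng.integers(30, 366, size=n_dup)
        dups["FDA_DT"] = _dt_str(later)
        df = pd.concat([df, dups], ignore_index=True)
    return df


def load_smiles_library() -> pd.DataFrame:
    """The built-in library of ~200 validated drug-like SMILES.

    Columns: cid, name, smiles, has_motif (1 if the molecule carries the
    sulfinyl-benzimidazole motif the positive class is enriched for).
    """
    ref = importlib.resources.files("pvtrigger.data") / "smiles_library.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def generate_molecule_set(n_pos: int, n_neg: int, seed: int = 0,
                          motif_enrichment: float = 0.95) -> pd.DataFrame:
    """Draw a labelled molecule table (cid, drugname, smiles, label).

    Positives come from the motif stratum of the library with probability
    ``motif_enrichment`` (>= 0.9 by default) and negatives from the non-motif
    stratum with the same probability, so the structural signal is strong but
    not perfectly separable. Sampling is without replacement.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    lib = load_smiles_library()
    rng = np.random.default_rng(seed)
    used: set[str] = set()

    def _draw(n: int, primary: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
        if n > len(primary):
            raise ValueError("requested set exceeds library stratum size")
        n_primary = int(np.sum(rng.random(n) < motif_enrichment))
        n_other = n - n_primary
        if n_other > len(other):
            raise ValueError("requested set exceeds library stratum size")
        rows = [primary.iloc[rng.choice(len(primary), n_primary, replace=False)],
                other.iloc[rng.choice(len(other), n_other, replace=False)]]
        return pd.concat(rows, ignore_index=True)

    motif = lib[lib["has_motif"] == 1]
    plain = lib[lib["has_motif"] == 0]
    pos = _draw(n_pos, motif, plain).assign(label=1)
    used = set(pos["cid"])
    neg = _draw(n_neg, plain[~plain["cid"].isin(used)],
                motif[~motif["cid"].isin(used)]).assign(label=0)
    out = pd.concat([pos, neg], ignore_index=True)
    out = out.rename(columns={"name": "drugname"})
    return out[["cid", "drugname", "smiles", "label"]]


_MT_GENES = [f"MT-{g}" for g in
             ("ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
              "CYTB", "CO1", "CO2", "CO3", "ATP6", "ATP8")]
_RIBO_GENES = [f"RPS{i}" for i in range(2, 13)] + [f"RPL{i}" for i in range(3, 14)]
_HB_GENES = ["HBB", "HBA1", "HBA2"]


def generate_expression(mode: str, n_samples_or_cells: int, groups: list[str],
                        signature: list[str], effect: float, seed: int = 0,
                        *, enriched_group: str | None = None, n_genes: int = 1000,
                        n_batches: int = 1, batch_shift: float = 0.0,
                        qc_fail_fraction: float = 0.0) -> ExpressionBundle:
    """Simulate an expression matrix with a planted drug signature.

    ``mode='bulk'``: log-normal expression on a log2 scale; signature genes in
    ``enriched_group`` are shifted by ``effect`` log2 units.  ``mode='single_cell'``:
    negative-binomial counts (gene means log-normal, dispersion 0.5); signature
    gene means are multiplied by ``2**effect`` in the enriched cell type, named
    mitochondrial / ribosomal / hemoglobin genes are present, and a
    ``qc_fail_fraction`` of cells is engineered to decisively violate one QC
    rule each (annotation columns ``truth_qc_fail`` / ``truth_qc_reason``).
    """
    if mode not in ("bulk", "single_cell"):
        raise ValueError("mode must be 'bulk' or 'single_cell'")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    if not groups:
        raise ValueError("groups must be non-empty")
    enriched_group = enriched_group or groups[0]
    if enriched_group not in groups:
        raise ValueError(f"unknown group label {enriched_group!r}")
    rng = np.random.default_rng(seed)
    n = n_samples_or_cells

    special = (_MT_GENES + _RIBO_GENES + _HB_GENES) if mode == "single_cell" else []
    named = list(dict.fromkeys(list(signature) + special))
    n_filler = max(n_genes - len(named), 0)
    genes = named + [f"GENE{i:05d}" for i in range(n_filler)]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names in signature")
    sig_idx = np.array([genes.index(g) for g in signature])
    g = len(genes)

    labels = np.asarray(groups, dtype=object)[rng.integers(0, len(groups), size=n)]
    batches = rng.integers(0, n_batches, size=n)
    in_group = labels == enriched_group

    if mode == "bulk":
        mu = rng.normal(7.0, 1.5, size=g)
        log2x = rng.normal(mu[:, None], 1.0, size=(g, n))
        log2x[np.ix_(sig_idx, np.flatnonzero(in_group))] += effect
        log2x += batch_shift * batches[None, :]
        matrix = pd.DataFrame(2.0 ** log2x, index=genes,
                              columns=[f"S{i:04d}" for i in range(n)])
        ann = pd.DataFrame({"group": labels, "batch": batches},
                           index=matrix.columns)
        return ExpressionBundle(matrix=matrix, annotation=ann, mode="bulk")

    # single-cell negative-binomial counts
    base = np.exp(rng.normal(0.0, 1.0, size=g))     # gene-specific means
    base[[genes.index(x) for x in _HB_GENES]] = 0.0  # clean cells: no hemoglobin
    mt_rows = np.array([genes.index(x) for x in _MT_GENES])
    ribo_rows = np.array([genes.index(x) for x in _RIBO_GENES])
    other = np.setdiff1d(np.arange(g), np.concatenate([mt_rows, ribo_rows]))
    # calibrate family shares: ~5% mitochondrial, ~10% ribosomal of counts
    base[mt_rows] *= 0.05 * base[other].sum() / max(base[mt_rows].sum(), 1e-9) / 0.85
    base[ribo_rows] *= 0.10 * base[other].sum() / max(base[ribo_rows].sum(), 1e-9) / 0.85
    base *= 3000.0 / base.sum()                      # ~3000 counts per cell

    mean = np.repeat(base[:, None], n, axis=1)
    mean[np.ix_(sig_idx, np.flatnonzero(in_group))] *= 2.0 ** effect
    if batch_shift:
        mean *= 2.0 ** (batch_shift * batches[None, :] * rng.random(g)[:, None])

    n_fail = int(np.floor(qc_fail_fraction * n))
    fail_cells = rng.choice(n, size=n_fail, replace=False)
    reasons = np.array(["high_mt", "low_ribo", "hemoglobin", "few_genes"],
                       dtype=object)[np.arange(n_fail) % 4]
    for cell, reason in zip(fail_cells, reasons):
        if reason == "high_mt":
            mean[mt_rows, cell] *= 10.0       # ~35% mitochondrial
        elif reason == "low_ribo":
            mean[ribo_rows, cell] *= 0.05     # <1% ribosomal
        elif reason == "few_genes":
            mean[:, cell] *= 0.03             # ~90 counts: <200 genes

    disp = 0.5                                 # NB dispersion; size r = 1/disp
    r = 1.0 / disp
    counts = rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))
    for cell, reason in zip(fail_cells, reasons):
        if reason == "hemoglobin":
            counts[genes.index("HBB"), cell] = 1 + rng.poisson(4)

    qc_fail = np.zeros(n, dtype=bool)
    qc_fail[fail_cells] = True
    reason_col = np.full(n, "", dtype=object)
    reason_col[fail_cells] = reasons
    matrix = pd.DataFrame(counts, index=genes,
                          columns=[f"CELL{i:05d}" for i in range(n)])
    ann = pd.DataFrame({"cell_type": labels, "batch": batches,
                        "truth_qc_fail": qc_fail, "truth_qc_reason": reason_col},
                       index=matrix.columns)
    return ExpressionBundle(matrix=matrix, annotation=ann, mode="single_cell")
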
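"""Spontaneous-report disproportionality analysis.

Implements the four signal-detection statistics used for drug-event screening
in spontaneous reporting systems, applied to a deduplicated FAERS-like report
table:

* ROR — reporting odds ratio with a 95% CI on the log scale;
* PRR — proportional reporting ratio with a Yates-corrected chi-square;
* BCPNN IC — information component under the closed-form gamma approximation
  (Bate 1998 priors: alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1, gamma
  scaled so E(IC) -> 0 under independence), with IC025 = E(IC) - 2*sd;
* MGPS EBGM — DuMouchel's two-component gamma-Poisson shrinker, fitted by
  maximising the negative-binomial marginal likelihood of observed counts
  given their expectations, with EBGM = exp(E[ln lambda]) and EBGM05 the 5th
  posterior percentile.

A drug is flagged per algorithm using the field-standard positivity criteria
(a >= 3 & ROR CI low > 1; a >= 3, PRR >= 2 & chi2 >= 4; IC025 > 0;
EBGM05 > 2), and a consensus signal requires all four. A co-medication
sensitivity filter and a descriptive cohort summary complete the module.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "MgpsPrior",
    "SignalThresholds",
    "normalize_drug_name",
    "deduplicate",
    "build_contingency",
    "ror",
    "prr_chi2",
    "bcpnn_ic",
    "fit_mgps_prior",
    "mgps_ebgm",
    "disproportionality_table",
    "detect_signals",
    "sensitivity_filter",
    "descriptive_summary",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event counts: a = drug & event, b = drug only, c = event only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def corrected(self) -> "ContingencyTable":
        """Haldane-Anscombe +0.5 continuity correction (returns float cells)."""
        t = object.__new__(ContingencyTable)
        object.__setattr__(t, "a", self.a + 0.5)
        object.__setattr__(t, "b", self.b + 0.5)
        object.__setattr__(t, "c", self.c + 0.5)
        object.__setattr__(t, "d", self.d + 0.5)
        return t


_PAREN = re.compile(r"\([^)]*\)")


def normalize_drug_name(raw: str) -> list[str]:
    """Normalize a FAERS-style drug field into a list of names.

    Uppercases, splits compound entries on '|', strips parenthetical
    qualifiers and trailing periods (fields like 'CELECOXIB.|CELECOXIB'
    normalize to a single name).
    """
    names = []
    for part in str(raw).split("|"):
        name = _PAREN.sub("", part.upper()).strip().rstrip(".").strip()
        if name and name not in names:
            names.append(name)
    return names


def _parse_dates(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")


def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Keep one row per CASEID: the latest receipt date, last-in-file on ties.

    Rows whose FDA_DT cannot be parsed are rejected with a logged warning.
    """
    dates = _parse_dates(reports["FDA_DT"])
    bad = dates.isna()
    if bad.any():
        logger.warning("dropping %d rows with unparseable FDA_DT", int(bad.sum()))
    df = reports.loc[~bad].copy()
    order = np.arange(len(df))
    keep = (df.assign(_dt=dates[~bad].to_numpy(), _ord=order)
              .sort_values(["_dt", "_ord"], kind="stable")
              .groupby("CASEID", sort=False).tail(1)
              .sort_values("_ord"))
    return keep.drop(columns=["_dt", "_ord"]).reset_index(drop=True)


def _drug_sets(reports: pd.DataFrame) -> list[frozenset]:
    return [frozenset(normalize_drug_name(x)) for x in reports["DRUGNAME"]]


def build_contingency(reports: pd.DataFrame, drug: str,
                      event: str) -> ContingencyTable:
    """2x2 table for one drug-event pair over a deduplicated report table.

    A report with several listed drugs counts once for each of them.
    """
    if len(reports) == 0:
        raise ValueError("empty report table")
    drug = normalize_drug_name(drug)[0]
    event = event.strip().upper()
    has_drug = np.array([drug in s for s in _drug_sets(reports)])
    has_event = reports["PT"].str.strip().str.upper().eq(event).to_numpy()
    a = int((has_drug & has_event).sum())
    b = int((has_drug & ~has_event).sum())
    c = int((~has_drug & has_event).sum())
    d = int((~has_drug & ~has_event).sum())
    return ContingencyTable(a, b, c, d)


def ror(t: ContingencyTable) -> tuple[float, tuple[float, float], bool]:
    """Reporting odds ratio with 95% CI; zero cells get the +0.5 correction.

    Returns (ror, (lo, hi), corrected).
    """
    corrected = min(t.a, t.b, t.c, t.d) == 0
    u = t.corrected() if corrected else t
    est = (u.a * u.d) / (u.b * u.c)
    se = np.sqrt(1 / u.a + 1 / u.b + 1 / u.c + 1 / u.d)
    lo, hi = np.exp(np.log(est) - 1.96 * se), np.exp(np.log(est) + 1.96 * se)
    return float(est), (float(lo), float(hi)), corrected


def prr_chi2(t: ContingencyTable) -> tuple[float, float, bool]:
    """Proportional reporting ratio and Yates-corrected chi-square.

    The chi-square is always computed on the observed (uncorrected) cells;
    the PRR falls back to +0.5-corrected cells when a marginal cell is zero.
    Returns (prr, chi2, corrected).
    """
    corrected = t.a + t.b == 0 or t.c + t.d == 0 or t.c == 0
    u = t.corrected() if corrected else t
    prr = (u.a / (u.a + u.b)) / (u.c / (u.c + u.d))
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    exp = np.outer(row, col) / t.n
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
        cells = np.where(exp > 0, dev ** 2 / exp, 0.0)
    return float(prr), float(cells.sum()), corrected


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """Information component E(IC) and IC025 = E(IC) - 2*sd(IC).

    Closed-form gamma approximation of the BCPNN posterior with Beta priors
    alpha1 = beta1 = 1 on the margins, alpha = beta = 2 on the joint cell,
    gamma11 = 1 and gamma scaled so E(IC) = 0 under exact independence. The
    point estimate converges to log2(a*N / ((a+b)(a+c))) as counts grow.
    """
    a, n = t.a, t.n
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    row, col = t.a + t.b, t.a + t.c
    gamma = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
    eic = np.log2((a + g11) * (n + al) * (n + be)
                  / ((n + gamma) * (row + a1) * (col + b1)))
    vic = ((n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
           + (n - row + al - a1) / ((row + a1) * (1 + n + al))
           + (n - col + be - b1) / ((col + b1) * (1 + n + be))) / np.log(2) ** 2
    return float(eic), float(eic - 2.0 * np.sqrt(vic))


@dataclass
class MgpsPrior:
    """Two-component gamma mixture prior for the relative reporting rate.

    Components Gamma(alpha_i, beta_i) (shape, rate) mixed with weight
    ``p_mix`` on the first.
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    p_mix: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be > 0")
        if not 0.0 <= self.p_mix <= 1.0:
            raise ValueError("p_mix must be in [0, 1]")


def _nb_logpmf(a: np.ndarray, e: np.ndarray, alpha: float,
               beta: float) -> np.ndarray:
    """Marginal log P(a | E) when lambda ~ Gamma(alpha, beta), a ~ Poisson(lambda*E)."""
    return (special.gammaln(alpha + a) - special.gammaln(alpha)
            - special.gammaln(a + 1) + alpha * np.log(beta / (beta + e))
            + a * np.log(e / (beta + e)))


def _mixture_nll(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_p = theta
    p = 1.0 / (1.0 + np.exp(-logit_p))
    l1 = _nb_logpmf(a, e, np.exp(la1), np.exp(lb1)) + np.log(p)
    l2 = _nb_logpmf(a, e, np.exp(la2), np.exp(lb2)) + np.log1p(-p)
    return -float(np.logaddexp(l1, l2).sum())


def fit_mgps_prior(tables: list[ContingencyTable], seed: int = 0,
                   n_starts: int = 6, min_count: int = 1) -> MgpsPrior:
    """Fit the 5-parameter mixture prior by seeded multi-start ML.

    Fitting is restricted to pairs with a >= ``min_count`` (DuMouchel's
    truncation); the DuMouchel starting values (0.2, 0.1, 2, 4, 1/3) seed the
    first start and the rest are log-scale perturbations of it.
    """
    if len(tables) < 10:
        raise ValueError("need >= 10 drug-event pairs to fit the MGPS prior")
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([t.expected for t in tables], dtype=float)
    keep = (a >= min_count) & (e > 0)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 usable pairs after truncation")
    a, e = a[keep], e[keep]
    rng = np.random.default_rng(seed)
    base = np.array([np.log(0.2), np.log(0.1), np.log(2.0), np.log(4.0),
                     np.log(0.5)])  # logit(1/3) = log(0.5)
    best = None
    for i in range(n_starts):
        x0 = base if i == 0 else base + rng.normal(0, 1.0, size=5)
        res = optimize.minimize(_mixture_nll, x0, args=(a, e),
                                method="L-BFGS-B",
                                bounds=[(-10, 8)] * 4 + [(-8, 8)])
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("MGPS prior fit failed to converge in any start")
    la1, lb1, la2, lb2, lp = best.x
    return MgpsPrior(np.exp(la1), np.exp(lb1), np.exp(la2), np.exp(lb2),
                     1.0 / (1.0 + np.exp(-lp)))


def mgps_ebgm(tables: list[ContingencyTable],
              prior: MgpsPrior | None = None,
              seed: int = 0) -> list[tuple[float, float]]:
    """EBGM and EBGM05 for each table; the prior is fitted if not given.

    The posterior for lambda = a/E is the gamma mixture
    Q * Gamma(alpha1 + a, beta1 + E) + (1-Q) * Gamma(alpha2 + a, beta2 + E);
    EBGM = exp(E[ln lambda]) via the digamma function and EBGM05 solves the
    mixture CDF = 0.05 by bracketed root-finding.
    """
    if prior is None:
        prior = fit_mgps_prior(tables, seed=seed)
    out = []
    for t in tables:
        a, e = t.a, t.expected
        if e <= 0:
            raise ValueError("expected count must be > 0")
        l1 = _nb_logpmf(np.array([a], float), np.array([e]), prior.alpha1,
                        prior.beta1)[0] + np.log(max(prior.p_mix, 1e-300))
        l2 = _nb_logpmf(np.array([a], float), np.array([e]), prior.alpha2,
                        prior.beta2)[0] + np.log(max(1 - prior.p_mix, 1e-300))
        q1 = float(np.exp(l1 - np.logaddexp(l1, l2)))
        sh1, ra1 = prior.alpha1 + a, prior.beta1 + e
        sh2, ra2 = prior.alpha2 + a, prior.beta2 + e
        elog = (q1 * (special.digamma(sh1) - np.log(ra1))
                + (1 - q1) * (special.digamma(sh2) - np.log(ra2)))
        ebgm = float(np.exp(elog))

        def cdf(x: float) -> float:
            return (q1 * stats.gamma.cdf(x, sh1, scale=1 / ra1)
                    + (1 - q1) * stats.gamma.cdf(x, sh2, scale=1 / ra2))

        lo, hi = 1e-12, 10.0
        while cdf(hi) < 0.05:
            hi *= 2
        ebgm05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi))
        out.append((ebgm, ebgm05))
    return out


@dataclass(frozen=True)
class SignalThresholds:
    """Field-standard positivity criteria, configurable per algorithm."""

    min_count: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


def disproportionality_table(reports: pd.DataFrame, event: str,
                             drugs: list[str] | None = None,
                             prior: MgpsPrior | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """All four statistics for every drug against one target event.

    The MGPS prior is fitted once on the full drug x event grid of the table
    (pairs with a >= 1) unless supplied. Returns one row per drug.
    """
    sets = _drug_sets(reports)
    if drugs is None:
        drugs = sorted({d for s in sets for d in s})
    n_total = len(reports)
    pt = reports["PT"].str.strip().str.upper()
    event = event.strip().upper()
    has_drug = {d: np.zeros(n_total, dtype=bool) for d in drugs}
    for i, s in enumerate(sets):
        for d in s:
            if d in has_drug:
                has_drug[d][i] = True

    def _table(d: str, ev_mask: np.ndarray) -> ContingencyTable:
        hd = has_drug[d]
        a = int((hd & ev_mask).sum())
        nd, ne = int(hd.sum()), int(ev_mask.sum())
        return ContingencyTable(a, nd - a, ne - a, n_total - nd - ne + a)

    if prior is None:
        grid = []
        for ev in sorted(pt.unique()):
            ev_mask = pt.eq(ev).to_numpy()
            for d in drugs:
                t = _table(d, ev_mask)
                if t.a >= 1:
                    grid.append(t)
        prior = fit_mgps_prior(grid, seed=seed)

    target_mask = pt.eq(event).to_numpy()
    tables = [_table(d, target_mask) for d in drugs]
    eb = mgps_ebgm(tables, prior=prior)
    rows = []
    for d, t, (ebgm, ebgm05) in zip(drugs, tables, eb):
        r, (lo, hi), r_corr = ror(t)
        prr, chi2, p_corr = prr_chi2(t)
        ic, ic025 = bcpnn_ic(t)
        rows.append(dict(drug=d, a=t.a, b=t.b, c=t.c, d=t.d, ror=r,
                         ror_lo=lo, ror_hi=hi, prr=prr, chi2=chi2, ic=ic,
                         ic025=ic025, ebgm=ebgm, ebgm05=ebgm05,
                         corrected=r_corr or p_corr))
    return pd.DataFrame(rows)


def detect_signals(results: pd.DataFrame,
                   thresholds: SignalThresholds = SignalThresholds()
                   ) -> pd.DataFrame:
    """Apply per-algorithm positivity flags and the all-four consensus."""
    th = thresholds
    out = results.copy()
    out["flag_ror"] = (out["a"] >= th.min_count) & (out["ror_lo"] > th.ror_ci_low)
    out["flag_prr"] = ((out["a"] >= th.min_count) & (out["prr"] >= th.prr_min)
                       & (out["chi2"] >= th.chi2_min))
    out["flag_bcpnn"] = out["ic025"] > th.ic025_min
    out["flag_mgps"] = out["ebgm05"] > th.ebgm05_min
    out["consensus"] = (out["flag_ror"] & out["flag_prr"]
                        & out["flag_bcpnn"] & out["flag_mgps"])
    return out


def sensitivity_filter(reports: pd.DataFrame,
                       excluded_drugs: list[str]) -> pd.DataFrame:
    """Drop reports listing any excluded drug (case-insensitive, normalized)."""
    if not excluded_drugs:
        return reports
    excl = {n for d in excluded_drugs for n in normalize_drug_name(d)}
    keep = [not (s & excl) for s in _drug_sets(reports)]
    return reports.loc[keep].reset_index(drop=True)


_AGE_BINS = [(0, 2), (3, 5), (6, 11), (12, 17)]


def descriptive_summary(reports: pd.DataFrame) -> dict:
    """Cohort descriptives with explicit denominators.

    Yearly counts, sex shares, pediatric age-group counts, weight quartiles,
    country / reporter shares and outcome rates; missing values are excluded
    from each denominator and reported.
    """
    out: dict = {"n_reports": int(len(reports))}
    years = _parse_dates(reports["FDA_DT"]).dt.year
    out["yearly_counts"] = {int(y): int(c)
                            for y, c in years.value_counts().sort_index().items()}

    sex = reports["SEX"].astype(str)
    known = sex.isin(["F", "M"])
    out["sex"] = {"denominator": int(known.sum()),
                  "missing": int((~known).sum()),
                  "female_share": float((sex == "F").sum() / max(known.sum(), 1)),
                  "male_share": float((sex == "M").sum() / max(known.sum(), 1))}

    age = pd.to_numeric(reports["AGE"], errors="coerce")
    groups = {f"{lo}-{hi}": int(((age >= lo) & (age <= hi)).sum())
              for lo, hi in _AGE_BINS}
    groups["unknown"] = int(age.isna().sum())
    out["age_groups"] = groups

    wt = pd.to_numeric(reports["WT"], errors="coerce").dropna()
    out["weight_kg"] = {"denominator": int(len(wt)),
                        "quartiles": [float(q) for q in
                                      np.quantile(wt, [0.25, 0.5, 0.75])]
                        if len(wt) else []}

    for key, col in (("country", "COUNTRY"), ("reporter", "OCCP_COD"),
                     ("outcome", "OUTC_COD")):
        vals = reports[col].astype(str)
        out[key] = {"denominator": int(len(vals)),
                    "shares": {k: float(v / len(vals))
                               for k, v in vals.value_counts().items()}}
    return out
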
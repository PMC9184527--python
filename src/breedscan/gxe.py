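"""Genotype means, genetic gain, grain-number variance partition and
factorial regression on environmental indices.

The variance partition uses sequential (type-I) sums of squares in the
model's written order: covariates (optional), year of release, residual
genotype, scenario, experiment-within-scenario, year x scenario, residual.
Genotype means come from a one-random-factor (experiment) mixed model fitted
by REML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import reml_fit

log = logging.getLogger(__name__)


# ----------------------------------------------------------- genotype means


def genotype_means(
    trial: pd.DataFrame, group_by: str = "scenario", value: str = "grain_number"
) -> pd.DataFrame:
    """Best linear unbiased estimates of hybrid means per group.

    Fits value = hybrid (fixed) + experiment (random) + error by REML within
    each group. Groups with fewer than 2 experiments fall back to arithmetic
    means with a warning. Hybrids absent from a group get NaN.
    """
    if group_by == "scenario":
        groups = trial["scenario"].astype(str)
    elif group_by == "treatment":
        groups = trial["scenario"].astype(str).str.split("-").str[1]
    elif group_by == "none":
        groups = pd.Series(["all"] * len(trial), index=trial.index)
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    hybrids = np.array(sorted(trial["hybrid"].astype(str).unique()), dtype=object)
    out = {}
    for g in sorted(groups.unique()):
        sub = trial.loc[groups == g]
        y = sub[value].to_numpy(dtype=float)
        hyb = sub["hybrid"].astype(str).to_numpy()
        exps = sub["experiment"].astype(str).to_numpy()
        present = np.array(sorted(set(hyb)))
        H = (hyb[:, None] == present[None, :]).astype(float)
        uniq_exp = np.array(sorted(set(exps)))
        est = pd.Series(np.nan, index=hybrids)
        if len(uniq_exp) < 2:
            warnings.warn(
                f"group {g!r} has fewer than 2 experiments; using arithmetic means",
                stacklevel=2,
            )
            for h in present:
                est[h] = float(y[hyb == h].mean())
        elif np.ptp(y) == 0:
            for h in present:
                est[h] = float(y[hyb == h].mean())
        else:
            Z = (exps[:, None] == uniq_exp[None, :]).astype(float)
            K = Z @ Z.T
            fit = reml_fit(y, H, K)
            est[present] = fit.beta
        out[g] = est
    return pd.DataFrame(out)


# ------------------------------------------------------------- genetic gain


@dataclass
class GeneticGain:
    slope: float
    stderr: float
    pvalue: float
    r2: float
    n: int


def genetic_gain(means: np.ndarray | pd.Series, years: np.ndarray) -> GeneticGain:
    """Genetic gain: OLS slope of the trait value on year of release."""
    means = np.asarray(means, dtype=float)
    years = np.asarray(years, dtype=float)
    ok = np.isfinite(means) & np.isfinite(years)
    if ok.sum() < 3:
        raise ValueError("need at least 3 (mean, year) pairs")
    if np.ptp(means[ok]) == 0:
        return GeneticGain(slope=0.0, stderr=0.0, pvalue=1.0, r2=0.0, n=int(ok.sum()))
    lr = stats.linregress(years[ok], means[ok])
    return GeneticGain(
        slope=float(lr.slope),
        stderr=float(lr.stderr),
        pvalue=float(lr.pvalue),
        r2=float(lr.rvalue**2),
        n=int(ok.sum()),
    )


# ------------------------------------------------------- variance partition


def _dummies(values: np.ndarray) -> np.ndarray:
    levels = np.array(sorted(set(values.astype(str))))
    return (values.astype(str)[:, None] == levels[None, :]).astype(float)


def _sequential_ss(y: np.ndarray, blocks: list[tuple[str, np.ndarray]]):
    """Sequential (type-I) sums of squares via incremental least squares."""
    n = len(y)
    X = np.ones((n, 1))
    resid = y - y.mean()
    ss_total = float(resid @ resid)
    rss_prev = ss_total
    rank_prev = 1
    rows = []
    for name, B in blocks:
        X = np.hstack([X, B])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        rows.append((name, rss_prev - rss, rank - rank_prev))
        rss_prev, rank_prev = rss, rank
    return rows, rss_prev, n - rank_prev, ss_total


@dataclass
class VariancePartition:
    """Ordered term -> (sum of squares, df, proportion of total)."""

    terms: list[str]
    ss: dict[str, float]
    df: dict[str, int]
    proportion: dict[str, float]
    residual_ss: float
    residual_df: int
    total_ss: float

    @property
    def residual_proportion(self) -> float:
        return self.residual_ss / self.total_ss

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "ss": self.ss[t], "df": self.df[t], "proportion": self.proportion[t]}
            for t in self.terms
        ]
        rows.append(
            {
                "term": "residual",
                "ss": self.residual_ss,
                "df": self.residual_df,
                "proportion": self.residual_proportion,
            }
        )
        return pd.DataFrame(rows)


def _model_blocks(trial: pd.DataFrame, covariates: tuple[str, ...]) -> list[tuple[str, np.ndarray]]:
    year = trial["year"].to_numpy(dtype=float)
    yc = (year - year.mean())[:, None]
    hyb = _dummies(trial["hybrid"].to_numpy())
    scen = _dummies(trial["scenario"].to_numpy())
    exp = _dummies(trial["experiment"].to_numpy())
    blocks: list[tuple[str, np.ndarray]] = []
    for cov in covariates:
        x = trial[cov].to_numpy(dtype=float)
        blocks.append((cov, (x - x.mean())[:, None]))
    blocks.append(("G_year", yc))
    blocks.append(("G_res", hyb))
    blocks.append(("Scen", scen))
    blocks.append(("E_res", exp))
    blocks.append(("G_year_x_Scen", yc * scen))
    return blocks


def partition_variance(
    trial: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    selection: str = "none",
    alpha: float = 0.05,
    value: str = "grain_number",
) -> VariancePartition:
    """Partition the grain-number variance into year-of-release, residual
    genotype, scenario, experiment-within-scenario and year x scenario terms
    (optionally preceded by trait covariates), as proportions of the total
    corrected sum of squares.

    selection='forward-backward' admits/removes terms at F-test alpha;
    excluded terms report proportion 0.
    """
    y = trial[value].to_numpy(dtype=float)
    blocks = _model_blocks(trial, covariates)
    term_names = [nm for nm, _ in blocks]
    if selection == "forward-backward":
        included = _forward_backward(y, blocks, alpha)
        blocks = [(nm, B) for nm, B in blocks if nm in included]
    elif selection != "none":
        raise ValueError(f"unknown selection {selection!r}")
    rows, rss, rdf, ss_total = _sequential_ss(y, blocks)
    if selection == "none":
        aliased = [nm for nm, _, df in rows if df == 0]
        if aliased:
            raise ValueError(f"rank-deficient design; fully aliased terms: {aliased}")
    ss = {nm: 0.0 for nm in term_names}
    df = {nm: 0 for nm in term_names}
    for nm, s, d in rows:
        ss[nm], df[nm] = max(s, 0.0), d
    if ss_total == 0:
        raise ValueError("response has zero variance")
    proportion = {nm: ss[nm] / ss_total for nm in term_names}
    return VariancePartition(
        terms=term_names,
        ss=ss,
        df=df,
        proportion=proportion,
        residual_ss=rss,
        residual_df=rdf,
        total_ss=ss_total,
    )


def _f_test(rss0: float, rss1: float, df_num: int, rss_df1: int) -> float:
    if df_num <= 0 or rss_df1 <= 0 or rss1 <= 0:
        return 1.0
    f = ((rss0 - rss1) / df_num) / (rss1 / rss_df1)
    return float(stats.f.sf(max(f, 0.0), df_num, rss_df1))


def _fit_rss(y: np.ndarray, blocks: list[np.ndarray]) -> tuple[float, int]:
    X = np.hstack([np.ones((len(y), 1))] + blocks) if blocks else np.ones((len(y), 1))
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2)), int(rank)


def _forward_backward(y, blocks, alpha) -> set[str]:
    names = [nm for nm, _ in blocks]
    mats = dict(blocks)
    included: list[str] = []
    # forward pass in the written model order
    changed = True
    while changed:
        changed = False
        for nm in names:
            if nm in included:
                continue
            rss0, rank0 = _fit_rss(y, [mats[n] for n in included])
            rss1, rank1 = _fit_rss(y, [mats[n] for n in included + [nm]])
            p = _f_test(rss0, rss1, rank1 - rank0, len(y) - rank1)
            if rank1 > rank0 and p < alpha:
                included.append(nm)
                changed = True
        # backward pass; a term fully aliased by the others (zero marginal
        # rank, e.g. year under the hybrid factor) is kept so sequential
        # attribution in the written order is preserved
        for nm in list(included):
            others = [n for n in included if n != nm]
            rss0, rank0 = _fit_rss(y, [mats[n] for n in others])
            rss1, rank1 = _fit_rss(y, [mats[n] for n in included])
            p = _f_test(rss0, rss1, rank1 - rank0, len(y) - rank1)
            if rank1 > rank0 and p >= alpha:
                included.remove(nm)
                changed = True
    return set(included)


# -------------------------------------------------------- factorial regression


@dataclass
class Sensitivities:
    """Per-genotype sensitivities to environmental indices."""

    table: pd.DataFrame  # columns: hybrid, beta1, se1, beta2, se2
    psi_included: bool
    rint_included: bool
    residual_gxe_proportion: float


def factorial_regression(
    trial: pd.DataFrame, alpha: float = 0.05, value: str = "grain_number"
) -> Sensitivities:
    """Factorial regression: genotype-specific slopes on centered soil water
    potential (beta1, per MPa) and intercepted radiation (beta2, per MJ m^-2),
    admitted sequentially by F-test at `alpha` on top of the main-effects
    model (year, hybrid, scenario, experiment)."""
    y = trial[value].to_numpy(dtype=float)
    hyb_levels = np.array(sorted(trial["hybrid"].astype(str).unique()))
    H = (trial["hybrid"].astype(str).to_numpy()[:, None] == hyb_levels[None, :]).astype(float)
    year = trial["year"].to_numpy(dtype=float)
    base = [
        (year - year.mean())[:, None],
        H,
        _dummies(trial["scenario"].to_numpy()),
        _dummies(trial["experiment"].to_numpy()),
    ]
    psi = trial["psi"].to_numpy(dtype=float)
    rint = trial["r_int"].to_numpy(dtype=float)
    psi_c = psi - psi.mean()
    rint_c = rint - rint.mean()
    blocks = list(base)
    included = {}
    # sum-to-zero coding on the hybrid axis: the panel-mean sensitivity is
    # aliased with experiment main effects, so slopes are estimated (and
    # reported) as deviations from the panel mean
    Hc = H - 1.0 / H.shape[1]
    for name, xc in (("psi", psi_c), ("rint", rint_c)):
        cand = Hc * xc[:, None]
        rss0, rank0 = _fit_rss(y, blocks)
        rss1, rank1 = _fit_rss(y, blocks + [cand])
        p = _f_test(rss0, rss1, rank1 - rank0, len(y) - rank1)
        if rank1 > rank0 and p < alpha:
            blocks.append(cand)
            included[name] = True
        else:
            included[name] = False
    X = np.hstack([np.ones((len(y), 1))] + blocks)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = max(len(y) - rank, 1)
    sigma2 = rss / dof
    XtX_pinv = np.linalg.pinv(X.T @ X)
    se_all = np.sqrt(np.clip(np.diag(XtX_pinv) * sigma2, 0, None))
    nh = len(hyb_levels)
    offset = 1 + sum(b.shape[1] for b in base)
    b1 = np.full(nh, np.nan)
    s1 = np.full(nh, np.nan)
    b2 = np.full(nh, np.nan)
    s2 = np.full(nh, np.nan)
    pos = offset
    if included["psi"]:
        b1 = beta[pos : pos + nh]
        s1 = se_all[pos : pos + nh]
        pos += nh
    if included["rint"]:
        b2 = beta[pos : pos + nh]
        s2 = se_all[pos : pos + nh]
    ss_total = float(np.sum((y - y.mean()) ** 2))
    table = pd.DataFrame(
        {"hybrid": hyb_levels, "beta1": b1, "se1": s1, "beta2": b2, "se2": s2}
    )
    return Sensitivities(
        table=table,
        psi_included=included["psi"],
        rint_included=included["rint"],
        residual_gxe_proportion=rss / ss_total if ss_total > 0 else np.nan,
    )
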
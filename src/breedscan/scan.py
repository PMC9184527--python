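"""Genome scans for regions under selection (RUS).

Two complementary scans:

(i)  temporal_mlm_scan — per-SNP regression of year of release on allele
     counts with a genomic-relationship random effect (EMMA REML on the null
     model, EMMAX-style fixed variance ratio for the per-SNP GLS tests).
(ii) xtx_scan — a moment-based, covariance-standardized old-vs-recent
     allele-frequency differentiation statistic. This is a frequentist
     analogue of the Bayesian XtX: group-wise standardized frequency
     deviations are whitened by their genome-wide covariance (estimated on
     an LD-pruned SNP subset), so shared-structure differentiation is
     absorbed and outliers reflect locus-specific change.

Flagged SNPs are merged into RUS intervals within a window per chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, KinshipMatrix, RegionSet
from .mixedmodel import gls_scan, reml_fit

log = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Per-SNP scan statistics and flags."""

    table: pd.DataFrame  # snp_id, chrom, pos, and method columns
    method: str
    threshold: float

    @property
    def flagged(self) -> np.ndarray:
        return self.table["flag"].to_numpy(dtype=bool)


def temporal_mlm_scan(
    G: GenotypeMatrix,
    years: np.ndarray,
    K: KinshipMatrix,
    threshold: float = 3.5,
    ridge: float = 1e-8,
    exact: bool = False,
) -> ScanResult:
    """Kinship-controlled regression of year of release on allele counts.

    The null model year = mu + u + e with u ~ N(0, sg2*K) is fitted once by
    REML; each SNP is then tested by GLS with the null variance ratio held
    fixed (EMMAX approximation; `exact=True` refits the REML ratio per SNP).
    SNPs with -log10 p above `threshold` are flagged.
    """
    if not G.is_complete:
        raise ValueError("scan requires a complete genotype matrix")
    years = np.asarray(years, dtype=float)
    if G.n_hybrids < 20:
        raise ValueError("need at least 20 hybrids for the temporal scan")
    if np.ptp(years) == 0:
        raise ValueError("degenerate response: years are constant")
    X = np.ones((G.n_hybrids, 1))
    fit = reml_fit(years, X, K.values, ridge=ridge)
    markers_rot = fit.eigvecs.T @ G.counts
    beta, se, pval = gls_scan(fit, markers_rot)
    if exact:
        import dataclasses

        for j in range(G.n_snps):
            x = G.counts[:, j]
            if np.ptp(x) == 0:
                continue
            # per-SNP REML ratio from the full model, then the GLS test at
            # that ratio against the null fixed effects
            fj = reml_fit(years, np.column_stack([np.ones_like(x), x]), K.values, ridge=ridge)
            f0 = dataclasses.replace(fit, ratio=fj.ratio)
            bj, sj, pj = gls_scan(f0, markers_rot[:, j : j + 1])
            beta[j], se[j], pval[j] = bj[0], sj[0], pj[0]
    neglogp = -np.log10(pval)
    table = pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.chrom,
            "pos": G.pos,
            "beta": beta,
            "se": se,
            "neglog10p": neglogp,
            "flag": neglogp > threshold,
        }
    )
    log.info("temporal scan: %d/%d SNPs flagged at -log10 p > %.2f", int(table["flag"].sum()), G.n_snps, threshold)
    return ScanResult(table=table, method="temporal_mlm", threshold=threshold)


def xtx_scan(
    G: GenotypeMatrix,
    old_group: np.ndarray,
    recent_group: np.ndarray,
    pruned_snps: np.ndarray,
    quantile: float = 0.9995,
    ridge: float = 1e-6,
) -> ScanResult:
    """Covariance-standardized old-vs-recent differentiation scan.

    Per group g, z_g = (p_g - pi) / sqrt(pi*(1-pi)) with pi the pooled
    frequency; the 2x2 covariance of (z_old, z_recent) is estimated over the
    LD-pruned SNP subset and each SNP scores XtX = z' Omega^-1 z. The top
    (1 - quantile) fraction of informative SNPs is flagged.
    """
    if not G.is_complete:
        raise ValueError("scan requires a complete genotype matrix")
    old_group = np.asarray(old_group)
    recent_group = np.asarray(recent_group)
    if np.intersect1d(old_group, recent_group).size:
        raise ValueError("old and recent groups overlap")
    p_old = G.counts[old_group].mean(axis=0) / 2.0
    p_rec = G.counts[recent_group].mean(axis=0) / 2.0
    n_old, n_rec = len(old_group), len(recent_group)
    pi = (p_old * n_old + p_rec * n_rec) / (n_old + n_rec)
    informative = (pi > 0) & (pi < 1)
    denom = np.sqrt(np.where(informative, pi * (1 - pi), 1.0))
    z = np.stack([(p_old - pi) / denom, (p_rec - pi) / denom])  # (2, n_snps)
    z[:, ~informative] = 0.0
    pruned = np.asarray(pruned_snps)
    zp = z[:, pruned][:, informative[pruned]]
    if zp.shape[1] < 3:
        raise ValueError("too few informative pruned SNPs to estimate the covariance")
    omega = np.cov(zp)
    # with one old/recent pair the group deviations from the pooled frequency
    # are exactly proportional, so Omega is rank-1 by construction; the
    # Moore-Penrose inverse whitens on its support (ridge only if Omega ~ 0)
    if np.abs(omega).max() < ridge:
        omega = omega + ridge * np.eye(2)
    omega_inv = np.linalg.pinv(omega, rcond=1e-10, hermitian=True)
    xtx = np.einsum("in,ij,jn->n", z, omega_inv, z)
    xtx = np.where(informative, np.clip(xtx, 0.0, None), 0.0)
    n_inf = int(informative.sum())
    k = int(np.ceil((1.0 - quantile) * n_inf))
    flag = np.zeros(G.n_snps, dtype=bool)
    if k > 0 and n_inf > 0:
        inf_idx = np.flatnonzero(informative)
        order = inf_idx[np.argsort(xtx[inf_idx], kind="stable")[::-1]]
        flag[order[:k]] = True
    thresh = float(xtx[flag].min()) if flag.any() else float("inf")
    table = pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.chrom,
            "pos": G.pos,
            "xtx": xtx,
            "uninformative": ~informative,
            "flag": flag,
        }
    )
    log.info("xtx scan: %d/%d SNPs flagged above the %.4f quantile", int(flag.sum()), G.n_snps, quantile)
    return ScanResult(table=table, method="xtx", threshold=thresh)


def call_rus(
    scans: list[ScanResult],
    merge_window: int = 500_000,
    combine: str = "union",
) -> RegionSet:
    """Merge flagged SNPs from one or more scans into RUS intervals.

    combine='union' flags SNPs found by any method; 'intersection' requires
    all methods. Flagged positions become 1-bp intervals merged when within
    `merge_window` on the same chromosome; region names record the
    contributing methods.
    """
    if not scans:
        raise ValueError("no scans given")
    base = scans[0].table
    flags = np.stack([s.flagged for s in scans])
    if combine == "union":
        flagged = flags.any(axis=0)
    elif combine == "intersection":
        flagged = flags.all(axis=0)
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    if not flagged.any():
        return RegionSet.empty()
    chrom = base["chrom"].to_numpy(dtype=object)[flagged]
    pos = base["pos"].to_numpy(dtype=np.int64)[flagged]
    methods = np.array(
        [
            "+".join(s.method for s, f in zip(scans, flags[:, j]) if f)
            for j in np.flatnonzero(flagged)
        ],
        dtype=object,
    )
    order = np.lexsort((pos, chrom.astype(str)))
    chrom, pos, methods = chrom[order], pos[order], methods[order]
    records = []
    cur_chrom, cur_start, cur_end = chrom[0], int(pos[0]), int(pos[0]) + 1
    cur_methods = set(methods[0].split("+"))
    for c, p, m in zip(chrom[1:], pos[1:], methods[1:]):
        if str(c) == str(cur_chrom) and int(p) <= cur_end - 1 + merge_window:
            cur_end = int(p) + 1
            cur_methods |= set(m.split("+"))
        else:
            records.append((cur_chrom, cur_start, cur_end, "+".join(sorted(cur_methods))))
            cur_chrom, cur_start, cur_end = c, int(p), int(p) + 1
            cur_methods = set(m.split("+"))
    records.append((cur_chrom, cur_start, cur_end, "+".join(sorted(cur_methods))))
    named = [
        (c, s, e, f"rus_{i + 1}|{m}") for i, (c, s, e, m) in enumerate(records)
    ]
    return RegionSet.from_records(named)
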
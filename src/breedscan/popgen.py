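"""Genotype QC, imputation, relationship matrices, diversity, PCA, LD pruning."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix, KinshipMatrix

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int
    n_imputed: int


def allele_freq(counts: np.ndarray) -> np.ndarray:
    """Alternative-allele frequency per SNP, ignoring missing calls."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(counts, axis=0) / 2.0


def qc_and_impute(
    G: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.20
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with MAF < maf_min (strict) or missing fraction > max_missing
    (strict), then impute remaining missing calls with the per-SNP modal genotype.

    MAF is computed over non-missing calls. Ties in the modal genotype are
    broken toward the smaller allele count.
    """
    if G.n_snps == 0 or G.n_hybrids == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = np.isnan(G.counts).mean(axis=0)
    p = allele_freq(G.counts)
    maf = np.minimum(p, 1.0 - p)
    fail_missing = miss_frac > max_missing
    # SNPs that are entirely missing have undefined MAF; drop them via the
    # missingness filter and never via MAF
    maf = np.where(np.isnan(maf), 1.0, maf)
    fail_maf = maf < maf_min
    keep = ~(fail_maf | fail_missing)
    report = QCReport(
        n_input=G.n_snps,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_missing.sum()),
        n_retained=int(keep.sum()),
        n_imputed=0,
    )
    if report.n_retained == 0:
        raise ValueError(
            "no SNPs survived QC "
            f"(MAF filter removed {report.n_removed_maf}, "
            f"missingness filter removed {report.n_removed_missing})"
        )
    G2 = G.take_snps(np.flatnonzero(keep))
    counts = G2.counts.copy()
    nan_mask = np.isnan(counts)
    if nan_mask.any():
        # modal genotype per SNP over {0,1,2}; ties -> smaller count
        tallies = np.stack([(counts == g).sum(axis=0) for g in (0.0, 1.0, 2.0)])
        modal = np.argmax(tallies, axis=0).astype(float)
        counts[nan_mask] = np.broadcast_to(modal, counts.shape)[nan_mask]
        report.n_imputed = int(nan_mask.sum())
    G2.counts = counts
    log.info(
        "QC: %d SNPs in, %d removed (MAF), %d removed (missingness), %d retained, %d calls imputed",
        report.n_input,
        report.n_removed_maf,
        report.n_removed_missing,
        report.n_retained,
        report.n_imputed,
    )
    return G2, report


def grm(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Columns centered by 2*p_hat; cross-product scaled by sum(2*p*(1-p)) over
    polymorphic SNPs. Monomorphic SNPs contribute nothing and are excluded
    from the denominator with a warning.
    """
    if not G.is_complete:
        raise ValueError("GRM requires a complete matrix; run qc_and_impute first")
    p = G.counts.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic SNPs excluded from GRM denominator",
            stacklevel=2,
        )
    Z = G.counts - 2.0 * p
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    if denom == 0:
        raise ValueError("all SNPs monomorphic; GRM undefined")
    values = (Z @ Z.T) / denom
    return KinshipMatrix(values=values, hybrid_ids=G.hybrid_ids, method="vanraden1")


def ibs_matrix(G: GenotypeMatrix) -> KinshipMatrix:
    """Pairwise identity-by-state: mean over SNPs of (2 - |c_i - c_j|) / 2."""
    if not G.is_complete:
        raise ValueError("IBS requires a complete matrix; impute first")
    c = G.counts
    a0 = (c == 0).astype(float)
    a1 = (c == 1).astype(float)
    a2 = (c == 2).astype(float)
    # sum over SNPs of |c_i - c_j| decomposed by genotype-class cross products
    abs_diff = (a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T) + 2.0 * (
        a0 @ a2.T + a2 @ a0.T
    )
    values = 1.0 - abs_diff / (2.0 * G.n_snps)
    values = (values + values.T) / 2.0
    return KinshipMatrix(values=values, hybrid_ids=G.hybrid_ids, method="ibs")


def nei_diversity(G: GenotypeMatrix, groups: dict[str, str] | np.ndarray) -> dict[str, float]:
    """Nei's expected heterozygosity per hybrid group.

    He(group) = mean over SNPs of 2*p*(1-p) * 2n/(2n-1), with p and the
    small-sample correction computed within the group over non-missing calls.
    """
    if isinstance(groups, dict):
        labels = np.array([groups[str(h)] for h in G.hybrid_ids], dtype=object)
    else:
        labels = np.asarray(groups, dtype=object)
        if len(labels) != G.n_hybrids:
            raise ValueError("group labels length mismatch")
    out: dict[str, float] = {}
    for g in sorted(set(labels.astype(str))):
        sub = G.counts[labels.astype(str) == g]
        n_obs = (~np.isnan(sub)).sum(axis=0)
        ok = n_obs > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            p = np.nanmean(sub, axis=0) / 2.0
        he = 2.0 * p[ok] * (1.0 - p[ok])
        corr = (2.0 * n_obs[ok]) / (2.0 * n_obs[ok] - 1.0)
        out[g] = float(np.mean(he * corr))
    return out


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance: np.ndarray
    r2_pc1_year: float


def pca_year(G: GenotypeMatrix, years: np.ndarray, scale: bool = False) -> PCAResult:
    """Genotype PCA with the leading axis regressed on year of release.

    Columns are centered by the mean allele count (optionally scaled by
    sqrt(2*p*(1-p))); scores come from the SVD of the centered matrix. PC1's
    sign is fixed so it correlates positively with year; other components are
    signed so their largest-magnitude loading is positive.
    """
    if not G.is_complete:
        raise ValueError("PCA requires a complete matrix")
    if G.n_hybrids < 3:
        raise ValueError("PCA requires at least 3 hybrids")
    years = np.asarray(years, dtype=float)
    X = G.counts - G.counts.mean(axis=0)
    if scale:
        p = G.counts.mean(axis=0) / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
        ok = sd > 0
        X = X[:, ok] / sd[ok]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    # deterministic sign convention
    for j in range(scores.shape[1]):
        if j == 0:
            r = np.corrcoef(scores[:, 0], years)[0, 1]
            if np.isfinite(r) and r < 0:
                scores[:, 0] *= -1
        else:
            i = np.argmax(np.abs(Vt[j]))
            if Vt[j, i] < 0:
                scores[:, j] *= -1
    ev = S**2 / (G.n_hybrids - 1)
    lr = stats.linregress(years, scores[:, 0])
    return PCAResult(scores=scores, explained_variance=ev, r2_pc1_year=float(lr.rvalue**2))


def ld_prune(
    G: GenotypeMatrix,
    window_snps: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
    target_n: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained SNP indices.

    Within each window (per chromosome, sliding by `step`), for each pair of
    retained SNPs with squared correlation > r2_max the later SNP is dropped.
    If target_n is given, a seeded uniform subsample of the pruned set is
    returned.
    """
    if not G.is_complete:
        raise ValueError("LD pruning requires a complete matrix")
    keep = np.ones(G.n_snps, dtype=bool)
    for ch in dict.fromkeys(G.chrom.astype(str)):
        idx = np.flatnonzero(G.chrom.astype(str) == ch)
        idx = idx[np.argsort(G.pos[idx], kind="stable")]
        m = len(idx)
        start = 0
        while start < m:
            window = idx[start : start + window_snps]
            live = [j for j in window if keep[j]]
            if len(live) > 1:
                sub = G.counts[:, live]
                sd = sub.std(axis=0)
                ok = sd > 0
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(sub, rowvar=False)
                r2 = np.square(np.nan_to_num(r))
                for a in range(len(live)):
                    if not keep[live[a]] or not ok[a]:
                        continue
                    for b in range(a + 1, len(live)):
                        if keep[live[b]] and ok[b] and r2[a, b] > r2_max:
                            keep[live[b]] = False
            if start + window_snps >= m:
                break
            start += step
    retained = np.flatnonzero(keep)
    if target_n is not None and target_n < len(retained):
        rng = np.random.default_rng(seed)
        retained = np.sort(rng.choice(retained, size=target_n, replace=False))
    return retained
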
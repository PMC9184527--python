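"""Permutation enrichment of RUS-QTL colocalization.

The null keeps the RUS fixed and redraws, many times, a set of random
regions matching the QTL set in number and physical lengths; the observed
overlap count is compared with the null distribution using the permutation
p-value (b+1)/(m+1), alongside a chi-square statistic against the null-mean
expected count. Random regions may overlap one another and the original QTL
positions (no exclusion is imposed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GenomeSpec, GenotypeMatrix, RegionSet

log = logging.getLogger(__name__)


# ------------------------------------------------------------ interval utils


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [], []
    for a, b in zip(s, e):
        if ms and a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.array(ms, dtype=np.int64), np.array(me, dtype=np.int64)


def _merged_by_chrom(regions: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for ch in dict.fromkeys(regions.chrom.astype(str)):
        mask = regions.chrom.astype(str) == ch
        out[ch] = _merge_intervals(regions.start[mask], regions.end[mask])
    return out


def _overlaps_fixed(merged, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Boolean per query region: intersects >= 1 merged fixed interval."""
    hit = np.zeros(len(starts), dtype=bool)
    for ch, (ms, me) in merged.items():
        mask = chroms == ch
        if not mask.any() or len(ms) == 0:
            continue
        s, e = starts[mask], ends[mask]
        i = np.searchsorted(ms, e, side="left")  # count of intervals starting before e
        ok = i > 0
        sub = np.zeros(mask.sum(), dtype=bool)
        sub[ok] = me[i[ok] - 1] > s[ok]
        hit[mask] = sub
    return hit


def overlap_count(fixed: RegionSet, query: RegionSet) -> int:
    """Number of query regions intersecting at least one fixed region
    (half-open semantics; abutting regions do not overlap)."""
    if len(fixed) == 0 or len(query) == 0:
        return 0
    merged = _merged_by_chrom(fixed)
    return int(
        _overlaps_fixed(merged, query.chrom.astype(str), query.start, query.end).sum()
    )


# --------------------------------------------------------------- null model


def _placement_weights(lengths: np.ndarray, genome: GenomeSpec):
    """Per template region: candidate chromosomes and their valid-start counts."""
    chroms = np.array(genome.chroms, dtype=object)
    chrom_len = np.array([genome.lengths[c] for c in chroms], dtype=np.int64)
    valid = chrom_len[None, :] - lengths[:, None] + 1  # (n_regions, n_chroms)
    valid = np.clip(valid, 0, None)
    bad = valid.sum(axis=1) == 0
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} template region(s) longer than every chromosome"
        )
    return chroms, chrom_len, valid


def _sample_placements(lengths: np.ndarray, genome: GenomeSpec, rng, m: int):
    """Sample m placements of each template length.

    Chromosome chosen with probability proportional to (length - l + 1);
    start uniform over valid positions. Returns (chrom_idx, starts) arrays of
    shape (m, n_regions).
    """
    chroms, chrom_len, valid = _placement_weights(lengths, genome)
    nq = len(lengths)
    probs = valid / valid.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((m, nq))
    chrom_idx = np.empty((m, nq), dtype=np.int64)
    for q in range(nq):
        chrom_idx[:, q] = np.searchsorted(cum[q], u[:, q], side="right")
    chrom_idx = np.clip(chrom_idx, 0, len(chroms) - 1)
    nvalid = valid[np.arange(nq)[None, :], chrom_idx]
    starts = (rng.random((m, nq)) * nvalid).astype(np.int64)
    return chrom_idx, starts


def sample_random_regions(template: RegionSet, genome: GenomeSpec, seed: int | None = None) -> RegionSet:
    """One random region per template region, preserving its length."""
    rng = np.random.default_rng(seed)
    lengths = template.lengths()
    chroms = np.array(genome.chroms, dtype=object)
    chrom_idx, starts = _sample_placements(lengths, genome, rng, 1)
    recs = [
        (chroms[chrom_idx[0, q]], int(starts[0, q]), int(starts[0, q] + lengths[q]), f"rand_{q + 1}")
        for q in range(len(template))
    ]
    return RegionSet.from_records(recs)


# ----------------------------------------------------------- enrichment test


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    null_counts: np.ndarray
    p_perm: float
    chi2: float
    p_chi2: float
    m: int
    seed: int | None
    alternative: str = "enrichment"
    flag: str = ""


def _null_counts_flat(
    rus: RegionSet, template_lengths: np.ndarray, genome: GenomeSpec, m: int, rng
) -> np.ndarray:
    merged = _merged_by_chrom(rus)
    chroms = [str(c) for c in genome.chroms]
    chrom_idx, starts = _sample_placements(template_lengths, genome, rng, m)
    ends = starts + template_lengths[None, :]
    hit = np.zeros(chrom_idx.shape, dtype=bool)
    for ci, ch in enumerate(chroms):
        if ch not in merged or len(merged[ch][0]) == 0:
            continue
        ms, me = merged[ch]
        mask = chrom_idx == ci
        if not mask.any():
            continue
        s = starts[mask]
        e = ends[mask]
        i = np.searchsorted(ms, e, side="left")
        ok = i > 0
        h = np.zeros(len(s), dtype=bool)
        h[ok] = me[i[ok] - 1] > s[ok]
        hit[mask] = h
    return hit.sum(axis=1).astype(np.int64)


def enrichment_test(
    rus: RegionSet,
    qtls: RegionSet,
    genome: GenomeSpec,
    m: int = 100_000,
    seed: int | None = None,
    alternative: str = "enrichment",
) -> EnrichmentResult:
    """Permutation test of RUS-QTL colocalization enrichment.

    observed = number of QTLs overlapping >= 1 RUS; the null redraws m
    number/length-matched random region sets. p = (b+1)/(m+1) with b the
    count of null values >= observed (<= for alternative='depletion'). A
    chi-square statistic against the null-mean expected count is reported
    alongside; the permutation p is primary.
    """
    if m < 100:
        log.warning("m = %d gives coarse p-value resolution", m)
    if len(rus) == 0 or len(qtls) == 0:
        return EnrichmentResult(
            observed=0,
            null_mean=0.0,
            null_sd=0.0,
            null_counts=np.zeros(0, dtype=np.int64),
            p_perm=1.0,
            chi2=0.0,
            p_chi2=1.0,
            m=m,
            seed=seed,
            alternative=alternative,
            flag="empty-input",
        )
    rng = np.random.default_rng(seed)
    observed = overlap_count(rus, qtls)
    null_counts = _null_counts_flat(rus, qtls.lengths(), genome, m, rng)
    if alternative == "enrichment":
        b = int((null_counts >= observed).sum())
    elif alternative == "depletion":
        b = int((null_counts <= observed).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p_perm = (b + 1) / (m + 1)
    mean = float(null_counts.mean())
    if mean > 0:
        chi2 = (observed - mean) ** 2 / mean
        p_chi2 = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p_chi2 = float("inf") if observed > 0 else 0.0, 0.0 if observed > 0 else 1.0
    return EnrichmentResult(
        observed=observed,
        null_mean=mean,
        null_sd=float(null_counts.std()),
        null_counts=null_counts,
        p_perm=float(p_perm),
        chi2=float(chi2),
        p_chi2=p_chi2,
        m=m,
        seed=seed,
        alternative=alternative,
    )


# ------------------------------------------------- allele-frequency contrast


@dataclass
class FreqShiftResult:
    statistic: float
    null_quantile_95: float
    p_perm: float
    n_snps_in: int
    m: int


def freq_shift_contrast(
    G: GenotypeMatrix,
    old_group: np.ndarray,
    recent_group: np.ndarray,
    qtls: RegionSet,
    genome: GenomeSpec,
    m: int = 10_000,
    seed: int | None = None,
) -> FreqShiftResult:
    """Mean |recent - old| allele-frequency difference inside the QTL space,
    against a null of number/length-matched random regions.

    SNPs are counted once inside the union of the region set; region sets
    whose union contains no SNPs contribute a null value of 0.
    """
    if not G.is_complete:
        raise ValueError("frequency contrast requires a complete matrix")
    p_old = G.counts[np.asarray(old_group)].mean(axis=0) / 2.0
    p_rec = G.counts[np.asarray(recent_group)].mean(axis=0) / 2.0
    adp = np.abs(p_rec - p_old)

    # per-chromosome sorted positions with prefix sums of |dp|
    chrom_data = {}
    for ch in dict.fromkeys(G.chrom.astype(str)):
        mask = G.chrom.astype(str) == ch
        order = np.argsort(G.pos[mask], kind="stable")
        pos = G.pos[mask][order]
        vals = adp[mask][order]
        chrom_data[ch] = (pos, np.concatenate([[0.0], np.cumsum(vals)]))

    def region_stat(chroms, starts, ends):
        total, count = 0.0, 0
        by = {}
        for c, s, e in zip(chroms, starts, ends):
            by.setdefault(str(c), []).append((int(s), int(e)))
        for ch, ivals in by.items():
            if ch not in chrom_data:
                continue
            pos, csum = chrom_data[ch]
            ms, me = _merge_intervals(
                np.array([i[0] for i in ivals], dtype=np.int64),
                np.array([i[1] for i in ivals], dtype=np.int64),
            )
            lo = np.searchsorted(pos, ms, side="left")
            hi = np.searchsorted(pos, me, side="left")
            total += float(np.sum(csum[hi] - csum[lo]))
            count += int(np.sum(hi - lo))
        return total, count

    obs_total, obs_count = region_stat(qtls.chrom, qtls.start, qtls.end)
    statistic = obs_total / obs_count if obs_count else float("nan")
    rng = np.random.default_rng(seed)
    lengths = qtls.lengths()
    chroms = np.array(genome.chroms, dtype=object)
    chrom_idx, starts = _sample_placements(lengths, genome, rng, m)
    null = np.zeros(m)
    for it in range(m):
        t, c = region_stat(chroms[chrom_idx[it]], starts[it], starts[it] + lengths)
        null[it] = t / c if c else 0.0
    if obs_count == 0:
        p = 1.0
    else:
        b = int((null >= statistic).sum())
        p = (b + 1) / (m + 1)
    return FreqShiftResult(
        statistic=float(statistic),
        null_quantile_95=float(np.quantile(null, 0.95)),
        p_perm=float(p),
        n_snps_in=obs_count,
        m=m,
    )
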
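"""Readers and writers for the standard formats the pipeline touches.

VCF positions (1-based) are decremented to the internal 0-based half-open
convention on read and incremented back on write. Malformed rows raise with
the offending line number; skipped-record counts are logged and returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from .containers import GenomeSpec, GenotypeMatrix, RegionSet

log = logging.getLogger(__name__)


@dataclass
class ParseReport:
    n_records: int = 0
    n_retained: int = 0
    skipped: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------- genotypes


def read_genotypes(path, format: str = "vcf") -> tuple[GenotypeMatrix, ParseReport]:
    """Read genotypes from VCF or an additive-coded matrix.

    Allele counts are coded 0/1/2 as copies of the alternative allele
    relative to the reference; multiallelic VCF records are skipped with a
    logged count; missing calls become NaN.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "additive-matrix":
        return _read_additive_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> tuple[GenotypeMatrix, ParseReport]:
    report = ParseReport()
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vf.header.samples)
    rows, snp_ids, chroms, poss, refs, alts = [], [], [], [], [], []
    for rec in vf:
        report.n_records += 1
        if rec.alts is None or len(rec.alts) != 1:
            report.skipped["multiallelic"] = report.skipped.get("multiallelic", 0) + 1
            continue
        counts = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            counts[i] = float(sum(1 for a in gt if a == 1))
        rows.append(counts)
        snp_ids.append(rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos - 1)  # VCF is 1-based
        refs.append(rec.ref)
        alts.append(rec.alts[0])
    vf.close()
    report.n_retained = len(rows)
    if report.skipped:
        log.info("VCF %s: skipped records %s", path, report.skipped)
    if not rows:
        raise ValueError(f"no biallelic markers retained from {path}")
    G = GenotypeMatrix(
        counts=np.array(rows).T,
        hybrid_ids=np.array(samples, dtype=object),
        snp_ids=np.array(snp_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
    )
    return G, report


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Write the matrix as an unphased GT-only VCF 4.2 text file."""
    chrom_order = list(dict.fromkeys(G.chrom.astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedscan\n")
        for ch in chrom_order:
            m = G.pos[G.chrom.astype(str) == ch].max() + 1
            fh.write(f"##contig=<ID={ch},length={int(m)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(h) for h in G.hybrid_ids)
            + "\n"
        )
        order = np.lexsort((G.pos, np.array([chrom_order.index(c) for c in G.chrom.astype(str)])))
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in order:
            col = G.counts[:, j]
            gts = "\t".join("./." if np.isnan(c) else gt_map[c] for c in col)
            fh.write(
                f"{G.chrom[j]}\t{int(G.pos[j]) + 1}\t{G.snp_ids[j]}\t{G.ref[j]}\t{G.alt[j]}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_genotypes_matrix(G: GenotypeMatrix, path) -> None:
    """Tab-separated additive matrix: marker map columns then one column per hybrid."""
    df = G.marker_map.copy()
    for i, h in enumerate(G.hybrid_ids):
        col = G.counts[i]
        df[str(h)] = [("NA" if np.isnan(c) else str(int(c))) for c in col]
    df.to_csv(path, sep="\t", index=False)


def _read_additive_matrix(path) -> tuple[GenotypeMatrix, ParseReport]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = set(needed) - set(df.columns)
    if missing:
        raise ValueError(f"additive matrix {path} missing columns {sorted(missing)}")
    hybrid_cols = [c for c in df.columns if c not in needed]
    if not hybrid_cols or df.empty:
        raise ValueError(f"no genotypes in {path}")
    counts = (
        df[hybrid_cols].replace("NA", np.nan).apply(pd.to_numeric, errors="raise").to_numpy().T
    )
    G = GenotypeMatrix(
        counts=counts,
        hybrid_ids=np.array(hybrid_cols, dtype=object),
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
    )
    report = ParseReport(n_records=G.n_snps, n_retained=G.n_snps)
    return G, report


# ------------------------------------------------------------------ regions


def read_regions(path) -> RegionSet:
    """Read a BED3/BED4 file (0-based half-open, preserved verbatim)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            name = parts[3] if len(parts) >= 4 else f"region_{len(records) + 1}"
            records.append((chrom, start, end, name))
    return RegionSet.from_records(records)


def write_regions(regions: RegionSet, path) -> None:
    """Write BED4, sorted by chromosome then start."""
    s = regions.sorted()
    with open(path, "w") as fh:
        for i in range(len(s)):
            fh.write(f"{s.chrom[i]}\t{s.start[i]}\t{s.end[i]}\t{s.name[i]}\n")


# ------------------------------------------------------------------- genome


def read_genome(path) -> GenomeSpec:
    """Two-column chrom-sizes text file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom length'")
            chrom, length = parts[0], int(parts[1])
            if chrom in lengths:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom}")
            lengths[chrom] = length
    return GenomeSpec(lengths)


def write_genome(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for ch, ln in genome.lengths.items():
            fh.write(f"{ch}\t{ln}\n")


# ------------------------------------------------------------------- config


def read_config(path) -> dict:
    """YAML configuration file shared by the CLI subcommands."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
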
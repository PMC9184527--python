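"""Core in-memory containers shared by all pipeline stages.

Coordinate convention: all genomic intervals and SNP positions are 0-based,
half-open. VCF input (1-based) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TEMPERATURE_CLASSES = ("cool", "warm", "hot")
WATER_CLASSES = ("WW", "WD")


@dataclass(frozen=True)
class ScenarioLabel:
    """One of the six environmental scenarios: temperature class x water class."""

    temperature: str
    water: str

    def __post_init__(self):
        if self.temperature not in TEMPERATURE_CLASSES:
            raise ValueError(f"unknown temperature class {self.temperature!r}")
        if self.water not in WATER_CLASSES:
            raise ValueError(f"unknown water class {self.water!r}")

    def __str__(self) -> str:
        return f"{self.temperature}-{self.water}"

    @classmethod
    def parse(cls, s: str) -> "ScenarioLabel":
        temp, water = s.split("-")
        return cls(temp, water)


ALL_SCENARIOS = tuple(
    ScenarioLabel(t, w) for t in TEMPERATURE_CLASSES for w in WATER_CLASSES
)

PHASES = ("vegetative", "flowering", "grain_filling")


@dataclass
class EnvRecord:
    """Phase-wise environmental covariates for one field experiment.

    light_* are cumulated intercepted light (MJ m^-2) per phenological phase;
    tmin_*/tmax_* are mean daily minimum/maximum temperatures (deg C); psi is
    the mean soil water potential (MPa) over the vegetative+flowering phases.
    """

    experiment: str
    light_vegetative: float
    light_flowering: float
    light_grain_filling: float
    tmin_vegetative: float
    tmin_flowering: float
    tmin_grain_filling: float
    tmax_vegetative: float
    tmax_flowering: float
    tmax_grain_filling: float
    psi: float
    scenario_true: ScenarioLabel | None = None

    COVARIATE_NAMES = (
        "light_vegetative",
        "light_flowering",
        "light_grain_filling",
        "tmin_vegetative",
        "tmin_flowering",
        "tmin_grain_filling",
        "tmax_vegetative",
        "tmax_flowering",
        "tmax_grain_filling",
    )

    def __post_init__(self):
        for phase in PHASES:
            if getattr(self, f"tmin_{phase}") > getattr(self, f"tmax_{phase}"):
                raise ValueError(f"Tmin > Tmax in phase {phase} of {self.experiment}")
            if getattr(self, f"light_{phase}") < 0:
                raise ValueError(f"negative light in phase {phase} of {self.experiment}")
        if self.psi > 0:
            raise ValueError(f"positive soil water potential in {self.experiment}")

    def covariates(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.COVARIATE_NAMES], dtype=float)

    def mean_tmax(self) -> float:
        return float(np.mean([getattr(self, f"tmax_{p}") for p in PHASES]))


def env_records_to_frame(envs: Iterable[EnvRecord]) -> pd.DataFrame:
    rows = []
    for e in envs:
        row = {"experiment": e.experiment, **{n: getattr(e, n) for n in EnvRecord.COVARIATE_NAMES}}
        row["psi"] = e.psi
        row["scenario_true"] = str(e.scenario_true) if e.scenario_true else ""
        rows.append(row)
    return pd.DataFrame(rows)


def env_records_from_frame(df: pd.DataFrame) -> list[EnvRecord]:
    out = []
    for _, r in df.iterrows():
        truth = None
        if "scenario_true" in df.columns and isinstance(r["scenario_true"], str) and r["scenario_true"]:
            truth = ScenarioLabel.parse(r["scenario_true"])
        out.append(
            EnvRecord(
                experiment=str(r["experiment"]),
                psi=float(r["psi"]),
                scenario_true=truth,
                **{n: float(r[n]) for n in EnvRecord.COVARIATE_NAMES},
            )
        )
    return out


@dataclass
class GenotypeMatrix:
    """Hybrids x SNPs additive allele counts with a marker map.

    counts holds the number of copies of the alternative allele (0, 1 or 2)
    as floats, with np.nan for missing calls; `chrom`/`pos` give each SNP's
    physical position (0-based).
    """

    counts: np.ndarray
    hybrid_ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.hybrid_ids = np.asarray(self.hybrid_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n, m = self.counts.shape
        if not (
            len(self.hybrid_ids) == n
            and len(self.snp_ids) == m
            and len(self.chrom) == m
            and len(self.pos) == m
            and len(self.ref) == m
            and len(self.alt) == m
        ):
            raise ValueError("genotype matrix dimensions inconsistent with marker map")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("allele counts must be 0, 1, 2 or missing")

    @property
    def n_hybrids(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.counts).any()

    @property
    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            counts=self.counts[:, idx],
            hybrid_ids=self.hybrid_ids,
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def take_hybrids(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            counts=self.counts[idx, :],
            hybrid_ids=self.hybrid_ids[idx],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
        )


@dataclass
class PanelMetadata:
    """Hybrid identifiers and their years of market release."""

    hybrid_ids: np.ndarray
    years: np.ndarray

    def __post_init__(self):
        self.hybrid_ids = np.asarray(self.hybrid_ids, dtype=object)
        self.years = np.asarray(self.years, dtype=float)
        if len(self.hybrid_ids) != len(self.years):
            raise ValueError("hybrid id / year length mismatch")

    def __len__(self) -> int:
        return len(self.hybrid_ids)

    def era_groups(self, n_group: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the n oldest and n most recent hybrids.

        Stable sort on year; ties broken by lexicographic hybrid id.
        """
        if 2 * n_group > len(self):
            raise ValueError("group size exceeds half the panel")
        order = np.lexsort((self.hybrid_ids.astype(str), self.years))
        return order[:n_group], order[-n_group:][::-1]

    def terciles(self) -> np.ndarray:
        """Old/intermediate/recent group label per hybrid (by year terciles)."""
        order = np.lexsort((self.hybrid_ids.astype(str), self.years))
        labels = np.empty(len(self), dtype=object)
        n = len(self)
        cuts = [n // 3, 2 * n // 3]
        labels[order[: cuts[0]]] = "old"
        labels[order[cuts[0] : cuts[1]]] = "intermediate"
        labels[order[cuts[1] :]] = "recent"
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hybrid": self.hybrid_ids, "year": self.years})


@dataclass
class KinshipMatrix:
    """Hybrids x hybrids relationship matrix (GRM or IBS)."""

    values: np.ndarray
    hybrid_ids: np.ndarray
    method: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.hybrid_ids = np.asarray(self.hybrid_ids, dtype=object)
        n = len(self.hybrid_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix not square / id mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")


@dataclass
class RegionSet:
    """A named set of genomic intervals in 0-based half-open coordinates."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: np.ndarray

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.name = np.asarray(self.name, dtype=object)
        k = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.name) == k):
            raise ValueError("region set field lengths differ")
        if k and not (self.start < self.end).all():
            raise ValueError("regions must satisfy start < end")
        if k and not (self.start >= 0).all():
            raise ValueError("regions must satisfy start >= 0")
        if len(set(self.name)) != k:
            raise ValueError("region names must be unique")

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "RegionSet":
        recs = list(records)
        if not recs:
            return cls.empty()
        named = []
        for i, r in enumerate(recs):
            if len(r) >= 4:
                named.append(tuple(r[:4]))
            else:
                named.append((r[0], r[1], r[2], f"region_{i + 1}"))
        c, s, e, n = zip(*named)
        return cls(np.array(c, dtype=object), np.array(s), np.array(e), np.array(n, dtype=object))

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(
            np.array([], dtype=object),
            np.array([], dtype=np.int64),
            np.array([], dtype=np.int64),
            np.array([], dtype=object),
        )

    def __len__(self) -> int:
        return len(self.chrom)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return (
            len(self) == len(other)
            and (self.chrom == other.chrom).all()
            and (self.start == other.start).all()
            and (self.end == other.end).all()
            and (self.name == other.name).all()
        )

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def sorted(self) -> "RegionSet":
        order = np.lexsort((self.start, self.chrom.astype(str)))
        return RegionSet(self.chrom[order], self.start[order], self.end[order], self.name[order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "name": self.name}
        )


@dataclass
class GenomeSpec:
    """Ordered chromosome id -> length (bp) map."""

    lengths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.lengths = dict(self.lengths)
        if any(v <= 0 for v in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __len__(self) -> int:
        return len(self.lengths)

    def total_length(self) -> int:
        return int(sum(self.lengths.values()))


@dataclass
class EffectTable:
    """Per-QTL scenario-specific allelic effects on yield (t ha^-1).

    `table` has one row per QTL with columns: qtl, marker, qtl_class
    ('adaptive' or 'constitutive'), favorable_allele, and one effect column
    per scenario label (e.g. 'cool-WW'). The favorable allele is the allele
    with positive yield effect in the cool/well-watered scenario.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"qtl", "marker", "qtl_class", "favorable_allele"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"effect table missing columns: {sorted(missing)}")
        for s in ALL_SCENARIOS:
            if str(s) not in self.table.columns:
                raise ValueError(f"effect table missing scenario column {s}")
        if self.table["qtl"].duplicated().any():
            raise ValueError("duplicate QTL names in effect table")
        for s in ALL_SCENARIOS:
            if not np.isfinite(self.table[str(s)]).all():
                raise ValueError("non-finite allelic effect")

    @property
    def qtls(self) -> list[str]:
        return list(self.table["qtl"])

    def effect(self, qtl: str, scenario: ScenarioLabel) -> float:
        row = self.table.loc[self.table["qtl"] == qtl]
        if row.empty:
            raise KeyError(f"unknown QTL {qtl!r}")
        col = str(scenario)
        return float(row.iloc[0][col])

    def row(self, qtl: str) -> pd.Series:
        row = self.table.loc[self.table["qtl"] == qtl]
        if row.empty:
            raise KeyError(f"unknown QTL {qtl!r}")
        return row.iloc[0]


TRIAL_COLUMNS = (
    "hybrid",
    "experiment",
    "scenario",
    "year",
    "grain_number",
    "yield_kg_ha",
    "veg",
    "silk",
    "rh_pad",
    "psi",
    "r_int",
)


def validate_trial(trial: pd.DataFrame) -> pd.DataFrame:
    """Check a TrialTable DataFrame against its invariants."""
    missing = set(TRIAL_COLUMNS) - set(trial.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if trial.duplicated(subset=["hybrid", "experiment"]).any():
        raise ValueError("duplicate (hybrid, experiment) records")
    if (trial["grain_number"] < 0).any():
        raise ValueError("negative grain number")
    if ((trial["rh_pad"] < 0) | (trial["rh_pad"] > 1)).any():
        raise ValueError("rh_pad outside [0, 1]")
    return trial
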
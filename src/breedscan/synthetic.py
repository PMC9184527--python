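"""Synthetic breeding panel, environments and multi-environment trials.

The generator emulates a 65-year European maize genetic-progress panel:
~60 hybrids released 1950-2015 genotyped at tens of thousands of SNPs on 10
chromosomes, with population structure whose leading PCA axis tracks year of
release (a two-ancestry mixture whose mixing weight is logistic in year), a
minority of loci with logit-linear year-trending allele frequencies, field
experiments spread over six environmental scenarios (cool/warm/hot x
WW/WD), grain number and yield driven by a year trend mediated by phenology
(vegetative duration), reproductive development (silk number) and plant
architecture (leaf-area height index -> ear-layer light), and QTLs whose
allelic effects are either scenario-stable or sign-flipping.

Every operation is bit-reproducible from `SimConfig.seed`; each stage uses
an independent child RNG stream so stages can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import (
    ALL_SCENARIOS,
    EffectTable,
    EnvRecord,
    GenotypeMatrix,
    PanelMetadata,
    ScenarioLabel,
    validate_trial,
)

# Approximate maize chromosome lengths (bp), 10 chromosomes.
MAIZE_CHROM_LENGTHS = {
    "1": 301_000_000,
    "2": 237_000_000,
    "3": 232_000_000,
    "4": 242_000_000,
    "5": 218_000_000,
    "6": 169_000_000,
    "7": 177_000_000,
    "8": 175_000_000,
    "9": 157_000_000,
    "10": 150_000_000,
}

# Default experiments per scenario in the simulated multi-site network
# (26 experiments, most in well-watered conditions, as in a European trial
# network spanning a temperature transect).
DEFAULT_EXPERIMENTS_PER_SCENARIO = {
    "cool-WW": 6,
    "cool-WD": 2,
    "warm-WW": 6,
    "warm-WD": 4,
    "hot-WW": 4,
    "hot-WD": 4,
}

# Scenario means for phase-wise Tmin/Tmax (deg C): cool, warm, hot.
SCENARIO_TEMPS = {"cool": (15.0, 25.0), "warm": (17.0, 28.0), "hot": (18.0, 30.0)}

# Grain-number effects (per m^2) of the six scenarios relative to the panel
# mean; strong yield contrasts between favourable and stressed scenarios.
DEFAULT_SCENARIO_GN_EFFECTS = {
    "cool-WW": 900.0,
    "cool-WD": -100.0,
    "warm-WW": 300.0,
    "warm-WD": -500.0,
    "hot-WW": 0.0,
    "hot-WD": -1000.0,
}


def default_effect_table(
    const_markers: Sequence[str] = ("qc1", "qc2", "qc3"),
    adapt_markers: Sequence[str] = ("qa1", "qa2", "qa3"),
    favorable_alleles: Mapping[str, str] | None = None,
) -> EffectTable:
    """Ground-truth QTL effect table (t ha^-1 per favorable-allele copy).

    Three constitutive QTLs with scenario-stable positive effects
    (0.10-0.24 t/ha) and three adaptive QTLs whose effects flip sign between
    well-watered/cool and water-deficit/hot scenarios (-0.16..+0.17 t/ha).
    """
    cols = [str(s) for s in ALL_SCENARIOS]  # cool-WW, cool-WD, warm-WW, ...
    rows = [
        # qtl, class, effects by (cool-WW, cool-WD, warm-WW, warm-WD, hot-WW, hot-WD)
        ("c1", "constitutive", [0.14, 0.12, 0.12, 0.11, 0.11, 0.10]),
        ("c2", "constitutive", [0.24, 0.23, 0.24, 0.22, 0.23, 0.22]),
        ("c3", "constitutive", [0.19, 0.17, 0.18, 0.16, 0.17, 0.15]),
        ("a1", "adaptive", [0.05, -0.10, 0.02, -0.14, -0.02, -0.16]),
        ("a2", "adaptive", [0.08, -0.08, 0.05, -0.12, 0.00, -0.14]),
        ("a3", "adaptive", [0.17, 0.12, 0.05, 0.00, -0.12, -0.15]),
    ]
    markers = dict(zip(("c1", "c2", "c3"), const_markers)) | dict(
        zip(("a1", "a2", "a3"), adapt_markers)
    )
    data = []
    for qtl, cls, effs in rows:
        if qtl not in markers:  # fewer than 3 markers supplied for this class
            continue
        fav = (favorable_alleles or {}).get(qtl, "G")
        rec = {"qtl": qtl, "marker": markers[qtl], "qtl_class": cls, "favorable_allele": fav}
        rec.update(dict(zip(cols, effs)))
        data.append(rec)
    return EffectTable(pd.DataFrame(data))


@dataclass
class SimConfig:
    """Study conditions for the simulated panel and trial network.

    Population-genetic parameters (structure_mid_year/structure_tau,
    ancestry_divergence, base_freq_beta) are calibrated so the leading
    genotype PCA axis correlates with year of release at R^2 ~ 0.7 and mean
    pairwise IBS sits near 0.72, as in elite dent panels of this era span.
    """

    n_hybrids: int = 60
    year_range: tuple[int, int] = (1950, 2015)
    n_snps: int = 20_000
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: dict(MAIZE_CHROM_LENGTHS))
    n_selected_loci: int = 50
    trend_slope: float = 0.05  # logit allele-frequency change per year at selected loci
    structure_mid_year: float = 1996.0
    structure_tau: float = 1.5  # years; np.inf = constant (no year-structure coupling)
    ancestry_divergence: float = 0.08  # Balding-Nichols F between the two ancestries
    base_freq_beta: tuple[float, float] = (0.55, 0.55)
    n_qtls_stable: int = 3
    n_qtls_adaptive: int = 3
    scenario_effects: EffectTable | None = None  # built at trial time if None
    n_experiments_per_scenario: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EXPERIMENTS_PER_SCENARIO)
    )
    gain_per_year: float = 101.0  # total yield trend, kg ha^-1 yr^-1
    grain_weight_g: float = 0.30  # individual grain weight; yield = GN * w * 10 kg/ha
    # (genetic, environment-within-scenario, GxE, residual) variances on the
    # grain-number scale
    var_components: tuple[float, float, float, float] = (140_000.0, 200_000.0, 40_000.0, 40_000.0)
    scenario_gn_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCENARIO_GN_EFFECTS)
    )
    base_grain_number: float = 3000.0
    gei_year_slope_sd: float = 7.0  # per-scenario deviation of the GN-vs-year slope
    env_temp_sd: float = 0.6  # within-scenario dispersion of phase temperatures (deg C)
    env_light_rel_sd: float = 0.08  # relative dispersion of phase light sums
    psi_ww: tuple[float, float] = (-0.05, 0.015)  # mean, sd (MPa)
    psi_wd: tuple[float, float] = (-0.40, 0.08)
    beta_psi: np.ndarray | None = None  # optional per-hybrid GN sensitivity to psi
    beta_rint: np.ndarray | None = None  # optional per-hybrid GN sensitivity to R_int
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_hybrids <= 0 or self.n_snps <= 0:
            raise ValueError("counts must be positive")
        if self.year_range[0] >= self.year_range[1]:
            raise ValueError("degenerate year_range")
        if self.n_selected_loci > self.n_snps:
            raise ValueError("n_selected_loci exceeds n_snps")
        if self.n_selected_loci < 0 or self.n_qtls_stable < 0 or self.n_qtls_adaptive < 0:
            raise ValueError("counts must be non-negative")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if any(v < 0 for v in self.var_components):
            raise ValueError("variances must be non-negative")
        if sum(self.n_experiments_per_scenario.values()) <= 0:
            raise ValueError("need at least one experiment")
        if any(v < 0 for v in self.n_experiments_per_scenario.values()):
            raise ValueError("experiment counts must be non-negative")
        return self

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class PanelTruth:
    """Planted ground truth of the simulated panel."""

    selected_snps: np.ndarray  # indices of loci with year-trending frequencies
    selected_snp_ids: np.ndarray  # their SNP identifiers (stable across QC)
    mixing_weight: np.ndarray  # per-hybrid ancestry-B proportion
    freq_per_hybrid: np.ndarray | None = None  # (n_hybrids, n_snps) sampling freqs


def _years(config: SimConfig) -> np.ndarray:
    first, last = config.year_range
    return np.round(np.linspace(first, last, config.n_hybrids)).astype(int)


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, PanelMetadata, PanelTruth]:
    """Simulate the genotype panel.

    Hybrids carry years uniformly spanning year_range. Neutral SNP
    frequencies follow a two-ancestry Balding-Nichols model whose mixture
    proportion is logistic in year (emulating the progressive shift of
    germplasm origin); selected loci get a logit-linear frequency trend of
    `trend_slope` per year. Genotypes are binomial(2, p) draws; calls are
    set missing completely at random at `missing_rate`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n, m = config.n_hybrids, config.n_snps
    years = _years(config)

    p_anc = rng.beta(*config.base_freq_beta, size=m)
    p_anc = np.clip(p_anc, 0.01, 0.99)
    F = config.ancestry_divergence
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_A = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        p_B = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
    else:
        p_A = p_B = p_anc

    with np.errstate(invalid="ignore"):
        z = (years - config.structure_mid_year) / config.structure_tau
    z = np.nan_to_num(z, nan=0.0)  # tau = inf -> constant mixing
    w = expit(z)
    freq = w[:, None] * p_B[None, :] + (1 - w[:, None]) * p_A[None, :]

    selected = rng.choice(m, size=config.n_selected_loci, replace=False)
    selected = np.sort(selected)
    if len(selected):
        p0 = rng.uniform(0.2, 0.8, size=len(selected))
        lo = logit(p0)[None, :] + config.trend_slope * (
            years[:, None] - config.structure_mid_year
        )
        freq[:, selected] = expit(lo)

    counts = rng.binomial(2, freq).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(counts.shape) < config.missing_rate
        counts[miss] = np.nan

    # SNP positions: allocate to chromosomes proportionally to length, then
    # uniform positions, sorted within chromosome
    chroms = list(config.chrom_lengths)
    lens = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    chrom_of = rng.choice(len(chroms), size=m, p=probs)
    pos = np.empty(m, dtype=np.int64)
    order = []
    for ci in range(len(chroms)):
        idx = np.flatnonzero(chrom_of == ci)
        p = np.sort(rng.choice(int(lens[ci]), size=len(idx), replace=False))
        pos[idx] = p
        order.append(idx)
    order = np.concatenate(order)
    inv = np.empty(m, dtype=np.int64)
    inv[order] = np.arange(m)

    G = GenotypeMatrix(
        counts=counts[:, order],
        hybrid_ids=np.array([f"hyb_{i + 1:03d}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"snp_{j + 1:06d}" for j in range(m)], dtype=object),
        chrom=np.array([chroms[ci] for ci in chrom_of[order]], dtype=object),
        pos=pos[order],
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
    )
    meta = PanelMetadata(hybrid_ids=G.hybrid_ids.copy(), years=years.astype(float))
    truth = PanelTruth(
        selected_snps=inv[selected],
        selected_snp_ids=G.snp_ids[inv[selected]],
        mixing_weight=w,
        freq_per_hybrid=freq[:, order],
    )
    return G, meta, truth


def simulate_environments(config: SimConfig) -> list[EnvRecord]:
    """Simulate field-experiment environmental covariates.

    Phase-wise Tmin/Tmax are drawn around the scenario means (cool/warm/hot:
    Tmin 15/17/18, Tmax 25/28/30 deg C) with dispersion env_temp_sd; phase
    light sums scale mildly with scenario warmth; mean soil water potential
    is above -0.1 MPa for WW and below for WD. The planted scenario is
    stored on each record for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    base_light = {"vegetative": 450.0, "flowering": 230.0, "grain_filling": 600.0}
    phase_offset = {"vegetative": -1.0, "flowering": 0.0, "grain_filling": 1.0}
    records = []
    i = 0
    for scen in ALL_SCENARIOS:
        count = int(config.n_experiments_per_scenario.get(str(scen), 0))
        tmin0, tmax0 = SCENARIO_TEMPS[scen.temperature]
        warmth = 1.0 + 0.04 * (tmax0 - 28.0)
        for _ in range(count):
            i += 1
            kw = {}
            for phase in ("vegetative", "flowering", "grain_filling"):
                off = phase_offset[phase]
                tmin = tmin0 + off + rng.normal(0, config.env_temp_sd)
                tmax = tmax0 + off + rng.normal(0, config.env_temp_sd)
                if tmin > tmax:
                    tmin, tmax = tmax, tmin
                light = base_light[phase] * warmth * (
                    1.0 + rng.normal(0, config.env_light_rel_sd)
                )
                kw[f"tmin_{phase}"] = tmin
                kw[f"tmax_{phase}"] = tmax
                kw[f"light_{phase}"] = max(light, 0.0)
            if scen.water == "WW":
                mu, sd = config.psi_ww
                psi = float(np.clip(rng.normal(mu, sd), -0.095, -0.005))
            else:
                mu, sd = config.psi_wd
                psi = float(np.clip(rng.normal(mu, sd), -0.75, -0.12))
            records.append(
                EnvRecord(experiment=f"exp_{i:02d}_{scen}", psi=psi, scenario_true=scen, **kw)
            )
    if not records:
        raise ValueError("no experiments configured")
    return records


# Trait model coefficients: year -> veg/silk/rh_pad; rh_pad -> ear_light;
# veg/silk/ear_light -> grain number. Slopes chosen so the mediated shares of
# the year effect on grain number are ~20% (veg), ~20% (silk), ~48%
# (architecture via ear-layer light), the remainder direct.
_TRAIT = {
    "veg_base": 70.0,
    "veg_slope": 0.154,  # d20 per year (+10 d20 over 65 years)
    "veg_sd": 3.0,
    "silk_base": 400.0,
    "silk_slope": 0.8,
    "silk_sd": 15.0,
    "rh_base": 0.45,
    "rh_slope": 0.0012,
    "rh_sd": 0.015,
    "ear_base": 0.10,
    "ear_rh_coef": 0.45,
    "ear_sd": 0.008,
}

TRUE_TRAIT_DAG = (
    ("year", "veg"),
    ("year", "silk"),
    ("year", "rh_pad"),
    ("rh_pad", "ear_light"),
    ("veg", "grain_number"),
    ("silk", "grain_number"),
    ("ear_light", "grain_number"),
)


@dataclass
class TrialTruth:
    """Planted ground truth of the simulated trial network."""

    dag_edges: tuple[tuple[str, str], ...]
    effect_table: EffectTable | None
    qtl_snp_idx: dict[str, int]
    genetic_values: pd.DataFrame  # per-hybrid genotypic trait/GN values
    scenario_of_experiment: dict[str, ScenarioLabel]


def _gn_share_coefs(config: SimConfig):
    gn_slope = config.gain_per_year / (config.grain_weight_g * 10.0)
    a_veg = 0.20 * gn_slope / _TRAIT["veg_slope"]
    a_silk = 0.20 * gn_slope / _TRAIT["silk_slope"]
    a_ear = 0.48 * gn_slope / (_TRAIT["ear_rh_coef"] * _TRAIT["rh_slope"])
    direct = 0.12 * gn_slope
    return gn_slope, a_veg, a_silk, a_ear, direct


def simulate_trial(
    config: SimConfig,
    G: GenotypeMatrix,
    meta: PanelMetadata,
    envs: Sequence[EnvRecord],
    truth: PanelTruth | None = None,
) -> tuple[pd.DataFrame, TrialTruth]:
    """Simulate the multi-environment trial table.

    Grain number per (hybrid, experiment) = intercept + year trend (partly
    mediated by veg/silk/architecture traits) + QTL scenario effects +
    scenario effect + experiment deviation + year x scenario interaction +
    GxE noise + residual; yield (kg/ha) = GN * grain weight * 10.
    """
    config.validate()
    if G.n_hybrids != len(meta):
        raise ValueError("genotype matrix and metadata disagree on panel size")
    rng = np.random.default_rng([config.seed, 2])
    n = G.n_hybrids
    years = np.asarray(meta.years, dtype=float)
    yc = years - years.mean()

    gn_slope, a_veg, a_silk, a_ear, direct = _gn_share_coefs(config)
    var_g, var_e, var_gxe, var_res = config.var_components

    # genotypic trait values (constant across experiments, like BLUEs)
    veg = _TRAIT["veg_base"] + _TRAIT["veg_slope"] * yc + rng.normal(0, _TRAIT["veg_sd"], n)
    silk = _TRAIT["silk_base"] + _TRAIT["silk_slope"] * yc + rng.normal(0, _TRAIT["silk_sd"], n)
    rh = np.clip(
        _TRAIT["rh_base"] + _TRAIT["rh_slope"] * yc + rng.normal(0, _TRAIT["rh_sd"], n), 0.0, 1.0
    )
    ear = _TRAIT["ear_base"] + _TRAIT["ear_rh_coef"] * rh + rng.normal(0, _TRAIT["ear_sd"], n)

    # trait-noise already contributes genetic variance; the direct genetic
    # deviation supplies the remainder of var_g
    prop_var = (
        (a_veg * _TRAIT["veg_sd"]) ** 2
        + (a_silk * _TRAIT["silk_sd"]) ** 2
        + (a_ear * _TRAIT["ear_rh_coef"] * _TRAIT["rh_sd"]) ** 2
        + (a_ear * _TRAIT["ear_sd"]) ** 2
    )
    g_res = rng.normal(0, np.sqrt(max(var_g - prop_var, 0.0)), n)

    # QTL assignment: constitutive QTLs at planted trending loci, adaptive at
    # neutral loci
    effects = config.scenario_effects
    snp_ids = G.snp_ids.astype(str)
    use_qtls = effects is not None or (config.n_qtls_stable + config.n_qtls_adaptive) > 0
    if effects is None and use_qtls:
        # constitutive QTLs sit at planted trending loci still present after
        # QC; adaptive QTLs at neutral loci (matching ids, robust to QC)
        if truth is not None:
            sel_ids = [s for s in truth.selected_snp_ids.astype(str) if s in set(snp_ids)]
        else:
            sel_ids = []
        const_ids = sel_ids[: config.n_qtls_stable]
        if len(const_ids) < config.n_qtls_stable:
            extra = [s for s in snp_ids if s not in set(const_ids)]
            const_ids += extra[: config.n_qtls_stable - len(const_ids)]
        neutral_pool = np.array(
            [s for s in snp_ids if s not in set(sel_ids) and s not in set(const_ids)]
        )
        adapt_ids = rng.choice(neutral_pool, size=config.n_qtls_adaptive, replace=False)
        effects = default_effect_table(
            const_markers=const_ids, adapt_markers=list(np.sort(adapt_ids))
        )
    qtl_idx = {}
    qtl_counts = {}
    # effect of one favorable-allele copy on GN (t/ha -> grains/m^2)
    t_ha_to_gn = 1000.0 / (config.grain_weight_g * 10.0)
    if effects is not None:
        for qtl in effects.qtls:
            marker = str(effects.row(qtl)["marker"])
            j = np.flatnonzero(snp_ids == marker)
            if len(j) == 0:
                raise ValueError(f"QTL peak marker {marker!r} not in the genotype matrix")
            qtl_idx[qtl] = int(j[0])
        for qtl, j in qtl_idx.items():
            c = G.counts[:, j].copy()
            c = np.where(np.isnan(c), np.nanmean(c), c)
            fav = str(effects.row(qtl)["favorable_allele"])
            if fav == str(G.ref[j]):
                c = 2.0 - c
            qtl_counts[qtl] = c

    scen_of_exp = {}
    for e in envs:
        if e.scenario_true is None:
            raise ValueError(f"experiment {e.experiment} lacks a scenario label")
        scen_of_exp[e.experiment] = e.scenario_true

    # field-frequency-weighted mean effect per QTL, used to keep the total
    # realized yield trend at gain_per_year despite trending QTL frequencies
    scen_counts = pd.Series([str(s) for s in scen_of_exp.values()]).value_counts()
    year_coef = direct
    mean_effects = {}
    for qtl in qtl_idx:
        me = sum(
            effects.effect(qtl, ScenarioLabel.parse(s)) * k for s, k in scen_counts.items()
        ) / scen_counts.sum()
        mean_effects[qtl] = me * t_ha_to_gn
        if np.ptp(qtl_counts[qtl]) > 0 and np.ptp(yc) > 0:
            slope_q = np.polyfit(yc, qtl_counts[qtl], 1)[0]
            year_coef -= mean_effects[qtl] * slope_q

    gn_genetic = (
        config.base_grain_number
        + a_veg * (veg - _TRAIT["veg_base"])
        + a_silk * (silk - _TRAIT["silk_base"])
        + a_ear * (ear - (_TRAIT["ear_base"] + _TRAIT["ear_rh_coef"] * _TRAIT["rh_base"]))
        + year_coef * yc
        + g_res
    )

    # per-scenario year-slope deviations (G_year x Scen interaction)
    gei_slopes = {
        str(s): rng.normal(0, config.gei_year_slope_sd) for s in ALL_SCENARIOS
    }
    exp_dev = {e.experiment: rng.normal(0, np.sqrt(var_e)) for e in envs}

    psi_all = np.array([e.psi for e in envs])
    rint_all = np.array([e.light_vegetative for e in envs])
    psi_mean, rint_mean = psi_all.mean(), rint_all.mean()

    rows = []
    for e in envs:
        scen = scen_of_exp[e.experiment]
        s = str(scen)
        scen_eff = config.scenario_gn_effects.get(s, 0.0)
        qtl_term = np.zeros(n)
        for qtl in qtl_idx:
            qtl_term += effects.effect(qtl, scen) * t_ha_to_gn * qtl_counts[qtl]
            qtl_term -= mean_effects[qtl] * qtl_counts[qtl].mean()  # center level
        gn = (
            gn_genetic
            + scen_eff
            + gei_slopes[s] * yc
            + exp_dev[e.experiment]
            + qtl_term
            + rng.normal(0, np.sqrt(var_gxe), n)
            + rng.normal(0, np.sqrt(var_res), n)
        )
        if config.beta_psi is not None:
            gn = gn + np.asarray(config.beta_psi) * (e.psi - psi_mean)
        if config.beta_rint is not None:
            gn = gn + np.asarray(config.beta_rint) * (e.light_vegetative - rint_mean)
        gn = np.clip(gn, 0.0, None)
        for i in range(n):
            rows.append(
                {
                    "hybrid": meta.hybrid_ids[i],
                    "experiment": e.experiment,
                    "scenario": s,
                    "year": years[i],
                    "grain_number": gn[i],
                    "yield_kg_ha": gn[i] * config.grain_weight_g * 10.0,
                    "veg": veg[i],
                    "silk": silk[i],
                    "rh_pad": rh[i],
                    "ear_light": ear[i],
                    "psi": e.psi,
                    "r_int": e.light_vegetative,
                }
            )
    trial = validate_trial(pd.DataFrame(rows))
    genetic_values = pd.DataFrame(
        {
            "hybrid": meta.hybrid_ids,
            "year": years,
            "veg": veg,
            "silk": silk,
            "rh_pad": rh,
            "ear_light": ear,
            "grain_number": gn_genetic,
        }
    )
    return trial, TrialTruth(
        dag_edges=TRUE_TRAIT_DAG,
        effect_table=effects,
        qtl_snp_idx=qtl_idx,
        genetic_values=genetic_values,
        scenario_of_experiment=scen_of_exp,
    )


def write_truth(truth: PanelTruth | TrialTruth, G: GenotypeMatrix | None, outdir) -> None:
    """Write ground-truth files (selected loci, true DAG, QTL table) as CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(truth, PanelTruth):
        ids = G.snp_ids[truth.selected_snps] if G is not None else truth.selected_snps
        pd.DataFrame({"selected_snp": ids}).to_csv(outdir / "selected_loci.csv", index=False)
    else:
        pd.DataFrame(truth.dag_edges, columns=["from", "to"]).to_csv(
            outdir / "true_dag.csv", index=False
        )
        if truth.effect_table is not None:
            truth.effect_table.table.to_csv(outdir / "qtl_effects.csv", index=False)
        pd.DataFrame(
            [(e, str(s)) for e, s in truth.scenario_of_experiment.items()],
            columns=["experiment", "scenario"],
        ).to_csv(outdir / "true_scenarios.csv", index=False)
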
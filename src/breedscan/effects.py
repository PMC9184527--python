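"""Scenario-conditional QTL allelic effects and favorable-allele frequency
shifts between breeding eras.

Allelic effects are estimated externally per environmental scenario; here
they are looked up per field from the field's scenario and summarized per
QTL. The favorable allele is the one with a positive yield effect in the
cool/well-watered scenario.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EffectTable, GenotypeMatrix, PanelMetadata, ScenarioLabel


def predict_field_effects(
    effects: EffectTable, field_scenarios: dict[str, ScenarioLabel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each QTL's scenario-specific effect to each field.

    Returns (per_field, summary): per_field has one row per (qtl, field) with
    the looked-up effect (t ha^-1); summary has per-QTL min/max/mean/SD over
    fields.
    """
    rows = []
    for qtl in effects.qtls:
        for fld, scen in field_scenarios.items():
            try:
                e = effects.effect(qtl, scen)
            except KeyError as exc:
                raise KeyError(f"no effect for QTL {qtl!r} in scenario {scen}") from exc
            rows.append({"qtl": qtl, "field": fld, "scenario": str(scen), "effect": e})
    per_field = pd.DataFrame(rows)
    summary = (
        per_field.groupby("qtl", sort=True)["effect"]
        .agg(["min", "max", "mean", "std"])
        .reset_index()
    )
    classes = effects.table.set_index("qtl")["qtl_class"]
    summary["qtl_class"] = summary["qtl"].map(classes)
    return per_field, summary


def favorable_freq_shift(
    G: GenotypeMatrix,
    effects: EffectTable,
    meta: PanelMetadata,
    n_group: int = 22,
) -> pd.DataFrame:
    """Favorable-allele frequency at each QTL's peak marker in the n oldest
    vs the n most recent hybrids.

    Frequencies are computed over non-missing calls only. A peak marker
    absent from the matrix yields a row flagged missing rather than an error.
    """
    old_idx, recent_idx = meta.era_groups(n_group)
    snp_index = {str(s): j for j, s in enumerate(G.snp_ids)}
    rows = []
    for qtl in effects.qtls:
        r = effects.row(qtl)
        marker = str(r["marker"])
        row = {
            "qtl": qtl,
            "marker": marker,
            "qtl_class": r["qtl_class"],
            "missing": marker not in snp_index,
        }
        if row["missing"]:
            row.update({"freq_old": np.nan, "freq_recent": np.nan, "delta": np.nan})
        else:
            j = snp_index[marker]
            fav_is_alt = str(r["favorable_allele"]) == str(G.alt[j])

            def freq(idx):
                c = G.counts[idx, j]
                c = c[~np.isnan(c)]
                if len(c) == 0:
                    return np.nan
                p_alt = c.mean() / 2.0
                return p_alt if fav_is_alt else 1.0 - p_alt

            fo, fr = freq(old_idx), freq(recent_idx)
            row.update({"freq_old": fo, "freq_recent": fr, "delta": fr - fo})
        rows.append(row)
    return pd.DataFrame(rows)
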
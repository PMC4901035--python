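"""Published treatment means from the source Rusitec / batch-culture study.

These dictionaries transcribe the printed treatment-mean tables of the
study the pipeline reproduces.  They serve three roles: default parameter
sets for the synthetic generator, fixtures for the table-reproduction
tests, and inputs for the reproduction report.

Treatments follow the 2 x 2 factorial: forage (GRA = fresh ryegrass,
HAY = ryegrass hay) x vitamin E (- = none, + = 50 IU/d alpha-tocopheryl
acetate).  Four Rusitec vessels per treatment, fed 11.25 g DM/d at an
80:20 forage:concentrate ratio.
"""

from __future__ import annotations

TREATMENTS = ("GRA-", "GRA+", "HAY-", "HAY+")

#: Diet chemical composition (% of DM unless noted).
DIET_COMPOSITION = {
    "grass": {"om_pct": 91.2, "n_pct": 1.83, "ndf_pct": 50.0},
    "grass_hay": {"om_pct": 91.0, "n_pct": 1.69, "ndf_pct": 54.6},
    "concentrate": {"om_pct": 93.8, "n_pct": 2.51, "ndf_pct": 39.3},
}

#: Rusitec feeding regime.
DM_INTAKE_G_D = 11.25
FORAGE_FRACTION = 0.8

#: Daily VFA outflows (mmol/d) and N flows (mg/d) per treatment.
OUTFLOWS = {
    "GRA-": {"acetate": 14.2, "propionate": 8.02, "butyrate": 4.50,
             "isobutyrate": 0.39, "valerate": 1.28, "isovalerate": 1.07,
             "total_vfa": 31.2, "ammonia_n": 58.8, "nan": 140.0,
             "nanm_n": 39.9, "microbial_n": 100.5},
    "GRA+": {"acetate": 15.7, "propionate": 8.93, "butyrate": 4.94,
             "isobutyrate": 0.41, "valerate": 1.27, "isovalerate": 1.28,
             "total_vfa": 33.8, "ammonia_n": 58.3, "nan": 152.0,
             "nanm_n": 54.8, "microbial_n": 97.7},
    "HAY-": {"acetate": 15.7, "propionate": 9.60, "butyrate": 5.51,
             "isobutyrate": 0.39, "valerate": 1.60, "isovalerate": 1.13,
             "total_vfa": 35.1, "ammonia_n": 48.8, "nan": 122.0,
             "nanm_n": 36.9, "microbial_n": 84.9},
    "HAY+": {"acetate": 16.8, "propionate": 9.96, "butyrate": 5.04,
             "isobutyrate": 0.41, "valerate": 1.42, "isovalerate": 1.22,
             "total_vfa": 35.5, "ammonia_n": 46.5, "nan": 115.0,
             "nanm_n": 28.6, "microbial_n": 86.3},
}

#: Degradability and methanogenesis treatment means.
DEGRADABILITY = {
    "GRA-": {"om_dis_pct": 57.4, "ndf_dis_pct": 44.1, "methane_mmol_d": 5.10},
    "GRA+": {"om_dis_pct": 63.5, "ndf_dis_pct": 52.5, "methane_mmol_d": 5.01},
    "HAY-": {"om_dis_pct": 60.6, "ndf_dis_pct": 52.8, "methane_mmol_d": 6.04},
    "HAY+": {"om_dis_pct": 63.7, "ndf_dis_pct": 55.1, "methane_mmol_d": 7.59},
}

#: Printed metabolic-hydrogen balance rows (for reproduction checks).
HYDROGEN_BALANCE_PRINTED = {
    "GRA-": {"h_produced": 58.2, "h_incorporated": 50.5,
             "recovery": 87.3, "ch4_vfa": 0.165},
    "GRA+": {"h_produced": 64.0, "h_incorporated": 52.9,
             "recovery": 82.7, "ch4_vfa": 0.149},
    "HAY-": {"h_produced": 67.8, "h_incorporated": 60.8,
             "recovery": 89.6, "ch4_vfa": 0.172},
    "HAY+": {"h_produced": 67.9, "h_incorporated": 66.0,
             "recovery": 97.4, "ch4_vfa": 0.214},
}

#: Printed N-metabolism and efficiency-of-synthesis rows.
NITROGEN_PRINTED = {
    "GRA-": {"apparent_deg": 36.5, "true_deg": 82.0, "mn_from_nh3": 36.0,
             "eff_nan": 0.72, "eff_intake": 0.45, "eff_true_deg": 0.55,
             "emps": 17.0},
    "GRA+": {"apparent_deg": 31.0, "true_deg": 75.2, "mn_from_nh3": 36.3,
             "eff_nan": 0.64, "eff_intake": 0.44, "eff_true_deg": 0.59,
             "emps": 14.9},
    "HAY-": {"apparent_deg": 41.8, "true_deg": 82.4, "mn_from_nh3": 45.7,
             "eff_nan": 0.70, "eff_intake": 0.41, "eff_true_deg": 0.49,
             "emps": 13.6},
    "HAY+": {"apparent_deg": 45.1, "true_deg": 86.4, "mn_from_nh3": 44.8,
             "eff_nan": 0.75, "eff_intake": 0.41, "eff_true_deg": 0.48,
             "emps": 13.2},
}

#: Bacterial community diversity treatment means (rarefied to 10 572
#: reads/sample; 971 OTUs overall).
BACTERIAL_DIVERSITY = {
    "GRA-": {"richness": 632, "shannon": 4.68, "evenness": 0.77,
             "simpson": 0.97, "chao1": 848, "goods": 0.71},
    "GRA+": {"richness": 616, "shannon": 4.53, "evenness": 0.71,
             "simpson": 0.96, "chao1": 802, "goods": 0.70},
    "HAY-": {"richness": 688, "shannon": 5.07, "evenness": 0.78,
             "simpson": 0.98, "chao1": 879, "goods": 0.73},
    "HAY+": {"richness": 635, "shannon": 4.60, "evenness": 0.71,
             "simpson": 0.96, "chao1": 905, "goods": 0.68},
}

#: Batch-culture (Experiment 1) reference scales: France-model parameters
#: of the control bottles and the control protozoal activity slope.
BATCH_CULTURE = {
    "asymptotic_gp_ml": 116.0,
    "gp_rate_per_h": 0.065,
    "protozoal_activity_pct_h": 9.95,
    "sampling_grid_h": (2.0, 4.0, 6.0, 9.0, 12.0, 24.0, 48.0, 72.0, 96.0),
}


def treatment_mean(table: dict, key: str, treatments=TREATMENTS) -> dict:
    """Extract one column (``key``) across treatments from a table dict."""
    return {t: table[t][key] for t in treatments}
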
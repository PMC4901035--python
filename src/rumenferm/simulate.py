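"""Synthetic data with the statistical structure the analyses assume.

Emulates the two experiments the pipeline targets, so every stage can be
exercised end-to-end without raw measurements:

* a 2 x 2 factorial Rusitec run (fresh grass vs. hay, with/without
  vitamin E; four vessels per treatment) emitting per-vessel VFA and N
  outflows plus 15N enrichments,
* batch-culture gas bottles on the 9-point pressure-transducer grid
  (2...96 h) with blank bottles,
* 14C bacterial-release tubes sampled hourly over 0-4 h,
* Dirichlet-multinomial OTU count tables with treatment fold-change
  effects on a designated OTU set.

Vessel-level noise is Normal on the measurement scale with SD derived
from the published standard error of the difference (SED = SD * sqrt(2/n),
so SD = SED * sqrt(n/2)).  Enrichments are constructed so that the
tracer ratio formulas return the configured microbial fraction and
ammonia contribution exactly in noise-free mode.  Every generator is a
pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference
from .community import OTUTable
from .exceptions import ValidationError
from .gas_kinetics import (DEFAULT_AMBIENT_KPA, DEFAULT_HEADSPACE_ML,
                           PressureSeries, ReleaseSeries)

VESSEL_NOISE_FIELDS = ("acetate", "propionate", "butyrate", "isobutyrate",
                       "valerate", "isovalerate", "methane", "nan_outflow",
                       "ammonia_outflow")


def sd_from_sed(sed: float, n_per_group: int = 4) -> float:
    """Vessel SD implied by a published SED with n vessels per treatment."""
    if sed < 0 or n_per_group < 1:
        raise ValidationError("SED must be >= 0 and n >= 1")
    return sed * math.sqrt(n_per_group / 2.0)


@dataclass(frozen=True)
class VesselConfig:
    """Treatment means and noise for the factorial fermenter experiment."""

    treatments: tuple[str, ...] = reference.TREATMENTS
    n_vessels: int = 4
    #: group size of the experiment the SEDs were published for; the
    #: implied vessel SD is fixed by it, independent of n_vessels.
    sed_n: int = 4
    #: treatment -> field -> mean; defaults transcribe the published
    #: outflow and methane tables ("table3/table7 defaults").
    means: dict = field(default_factory=lambda: {
        t: {**reference.OUTFLOWS[t],
            "methane": reference.DEGRADABILITY[t]["methane_mmol_d"],
            "om_disappearance": reference.DEGRADABILITY[t]["om_dis_pct"] / 100}
        for t in reference.TREATMENTS})
    #: field -> SED on the treatment-mean scale (published SED column).
    seds: dict = field(default_factory=lambda: {
        "acetate": 1.247, "propionate": 0.801, "butyrate": 0.483,
        "isobutyrate": 0.036, "valerate": 0.067, "isovalerate": 0.086,
        "methane": 0.792, "nan_outflow": 6.92, "ammonia_outflow": 3.86})
    #: treatment -> (microbial fraction of NAN, % microbial N from NH3).
    enrichment_targets: dict = field(default_factory=lambda: {
        t: (reference.OUTFLOWS[t]["microbial_n"] / reference.OUTFLOWS[t]["nan"],
            reference.NITROGEN_PRINTED[t]["mn_from_nh3"])
        for t in reference.TREATMENTS})
    ammonia_enrichment: float = 0.50   # atom % 15N excess of the NH3 pool
    enrichment_cv: float = 0.0         # relative noise on enrichments
    noise: float = 1.0                 # multiplier on all flow SDs


@dataclass(frozen=True)
class GasConfig:
    """Batch-culture gas bottles on the transducer sampling grid."""

    times_h: tuple[float, ...] = reference.BATCH_CULTURE["sampling_grid_h"]
    a_ml: float = reference.BATCH_CULTURE["asymptotic_gp_ml"]
    c_per_h: float = reference.BATCH_CULTURE["gp_rate_per_h"]
    sigma_ml: float = 1.0
    n_bottles: int = 4
    n_blanks: int = 2
    blank_a_ml: float = 8.0            # residual fermentation of inoculum
    blank_c_per_h: float = 0.05
    headspace_ml: float = DEFAULT_HEADSPACE_ML
    ambient_kpa: float = DEFAULT_AMBIENT_KPA


@dataclass(frozen=True)
class OTUConfig:
    """Dirichlet-multinomial OTU tables for the sequencing design."""

    n_samples: int = 32                # 16 vessels x 2 time points
    n_otus: int = 200
    concentration: float = 50.0        # Dirichlet precision (overdispersion)
    effect_otus: int = 20              # OTUs carrying the treatment effect
    fold_change: float = 1.0           # forage effect on those OTUs
    depth_range: tuple[int, int] = (5000, 12000)
    n_animals: int = 4

    def __post_init__(self):
        if self.effect_otus > self.n_otus:
            raise ValidationError("effect set larger than the OTU pool")
        if self.fold_change <= 0 or self.concentration <= 0:
            raise ValidationError("fold-change and concentration must be > 0")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValidationError("depth range min > max")


@dataclass(frozen=True)
class ReleaseConfig:
    """14C release tubes; control slope from the batch-culture table."""

    slope_pct_h: float = reference.BATCH_CULTURE["protozoal_activity_pct_h"]
    intercept_pct: float = 5.0
    sigma_pct: float = 0.3
    n_tubes: int = 4
    times_h: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)

    def __post_init__(self):
        if self.slope_pct_h < 0:
            raise ValidationError("release slope must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of all generator settings."""

    vessels: VesselConfig = field(default_factory=VesselConfig)
    gas: GasConfig = field(default_factory=GasConfig)
    otu: OTUConfig = field(default_factory=OTUConfig)
    release: ReleaseConfig = field(default_factory=ReleaseConfig)

    def with_noise(self, factor: float) -> "SimulationConfig":
        """Copy with every noise scale multiplied by ``factor``
        (0 gives the deterministic round-trip mode)."""
        return replace(
            self,
            vessels=replace(self.vessels, noise=self.vessels.noise * factor,
                            enrichment_cv=self.vessels.enrichment_cv * factor),
            gas=replace(self.gas, sigma_ml=self.gas.sigma_ml * factor),
            release=replace(self.release,
                            sigma_pct=self.release.sigma_pct * factor),
        )


# ---------------------------------------------------------------------------

def simulate_vessels(config: VesselConfig, seed: int | None = None
                     ) -> pd.DataFrame:
    """Per-vessel fermentation, N-flow and enrichment table.

    One row per vessel with VFA outflows (mmol/d), methane (mmol/d), OM
    disappearance, N flows (mg/d) and the three 15N enrichments.  In
    noise-free mode every vessel equals its treatment mean and the
    tracer formulas return the configured targets exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for treatment in config.treatments:
        means = config.means[treatment]
        mic_frac, from_nh3 = config.enrichment_targets[treatment]
        for v in range(config.n_vessels):
            row = {"sample_id": f"{treatment}_v{v + 1}",
                   "treatment": treatment, "replicate": v + 1}
            for fld in VESSEL_NOISE_FIELDS:
                mean = means.get(fld, means.get(fld.replace("_outflow", "")))
                if fld == "nan_outflow":
                    mean = means["nan"]
                elif fld == "ammonia_outflow":
                    mean = means["ammonia_n"]
                sd = sd_from_sed(config.seds[fld], config.sed_n) \
                    * config.noise
                val = mean if sd == 0 else rng.normal(mean, sd)
                row[fld] = max(val, 0.0)
            row["om_disappearance"] = means["om_disappearance"]
            # enrichments constructed to invert to the configured targets
            e_nh3 = config.ammonia_enrichment
            e_bact = e_nh3 * from_nh3 / 100.0
            e_nan = e_bact * mic_frac
            if config.enrichment_cv > 0:
                e_nh3 *= rng.lognormal(0.0, config.enrichment_cv)
                e_bact *= rng.lognormal(0.0, config.enrichment_cv)
                e_nan *= rng.lognormal(0.0, config.enrichment_cv)
            row["ammonia_enrichment"] = e_nh3
            row["bacterial_enrichment"] = e_bact
            row["nan_enrichment"] = e_nan
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_gas_curves(config: GasConfig, seed: int | None = None
                        ) -> list[PressureSeries]:
    """Pressure-transducer series for sample and blank bottles.

    Sample bottles follow Y = A(1 - exp(-ct)) plus the blank baseline and
    Normal(0, sigma) noise on the cumulative volume; blanks carry the
    baseline only.  Volumes are inverted to vented pressure increments
    using the same ideal-gas convention the analysis applies.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(config.times_h, dtype=float)
    if config.a_ml <= 0 or config.c_per_h <= 0:
        raise ValidationError("gas-model parameters must be > 0")
    blank_mean = config.blank_a_ml * (1.0 - np.exp(-config.blank_c_per_h * t))

    def to_pressures(cumulative: np.ndarray) -> np.ndarray:
        increments = np.diff(np.concatenate(([0.0], cumulative)))
        return increments * config.ambient_kpa / config.headspace_ml

    out = []
    for b in range(config.n_bottles):
        signal = config.a_ml * (1.0 - np.exp(-config.c_per_h * t))
        noise = rng.normal(0.0, config.sigma_ml, t.size) \
            if config.sigma_ml > 0 else 0.0
        cumulative = np.maximum(signal + blank_mean + noise, 0.0)
        out.append(PressureSeries(f"bottle_{b + 1}", t.copy(),
                                  to_pressures(cumulative),
                                  config.headspace_ml, config.ambient_kpa))
    for b in range(config.n_blanks):
        noise = rng.normal(0.0, config.sigma_ml, t.size) \
            if config.sigma_ml > 0 else 0.0
        cumulative = np.maximum(blank_mean + noise, 0.0)
        out.append(PressureSeries(f"blank_{b + 1}", t.copy(),
                                  to_pressures(cumulative),
                                  config.headspace_ml, config.ambient_kpa))
    return out


def simulate_otu_table(config: OTUConfig, seed: int | None = None
                       ) -> OTUTable:
    """Dirichlet-multinomial OTU table with a forage effect.

    Base OTU proportions follow a geometric-style ranked abundance
    profile.  For hay samples, the designated effect OTUs' base
    proportions are multiplied by ``fold_change`` before renormalising.
    Metadata assigns the 2 x 2 factorial, time point and inoculum animal
    in the balanced pattern of the study design.
    """
    rng = np.random.default_rng(seed)
    k = config.n_otus
    base = np.exp(-0.03 * np.arange(k))
    base = rng.permutation(base)
    base /= base.sum()
    effect_idx = rng.choice(k, size=config.effect_otus, replace=False)

    sample_ids, meta_rows, counts = [], [], []
    for i in range(config.n_samples):
        forage = "HAY" if (i // 2) % 2 else "GRA"
        vitamin_e = "+" if (i // 4) % 2 else "-"
        time_point = "4h" if i % 2 == 0 else "24h"
        animal = f"cow{(i // 8) % config.n_animals + 1}"
        props = base.copy()
        if forage == "HAY":
            props[effect_idx] *= config.fold_change
            props /= props.sum()
        alpha = props * config.concentration
        p = rng.dirichlet(alpha)
        depth = int(rng.integers(config.depth_range[0],
                                 config.depth_range[1] + 1))
        counts.append(rng.multinomial(depth, p))
        sid = f"S{i + 1:03d}"
        sample_ids.append(sid)
        meta_rows.append({"sample_id": sid, "forage": forage,
                          "vitamin_e": vitamin_e, "time_point": time_point,
                          "inoculum_animal": animal})
    counts = pd.DataFrame(np.asarray(counts), index=sample_ids,
                          columns=[f"OTU{j + 1:04d}" for j in range(k)])
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return OTUTable(counts, metadata)


def simulate_release_assay(config: ReleaseConfig, seed: int | None = None
                           ) -> list[ReleaseSeries]:
    """14C-release time courses: %released = a + b*t + noise, clipped to
    [0, 100]."""
    rng = np.random.default_rng(seed)
    t = np.asarray(config.times_h, dtype=float)
    out = []
    for tube in range(config.n_tubes):
        y = config.intercept_pct + config.slope_pct_h * t
        if config.sigma_pct > 0:
            y = y + rng.normal(0.0, config.sigma_pct, t.size)
        out.append(ReleaseSeries(f"tube_{tube + 1}", t.copy(),
                                 np.clip(y, 0.0, 100.0)))
    return out
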
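"""Synthetic data generators mirroring a multi-cultivar fruit-metabolomics study.

The study design emulated throughout the package is 18 sweet-cherry cultivars
sampled in two growing seasons (vintages) with three biological replicate
pools each: 108 samples.  Targeted metabolite concentrations are expressed in
mg per 100 g fresh weight; antioxidant responses in mmol Trolox equivalents
per kg; untargeted LC-MS features as peak areas with isotope/adduct
correlation structure and per-sample global intensity factors.

Defaults follow the reported compositional ranges: per-cultivar anthocyanin
means span 14–114 mg/100 g, ascorbic acid 7–15 mg/100 g, hydroxycinnamic
acids up to 65 mg/100 g and quercetin glycosides up to 7 mg/100 g, with
variance dominated by cultivar rather than vintage (weak shared vintage
shift, lognormal replicate noise).  Antioxidant responses are linear in
concentrations with optional pairwise product (synergy) terms — the minimal
model able to express an additive-versus-synergistic dichotomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, ExtractionProtocol
from .errors import ConfigurationError, DomainError, SchemaError

__all__ = [
    "METABOLITE_CLASSES",
    "SimulationConfig",
    "FeatureMatrix",
    "default_config",
    "generate_metabolite_table",
    "generate_responses",
    "generate_feature_matrix",
    "simulate_assay_plate",
    "generate_planted_regression",
    "mixture_teac",
    "simulate_depletion_panel",
]

LABEL_COLS = ["sample_id", "cultivar", "vintage", "replicate"]

#: canonical targeted panel: metabolite -> polyphenol/vitamin class
METABOLITE_CLASSES: dict[str, str] = {
    "neochlorogenic_acid": "hydroxycinnamic_acid",
    "chlorogenic_acid": "hydroxycinnamic_acid",
    "coumaroyl_quinic_acid": "hydroxycinnamic_acid",
    "cyanidin_3_glucoside": "anthocyanin",
    "cyanidin_3_rutinoside": "anthocyanin",
    "quercetin_3_rutinoside": "quercetin",
    "quercetin_3_glucoside": "quercetin",
    "ascorbic_acid": "ascorbic_acid",
}

# [M-H]- masses and retention times used when expanding metabolites into
# m/z features (monoisotopic, +1 isotope at +1.0034, formate adduct +46.0055).
_MZ_RT: dict[str, tuple[float, float]] = {
    "neochlorogenic_acid": (353.0878, 4.1),
    "chlorogenic_acid": (353.0878, 6.3),
    "coumaroyl_quinic_acid": (337.0929, 7.6),
    "cyanidin_3_glucoside": (447.0933, 8.2),
    "cyanidin_3_rutinoside": (593.1512, 8.9),
    "quercetin_3_rutinoside": (609.1461, 11.4),
    "quercetin_3_glucoside": (463.0882, 11.9),
    "ascorbic_acid": (175.0248, 1.6),
}

_ISOTOPE_DELTA = 1.0034
_ADDUCT_DELTA = 46.0055

# mmol TE/kg contributed per mg/100 g fw: cyanidin-3-O-rutinoside strongest,
# then ascorbate and cyanidin-3-O-glucoside, the rest much weaker.
_DEFAULT_BETA: dict[str, float] = {
    "neochlorogenic_acid": 0.030,
    "chlorogenic_acid": 0.030,
    "coumaroyl_quinic_acid": 0.020,
    "cyanidin_3_glucoside": 0.120,
    "cyanidin_3_rutinoside": 0.250,
    "quercetin_3_rutinoside": 0.050,
    "quercetin_3_glucoside": 0.040,
    "ascorbic_acid": 0.150,
}

# synergy between anthocyanins and quercetins / ascorbic acid: product terms
# vanish whenever the anthocyanin partner is absent.
_DEFAULT_SYNERGY: tuple[tuple[str, str, float], ...] = (
    ("cyanidin_3_rutinoside", "quercetin_3_rutinoside", 0.004),
    ("cyanidin_3_rutinoside", "ascorbic_acid", 0.003),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``cultivar_means`` is a cultivars × metabolites table of mean
    concentrations (mg/100 g fw); when ``None`` it is drawn once from the
    documented compositional ranges using ``seed``.
    """

    n_cultivars: int = 18
    n_vintages: int = 2
    n_replicates: int = 3
    cultivar_means: pd.DataFrame | None = None
    vintage_shift_sd: float = 0.05
    replicate_cv: float = 0.10
    n_noise_features: int = 104
    isotope_fraction: float = 0.12
    adduct_fraction: float = 0.25
    intensity_factor_sd: float = 0.30
    feature_noise_cv: float = 0.05
    noise_feature_cv: float = 0.30
    response_intercept: float = 2.0
    response_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BETA)
    )
    synergy_terms: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(_DEFAULT_SYNERGY)
    )
    response_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cultivars", "n_vintages", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in ("vintage_shift_sd", "replicate_cv", "response_noise_sd",
                     "isotope_fraction", "adduct_fraction",
                     "intensity_factor_sd", "feature_noise_cv",
                     "noise_feature_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_noise_features < 0:
            raise ConfigurationError("n_noise_features must be >= 0")
        if self.cultivar_means is not None and (self.cultivar_means.values < 0).any():
            raise ConfigurationError("cultivar_means must be non-negative")

    def resolved_means(self) -> pd.DataFrame:
        if self.cultivar_means is not None:
            return self.cultivar_means
        return _draw_default_means(self.n_cultivars, self.seed)


def default_config(**overrides) -> SimulationConfig:
    """The study-scale configuration (18 × 2 × 3) with documented defaults."""
    return replace(SimulationConfig(), **overrides) if overrides else SimulationConfig()


def _draw_default_means(n_cultivars: int, seed: int) -> pd.DataFrame:
    """Per-cultivar metabolite means from the documented compositional ranges.

    Class totals are uniform over anthocyanins 14–114, hydroxycinnamic acids
    10–65, quercetins 1–7 and ascorbic acid 7–15 mg/100 g, then split among
    class members at fixed within-class proportions (rutinosides dominate).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0FFEE)))
    totals = {
        "anthocyanin": rng.uniform(14.0, 114.0, n_cultivars),
        "hydroxycinnamic_acid": rng.uniform(10.0, 65.0, n_cultivars),
        "quercetin": rng.uniform(1.0, 7.0, n_cultivars),
        "ascorbic_acid": rng.uniform(7.0, 15.0, n_cultivars),
    }
    split = {
        "neochlorogenic_acid": 0.45,
        "chlorogenic_acid": 0.35,
        "coumaroyl_quinic_acid": 0.20,
        "cyanidin_3_glucoside": 0.20,
        "cyanidin_3_rutinoside": 0.80,
        "quercetin_3_rutinoside": 0.70,
        "quercetin_3_glucoside": 0.30,
        "ascorbic_acid": 1.00,
    }
    cultivars = [f"cv{i+1:02d}" for i in range(n_cultivars)]
    data = {
        met: totals[cls] * split[met] for met, cls in METABOLITE_CLASSES.items()
    }
    return pd.DataFrame(data, index=pd.Index(cultivars, name="cultivar"))


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal noise with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_metabolite_table(config: SimulationConfig) -> pd.DataFrame:
    """Targeted concentration table for the full cultivar × vintage × replicate design.

    Each concentration is cultivar mean × vintage multiplier × lognormal
    replicate noise, truncated at zero.  The vintage multiplier is a shared
    shift per metabolite class and vintage (weak vintage effect); replicate
    noise has unit mean so large-replicate averages recover the cultivar
    means.  Columns: sample_id, cultivar, vintage, replicate, then one column
    per metabolite (mg/100 g fw).
    """
    means = config.resolved_means()
    metabolites = list(means.columns)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    vintages = [2014 + v for v in range(config.n_vintages)]
    classes = [METABOLITE_CLASSES.get(m, "other") for m in metabolites]
    uniq_classes = sorted(set(classes))
    # shared multiplicative vintage shift per (vintage, class)
    shift = {
        (v, cls): float(_lognormal_multiplier(rng, config.vintage_shift_sd, ()))
        for v in vintages
        for cls in uniq_classes
    }
    rows = []
    values = []
    for cultivar in means.index:
        mu = means.loc[cultivar].to_numpy(dtype=float)
        for v in vintages:
            vint_mult = np.array([shift[(v, cls)] for cls in classes])
            for r in range(1, config.n_replicates + 1):
                noise = _lognormal_multiplier(rng, config.replicate_cv, len(metabolites))
                conc = np.maximum(mu * vint_mult * noise, 0.0)
                rows.append((f"{cultivar}_{v}_r{r}", cultivar, v, r))
                values.append(conc)
    labels = pd.DataFrame(rows, columns=LABEL_COLS)
    table = pd.concat(
        [labels, pd.DataFrame(values, columns=metabolites)], axis=1
    )
    return table


def metabolite_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in LABEL_COLS]


def generate_responses(
    table: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-sample antioxidant responses (mmol TE/kg).

    TEAC_i = intercept + Σ_j β_j c_ij + Σ_(j,k) γ_jk c_ij c_ik + ε_i with
    ε ~ N(0, response_noise_sd²).  Coefficients must reference metabolites
    present in the table.
    """
    mets = metabolite_columns(table)
    bad = [m for m in config.response_coefficients if m not in mets]
    bad += [m for pair in config.synergy_terms for m in pair[:2] if m not in mets]
    if bad:
        raise SchemaError(f"response coefficients reference unknown metabolites: {sorted(set(bad))}")
    conc = table[mets]
    teac = np.full(len(table), float(config.response_intercept))
    for met, beta in config.response_coefficients.items():
        teac = teac + beta * conc[met].to_numpy(dtype=float)
    for met_i, met_j, gamma in config.synergy_terms:
        teac = teac + gamma * conc[met_i].to_numpy(dtype=float) * conc[met_j].to_numpy(dtype=float)
    if config.response_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
        teac = teac + rng.normal(0.0, config.response_noise_sd, len(table))
    return pd.DataFrame(
        {"sample_id": table["sample_id"].to_numpy(), "teac": teac}
    )


@dataclass
class FeatureMatrix:
    """Untargeted LC-MS feature matrix.

    ``features``: feature_id, mz, rt, annotation (one row per feature);
    ``samples``: the label columns of the generating metabolite table;
    ``values``: samples × features peak areas (index = sample_id).
    ``true_intensity_factors`` records the injected per-sample global
    intensity factors so normalization can be checked against ground truth.
    """

    features: pd.DataFrame
    samples: pd.DataFrame
    values: pd.DataFrame
    true_intensity_factors: pd.Series | None = None


def generate_feature_matrix(
    table: pd.DataFrame, config: SimulationConfig
) -> FeatureMatrix:
    """Expand a metabolite table into correlated m/z features plus noise features.

    Each metabolite yields a monoisotopic feature, a +1 isotope at
    ``isotope_fraction`` of its area and (if ``adduct_fraction`` > 0) an
    adduct feature.  All features of a sample share one lognormal global
    intensity factor (instrument drift); noise features carry no cultivar
    effect.  Multiplicative measurement noise with CV ``feature_noise_cv``
    applies to every value.
    """
    if len(table) == 0:
        raise ConfigurationError("metabolite table is empty")
    mets = metabolite_columns(table)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    n = len(table)

    feat_rows: list[tuple[str, float, float, str]] = []
    base_cols: list[np.ndarray] = []
    ion_yield = 1000.0  # area units per mg/100 g
    for met in mets:
        mz, rt = _MZ_RT.get(met, (100.0 + 50.0 * len(feat_rows), 5.0))
        conc = table[met].to_numpy(dtype=float)
        area = conc * ion_yield
        feat_rows.append((f"{met}|M", mz, rt, met))
        base_cols.append(area)
        if config.isotope_fraction > 0:
            feat_rows.append((f"{met}|M+1", mz + _ISOTOPE_DELTA, rt, met))
            base_cols.append(area * config.isotope_fraction)
        if config.adduct_fraction > 0:
            feat_rows.append((f"{met}|adduct", mz + _ADDUCT_DELTA, rt, met))
            base_cols.append(area * config.adduct_fraction)
    for k in range(config.n_noise_features):
        mz = float(rng.uniform(150.0, 800.0))
        rt = float(rng.uniform(0.5, 15.0))
        level = float(rng.lognormal(np.log(5000.0), 0.5))
        col = level * _lognormal_multiplier(rng, config.noise_feature_cv, n)
        feat_rows.append((f"noise{k+1:03d}", mz, rt, ""))
        base_cols.append(col)

    base = np.column_stack(base_cols)
    factors = _lognormal_multiplier(rng, _sd_to_cv(config.intensity_factor_sd), n)
    noise = _lognormal_multiplier(rng, config.feature_noise_cv, base.shape)
    values = base * factors[:, None] * noise

    features = pd.DataFrame(
        feat_rows, columns=["feature_id", "mz", "rt", "annotation"]
    )
    sample_ids = table["sample_id"].to_numpy()
    return FeatureMatrix(
        features=features,
        samples=table[LABEL_COLS].copy(),
        values=pd.DataFrame(
            values, index=pd.Index(sample_ids, name="sample_id"),
            columns=features["feature_id"].to_list(),
        ),
        true_intensity_factors=pd.Series(factors, index=sample_ids, name="factor"),
    )


def _sd_to_cv(sd: float) -> float:
    """Lognormal sigma parameter -> coefficient of variation."""
    return float(np.sqrt(np.expm1(sd**2)))


DEFAULT_TROLOX_STANDARDS_MM = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.0)


def simulate_assay_plate(
    true_teac: pd.Series | Mapping[str, float],
    curve: CalibrationCurve,
    protocol: ExtractionProtocol,
    n_wells: int = 3,
    noise_sd: float = 0.0,
    trolox_standards_mM: Sequence[float] = DEFAULT_TROLOX_STANDARDS_MM,
    seed: int = 0,
) -> pd.DataFrame:
    """Inverse of the assay readout: absorbances implied by true TEACs.

    For each sample the diluted-extract Trolox-equivalent concentration is
    ``teac / (dilution_factor × solvent_volumes)`` and its well absorbance is
    ``intercept + slope × concentration + N(0, noise_sd²)``, replicated over
    ``n_wells``.  Trolox standard wells at the stated serial dilutions are
    included so the plate is self-calibrating.

    Long-format columns: sample_id, role ('sample'|'standard'),
    trolox_mM (standards only), replicate, absorbance.
    """
    if curve.slope <= 0:
        raise ValueError("curve slope must be > 0 to simulate a readable plate")
    teacs = pd.Series(dict(true_teac)) if not isinstance(true_teac, pd.Series) else true_teac
    if (teacs < 0).any():
        bad = teacs[teacs < 0].index.tolist()
        raise DomainError(f"negative true TEAC for samples: {bad}")
    rng = np.random.default_rng(seed)
    rows = []
    for conc in trolox_standards_mM:
        for r in range(1, n_wells + 1):
            a = curve.signal(conc) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((f"std_{conc:g}mM", "standard", conc, r, a))
    scale = protocol.concentration_scale
    for sid, teac in teacs.items():
        conc = teac / scale
        for r in range(1, n_wells + 1):
            a = curve.signal(conc) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((sid, "sample", np.nan, r, a))
    return pd.DataFrame(
        rows, columns=["sample_id", "role", "trolox_mM", "replicate", "absorbance"]
    )


def generate_planted_regression(
    n_cultivars: int = 18,
    n_replicates: int = 3,
    n_informative: int = 3,
    n_noise: int = 20,
    beta: float = 1.0,
    target_r2: float = 0.7,
    replicate_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Cultivar-structured regression problem with known informative variables.

    Variables have cultivar-level means N(0,1) shared by the replicates of a
    cultivar plus replicate noise N(0, replicate_sd²).  The response is
    ``Σ β x_j`` over the informative variables plus Gaussian noise scaled so
    the population R² equals ``target_r2``.  Returns (X, y, informative
    variable names) — the generating truth for selection benchmarks.
    """
    if not (0 < target_r2 < 1):
        raise ConfigurationError("target_r2 must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    n = n_cultivars * n_replicates
    p = n_informative + n_noise
    mu = rng.normal(0.0, 1.0, (n_cultivars, p))
    X = np.repeat(mu, n_replicates, axis=0) + rng.normal(0.0, replicate_sd, (n, p))
    names = [f"v{j+1:02d}" for j in range(p)]
    informative = names[:n_informative]
    signal = beta * X[:, :n_informative].sum(axis=1)
    sig_var = beta**2 * n_informative * (1.0 + replicate_sd**2)
    noise_sd = float(np.sqrt(sig_var * (1.0 - target_r2) / target_r2))
    y = signal + rng.normal(0.0, noise_sd, n)
    idx = pd.Index(
        [f"cv{c+1:02d}_r{r+1}" for c in range(n_cultivars) for r in range(n_replicates)],
        name="sample_id",
    )
    return (
        pd.DataFrame(X, index=idx, columns=names),
        pd.Series(y, index=idx, name="y"),
        informative,
    )


# ---------------------------------------------------------------------------
# phytocomplex depletion panels


def mixture_teac(
    concentrations: Mapping[str, float],
    unit_activities: Mapping[str, float],
    synergy_terms: Sequence[tuple[str, str, float]] = (),
) -> float:
    """True TEAC of a reconstituted mixture.

    ``Σ_j ua_j c_j + Σ_(j,k) γ_jk c_j c_k`` — the additive part plus pairwise
    interactions.  Components absent from the mixture contribute nothing, so
    any interaction involving a removed component vanishes automatically.
    """
    teac = 0.0
    for comp, conc in concentrations.items():
        if comp not in unit_activities:
            raise SchemaError(f"no unit activity for component {comp!r}")
        teac += unit_activities[comp] * conc
    for ci, cj, gamma in synergy_terms:
        teac += gamma * concentrations.get(ci, 0.0) * concentrations.get(cj, 0.0)
    return teac


def simulate_depletion_panel(
    design_name: str,
    composition: Mapping[str, float],
    component_classes: Mapping[str, str],
    unit_activities: Mapping[str, float],
    synergy_terms: Sequence[tuple[str, str, float]],
    curve: CalibrationCurve,
    protocol: ExtractionProtocol,
    classes_to_test: Sequence[str] | None = None,
    natural_extract_teac: float | None = None,
    noise_sd: float = 0.0,
    n_wells: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full/depleted/isolated phytocomplex experiment.

    Builds the design table (one row per compound per condition) and the
    corresponding assay plate.  Conditions generated: ``full``, and for each
    tested class ``depleted:<class>`` (full minus that class) and
    ``isolated:<class>`` (that class alone); optionally a ``natural_extract``
    pseudo-condition whose TEAC is supplied rather than composed.
    """
    classes = sorted(set(component_classes[c] for c in composition))
    if classes_to_test is None:
        classes_to_test = classes
    conditions: dict[str, dict[str, float]] = {"full": dict(composition)}
    for cls in classes_to_test:
        members = {c: v for c, v in composition.items() if component_classes[c] == cls}
        if not members:
            raise ConfigurationError(f"class {cls!r} absent from composition")
        conditions[f"depleted:{cls}"] = {
            c: v for c, v in composition.items() if component_classes[c] != cls
        }
        conditions[f"isolated:{cls}"] = members

    design_rows = []
    true_teacs: dict[str, float] = {}
    for cond, comps in conditions.items():
        sid = f"{design_name}|{cond}"
        true_teacs[sid] = mixture_teac(comps, unit_activities, synergy_terms)
        for comp, conc in comps.items():
            design_rows.append(
                (design_name, cond, comp, component_classes[comp], conc)
            )
    if natural_extract_teac is not None:
        sid = f"{design_name}|natural_extract"
        true_teacs[sid] = float(natural_extract_teac)
        design_rows.append((design_name, "natural_extract", "extract", "extract", np.nan))

    designs = pd.DataFrame(
        design_rows,
        columns=["design", "condition", "compound", "class", "concentration_mg_per_ml"],
    )
    plate = simulate_assay_plate(
        pd.Series(true_teacs), curve, protocol,
        n_wells=n_wells, noise_sd=noise_sd, seed=seed,
    )
    return designs, plate
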
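"""Additive-versus-synergistic analysis of artificial simplified phytocomplexes.

A reconstituted phytocomplex (authentic standards mixed at extract-matched
concentrations) is assayed intact ("full"), with one metabolite class removed
("depleted"), and as the removed class alone ("isolated").  Under pure
additivity the activity lost on depletion equals the activity of the
isolated class; a loss exceeding the isolated activity indicates synergy,
a smaller loss antagonism.  The synergy index is

    index = (TEAC_full − TEAC_depleted) − TEAC_component

in mmol TE/kg.  Uncertainty comes from a parametric bootstrap on the three
condition means (Normal with the observed sd/√n — with n = 3 replicates a
nonparametric bootstrap would be degenerate); the classification follows the
sign of the bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    ExtractionProtocol,
    TEACResult,
    teac_from_absorbance,
)
from .errors import DesignError, DomainError, InsufficientReplicationError, SchemaError

__all__ = [
    "SynergyAssessment",
    "expected_additive_teac",
    "assess_depletion",
    "coverage_fraction",
    "run_depletion_panel",
]


@dataclass
class SynergyAssessment:
    """Depletion-experiment verdict for one metabolite class."""

    class_tested: str
    teac_full: TEACResult
    teac_depleted: TEACResult
    teac_component: TEACResult
    loss: float
    synergy_index: float
    interaction_ratio: float
    classification: str  # additive | synergistic | antagonistic
    p_value: float
    ci: tuple[float, float]
    alpha: float = 0.05
    design: str = ""

    def to_row(self) -> dict:
        return {
            "design": self.design,
            "class_tested": self.class_tested,
            "teac_full": self.teac_full.teac,
            "teac_depleted": self.teac_depleted.teac,
            "teac_component": self.teac_component.teac,
            "loss": self.loss,
            "synergy_index": self.synergy_index,
            "interaction_ratio": self.interaction_ratio,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "p_value": self.p_value,
            "classification": self.classification,
        }


def expected_additive_teac(
    components: list[tuple[str, float, float | None]]
) -> float:
    """Additive expectation: Σ unit activity × concentration.

    ``components`` holds (name, concentration, TEAC per concentration unit);
    a missing unit activity is a schema error.
    """
    total = 0.0
    for name, conc, unit_activity in components:
        if unit_activity is None or (isinstance(unit_activity, float) and np.isnan(unit_activity)):
            raise SchemaError(f"missing unit activity for component {name!r}")
        total += unit_activity * conc
    return total


def _check_replicates(result: TEACResult, label: str) -> None:
    if result.n < 2:
        raise InsufficientReplicationError(
            f"{label} condition has {result.n} replicate(s); >= 2 required"
        )


def _bootstrap_index(
    full: TEACResult, depleted: TEACResult, component: TEACResult,
    n_boot: int, rng: np.random.Generator,
) -> np.ndarray:
    draws = []
    for res, sign in ((full, 1.0), (depleted, -1.0), (component, -1.0)):
        se = res.sd / np.sqrt(res.n)
        draws.append(sign * rng.normal(res.teac, se, n_boot))
    return draws[0] + draws[1] + draws[2]


def assess_depletion(
    full: TEACResult,
    depleted: TEACResult,
    component: TEACResult,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    class_tested: str = "",
    design: str = "",
) -> SynergyAssessment:
    """Classify one class's interaction from its depletion triple.

    The point estimate of the synergy index uses the condition means; the
    central (1−alpha) bootstrap interval of the index drives the
    classification: synergistic iff its lower bound is above 0, antagonistic
    iff its upper bound is below 0, additive otherwise.  The p-value is the
    (+1-corrected) two-sided bootstrap probability of a sign reversal.
    """
    for res, label in ((full, "full"), (depleted, "depleted"), (component, "component")):
        _check_replicates(res, label)
    loss = full.teac - depleted.teac
    index = loss - component.teac
    ratio = loss / component.teac if component.teac != 0 else float("inf")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5E6)))
    draws = _bootstrap_index(full, depleted, component, n_boot, rng)
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    # numerical guard: an exactly-additive zero-noise triple leaves a
    # rounding-level residual index that must not register as an interaction
    tol = 1e-9 * max(1.0, abs(full.teac))
    if lo > tol:
        classification = "synergistic"
    elif hi < -tol:
        classification = "antagonistic"
    else:
        classification = "additive"
    p_low = (1 + int((draws <= 0).sum())) / (n_boot + 1)
    p_high = (1 + int((draws >= 0).sum())) / (n_boot + 1)
    p_value = min(1.0, 2.0 * min(p_low, p_high))
    return SynergyAssessment(
        class_tested=class_tested,
        teac_full=full,
        teac_depleted=depleted,
        teac_component=component,
        loss=loss,
        synergy_index=index,
        interaction_ratio=ratio,
        classification=classification,
        p_value=p_value,
        ci=(float(lo), float(hi)),
        alpha=alpha,
        design=design,
    )


def coverage_fraction(
    asp: TEACResult,
    natural: TEACResult,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Fraction of the natural extract's activity covered by the reconstituted
    phytocomplex, with a parametric bootstrap interval on the ratio."""
    if natural.teac <= 0:
        raise DomainError(f"natural extract mean must be > 0, got {natural.teac}")
    frac = asp.teac / natural.teac
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC0E)))
    a = rng.normal(asp.teac, asp.sd / np.sqrt(max(asp.n, 1)), n_boot)
    b = rng.normal(natural.teac, natural.sd / np.sqrt(max(natural.n, 1)), n_boot)
    ok = b > 0
    ratios = a[ok] / b[ok] if ok.any() else np.array([frac])
    lo, hi = np.quantile(ratios, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(frac), (float(lo), float(hi))


def _condition_teacs(
    designs: pd.DataFrame,
    plates: pd.DataFrame,
    curve: CalibrationCurve,
    protocol: ExtractionProtocol,
) -> dict[tuple[str, str], TEACResult]:
    teacs: dict[tuple[str, str], TEACResult] = {}
    samples = plates[plates["role"] == "sample"] if "role" in plates.columns else plates
    for (design, cond) in designs[["design", "condition"]].drop_duplicates().itertuples(index=False):
        sid = f"{design}|{cond}"
        wells = samples[samples["sample_id"] == sid]
        if len(wells) == 0:
            raise DesignError(f"no plate wells for {sid!r}")
        teacs[(design, cond)] = teac_from_absorbance(
            wells["absorbance"].to_list(), curve, protocol, sample_id=sid
        )
    return teacs


def run_depletion_panel(
    designs: pd.DataFrame,
    plates: pd.DataFrame,
    curve: CalibrationCurve,
    protocol: ExtractionProtocol,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[SynergyAssessment]:
    """Assess every (full, depleted:class, isolated:class) triple in a panel.

    ``designs`` is the long composition table (design, condition, compound,
    class, concentration_mg_per_ml); ``plates`` the long absorbance table
    whose sample ids are ``"<design>|<condition>"``.  Each design is assessed
    against its own ``full`` condition, so a design whose full baseline is
    itself a depleted mixture (nested depletion) is handled like any other.
    """
    required = {"design", "condition", "compound", "class", "concentration_mg_per_ml"}
    missing = required - set(designs.columns)
    if missing:
        raise SchemaError(f"designs table missing columns: {sorted(missing)}")
    teacs = _condition_teacs(designs, plates, curve, protocol)
    out: list[SynergyAssessment] = []
    boot_counter = 0
    for design in designs["design"].unique():
        conds = set(
            designs.loc[designs["design"] == design, "condition"].unique()
        )
        classes = sorted(
            c.split(":", 1)[1] for c in conds if c.startswith("depleted:")
        )
        for cls in classes:
            for member in ("full", f"depleted:{cls}", f"isolated:{cls}"):
                if member not in conds:
                    raise DesignError(
                        f"design {design!r} lacks condition {member!r} needed "
                        f"to assess class {cls!r}"
                    )
            out.append(
                assess_depletion(
                    teacs[(design, "full")],
                    teacs[(design, f"depleted:{cls}")],
                    teacs[(design, f"isolated:{cls}")],
                    n_boot=n_boot,
                    alpha=alpha,
                    seed=seed + boot_counter,
                    class_tested=cls,
                    design=str(design),
                )
            )
            boot_counter += 1
    return out
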
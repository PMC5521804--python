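"""Standard-curve calibration and Trolox-equivalent conversion.

Plate-reader antioxidant assays (FRAP read at 593 nm, ABTS at 734 nm) report
raw absorbances.  A linear standard curve built from serial dilutions of
Trolox maps absorbance to a Trolox concentration in the assay well; extraction
arithmetic (powder mass, solvent volumes, dilution) then converts that
concentration into a Trolox-equivalent antioxidant capacity (TEAC) of the
original material, expressed in mmol Trolox equivalents per kg.

The same machinery quantifies HPLC peak areas against authentic-standard
curves (possibly shared "equivalents" curves, e.g. glycosides quantified as
cyanidin-3-O-glucoside equivalents), returning mg per 100 g fresh weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, DegenerateDesignError, SchemaError

__all__ = [
    "CalibrationCurve",
    "ExtractionProtocol",
    "TEACResult",
    "fit_standard_curve",
    "teac_from_absorbance",
    "quantify_peak_areas",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve: signal = intercept + slope * concentration.

    ``levels`` keeps the (concentration, signal) pairs the curve was fitted
    on; ``wavelength`` is metadata only.
    """

    analyte: str
    wavelength: float
    slope: float
    intercept: float
    r_squared: float
    levels: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")

    def signal(self, concentration: float) -> float:
        return self.intercept + self.slope * concentration

    def invert(self, signal: float) -> float:
        """Concentration implied by a signal; requires a positive slope."""
        if self.slope <= 0:
            raise CalibrationError(
                f"curve for {self.analyte!r} has non-positive slope {self.slope}"
            )
        return (signal - self.intercept) / self.slope

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationCurve":
        d = json.loads(text)
        d["levels"] = tuple(tuple(lv) for lv in d.get("levels", ()))
        return cls(**d)


@dataclass(frozen=True)
class ExtractionProtocol:
    """Extraction and plating arithmetic.

    powder_mass
        grams of material extracted.
    solvent_volumes
        extraction volume as a multiple of the powder mass (ml per g), e.g.
        9 for "nine volumes" of solvent.
    dilution_factor
        total dilution of the extract before plating (1 = undiluted).
    aliquot_volume / assay_volume
        µl of diluted extract added to the well and total well volume;
        recorded for provenance, not used in the mmol/kg conversion because
        the standard curve is built under identical plating.
    """

    powder_mass: float = 0.150
    solvent_volumes: float = 9.0
    dilution_factor: float = 5.0
    aliquot_volume: float = 20.0
    assay_volume: float = 220.0

    def __post_init__(self) -> None:
        for name in ("powder_mass", "solvent_volumes", "dilution_factor",
                     "aliquot_volume", "assay_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def concentration_scale(self) -> float:
        """Factor converting well-equivalent concentration (mM) to mmol/kg.

        Extract volume is ``solvent_volumes × powder_mass`` ml, so the amount
        of Trolox equivalents per kg of powder is
        ``c_mM × dilution_factor × solvent_volumes`` — the powder mass cancels.
        """
        return self.dilution_factor * self.solvent_volumes


@dataclass
class TEACResult:
    """Trolox-equivalent antioxidant capacity of one sample.

    ``teac`` is the mean of ``replicate_values`` (mmol TE/kg); ``sd`` their
    sample standard deviation.  ``clamped`` flags replicates whose signal fell
    below the blank and were clamped to zero.
    """

    sample_id: str
    assay: str
    teac: float
    replicate_values: list[float] = field(default_factory=list)
    sd: float = 0.0
    unit: str = "mmol TE/kg"
    clamped: bool = False

    @property
    def n(self) -> int:
        return len(self.replicate_values)


def fit_standard_curve(
    levels: Sequence[tuple[float, float]],
    analyte: str = "trolox",
    wavelength: float = float("nan"),
) -> CalibrationCurve:
    """Ordinary least squares line through (concentration, signal) pairs.

    Requires at least two distinct concentration levels; the intercept is
    free (not forced through the origin) so that non-zero blanks are
    absorbed by the fit.
    """
    pairs = [(float(c), float(s)) for c, s in levels]
    conc = np.array([c for c, _ in pairs])
    sig = np.array([s for _, s in pairs])
    if np.unique(conc).size < 2:
        raise DegenerateDesignError(
            f"standard curve for {analyte!r} needs >= 2 distinct concentrations"
        )
    res = stats.linregress(conc, sig)
    # rvalue is nan when the signal is constant; a flat line is a perfect fit
    # of a zero-slope curve, so report r² = 0 variance explained.
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return CalibrationCurve(
        analyte=analyte,
        wavelength=float(wavelength),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        levels=tuple(pairs),
    )


def teac_from_absorbance(
    absorbances: Sequence[float],
    curve: CalibrationCurve,
    protocol: ExtractionProtocol,
    sample_id: str = "",
    assay: str = "FRAP",
) -> TEACResult:
    """Convert replicate absorbances into a TEAC in mmol TE/kg.

    Each replicate maps through the inverted standard curve to a Trolox
    concentration, then scales by the extraction arithmetic.  Replicates
    below the blank (signal < intercept) clamp to zero and set the
    ``clamped`` flag rather than erroring: small negatives are routine plate
    noise.
    """
    if curve.slope <= 0:
        raise CalibrationError(
            f"cannot invert curve for {curve.analyte!r}: slope {curve.slope} <= 0"
        )
    scale = protocol.concentration_scale
    values: list[float] = []
    clamped = False
    for a in absorbances:
        conc = curve.invert(float(a))
        if conc < 0:
            conc = 0.0
            clamped = True
        values.append(conc * scale)
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return TEACResult(
        sample_id=sample_id,
        assay=assay,
        teac=float(arr.mean()),
        replicate_values=values,
        sd=sd,
        clamped=clamped,
    )


def quantify_peak_areas(
    areas: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    protocol: ExtractionProtocol,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Quantify integrated peak areas as mg per 100 g fresh weight.

    ``areas`` is samples × analytes (index = sample_id).  ``curves`` maps each
    analyte column to its standard curve; several analytes may share one
    curve (the "equivalents" convention).  Returns the concentration table
    and a per-analyte record of the curve actually used.

    The curve is assumed to map extract concentration in mg/l (at the plated
    dilution) to signal, so mg per 100 g fresh weight is
    ``(area − intercept)/slope × dilution_factor × solvent_volumes / 10``.
    """
    missing = [c for c in areas.columns if c not in curves]
    if missing:
        raise SchemaError(f"no calibration curve mapped for analytes: {missing}")
    scale = protocol.concentration_scale / 10.0  # mg/kg -> mg/100 g
    out = {}
    basis: dict[str, str] = {}
    for analyte in areas.columns:
        curve = curves[analyte]
        conc = (areas[analyte].astype(float) - curve.intercept) / curve.slope
        out[analyte] = np.maximum(conc, 0.0) * scale
        basis[analyte] = curve.analyte
    table = pd.DataFrame(out, index=areas.index)
    return table, basis
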
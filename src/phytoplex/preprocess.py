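"""Matrix preprocessing: median fold change normalization, log transform,
mean centering, and assembly of the modelling matrix X and response y.

Median fold change normalization removes per-sample global intensity
differences (injection volume, instrument drift): each sample is divided by
the median, over features, of its fold change relative to a reference
profile.  The reference defaults to the feature-wise median across samples;
passing a previously returned reference makes the operation exactly
idempotent (the median of ratios is scale-equivariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, NormalizationError
from .simulate import FeatureMatrix, metabolite_columns

logger = logging.getLogger("phytoplex")

__all__ = [
    "ModelMatrix",
    "median_fold_change_normalize",
    "log_mean_center",
    "build_model_inputs",
]


@dataclass
class ModelMatrix:
    """Modelling-ready matrix with provenance of the transforms applied."""

    X: pd.DataFrame
    y: pd.Series | None = None
    transform_log: bool = False
    pseudo: float = 0.0
    centered: bool = False
    column_means: pd.Series | None = None
    normalization_factors: pd.Series | None = None
    y_transform: str = "identity"
    dropped_samples: list[str] = field(default_factory=list)


def _values_frame(matrix: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values
    return matrix


def median_fold_change_normalize(
    matrix: FeatureMatrix | pd.DataFrame,
    reference: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Divide each sample by its median fold change to the reference profile.

    The per-sample factor is the median of value/reference over features
    positive in both the sample and the reference; zeros are excluded rather
    than pseudo-counted so the factor stays scale-free.  Returns
    ``(normalized, factors, reference)``; re-normalizing the output against
    the same returned reference gives factors identically 1.
    """
    values = _values_frame(matrix)
    if len(values) < 2:
        raise NormalizationError("median fold change needs >= 2 samples")
    if reference is None:
        reference = values.median(axis=0)
    ref = reference.to_numpy(dtype=float)
    if not (ref > 0).any():
        raise NormalizationError("reference profile has no positive feature")
    V = values.to_numpy(dtype=float)
    factors = np.empty(len(values))
    for i, sid in enumerate(values.index):
        mask = (V[i] > 0) & (ref > 0)
        if not mask.any():
            raise NormalizationError(
                f"sample {sid!r} shares no positive feature with the reference"
            )
        factors[i] = np.median(V[i, mask] / ref[mask])
    fac = pd.Series(factors, index=values.index, name="factor")
    normalized = values.div(fac, axis=0)
    return normalized, fac, reference


def log_mean_center(
    matrix: FeatureMatrix | pd.DataFrame,
    pseudo: float = 1.0,
    log: bool = True,
) -> ModelMatrix:
    """log(value + pseudo) followed by column mean-centering.

    Natural log (the base is irrelevant after centering); set ``log=False``
    for targeted concentration tables that are centered without transform.
    """
    values = _values_frame(matrix)
    X = np.log(values.to_numpy(dtype=float) + pseudo) if log else values.to_numpy(dtype=float)
    means = X.mean(axis=0)
    Xc = pd.DataFrame(X - means, index=values.index, columns=values.columns)
    return ModelMatrix(
        X=Xc,
        transform_log=log,
        pseudo=pseudo if log else 0.0,
        centered=True,
        column_means=pd.Series(means, index=values.columns),
    )


def build_model_inputs(
    matrix: FeatureMatrix | pd.DataFrame | ModelMatrix,
    responses: pd.DataFrame,
    response_transform: str = "identity",
    response_col: str = "teac",
) -> ModelMatrix:
    """Align a (possibly transformed) matrix with a response table.

    ``responses`` needs columns sample_id and ``response_col``.  Samples
    missing from either side are dropped (recorded in ``dropped_samples``);
    an empty intersection is an alignment error.  ``response_transform`` may
    be ``identity`` or ``log10`` (the convention for FRAP responses).
    """
    if response_transform not in ("identity", "log10"):
        raise ValueError(f"unknown response_transform {response_transform!r}")
    if isinstance(matrix, ModelMatrix):
        X = matrix.X
        base = matrix
    else:
        values = _values_frame(matrix)
        if isinstance(matrix, pd.DataFrame) and "sample_id" in matrix.columns:
            values = matrix.set_index("sample_id")[metabolite_columns(matrix)]
        X = values
        base = None
    y = responses.set_index("sample_id")[response_col].astype(float)
    common = X.index.intersection(y.index)
    if len(common) == 0:
        raise AlignmentError("no samples shared between matrix and responses")
    dropped = sorted(set(X.index).symmetric_difference(y.index))
    if dropped:
        logger.info("build_model_inputs: dropped %d unmatched sample(s)", len(dropped))
    Xa = X.loc[common]
    ya = y.loc[common]
    if response_transform == "log10":
        ya = np.log10(ya)
    ya = pd.Series(ya, index=common, name=response_col)
    return ModelMatrix(
        X=Xa,
        y=ya,
        transform_log=base.transform_log if base else False,
        pseudo=base.pseudo if base else 0.0,
        centered=base.centered if base else False,
        column_means=base.column_means if base else None,
        normalization_factors=base.normalization_factors if base else None,
        y_transform=response_transform,
        dropped_samples=[str(s) for s in dropped],
    )
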
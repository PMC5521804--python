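"""End-to-end pipeline driver: simulate → calibrate → normalize → model →
stability → synergy → report.

One master seed fans out deterministically to per-stage seeds, and the
resolved configuration is written next to the outputs, so a run is exactly
replayable from its output directory.  The report bundle (CSV/JSON) contains
no timestamps; wall-clock information goes to the log only.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .calibration import ExtractionProtocol, fit_standard_curve, teac_from_absorbance
from .errors import DesignError, PhytoplexError
from .pls import pca, permutation_test, select_by_vip
from .preprocess import build_model_inputs, log_mean_center, median_fold_change_normalize
from .simulate import (
    DEFAULT_TROLOX_STANDARDS_MM,
    SimulationConfig,
    generate_feature_matrix,
    generate_metabolite_table,
    generate_responses,
    simulate_assay_plate,
    simulate_depletion_panel,
)
from .stability import stability_select_pls
from .synergy import run_depletion_panel

logger = logging.getLogger("phytoplex")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("simulate", "calibrate", "normalize", "model", "stability", "synergy")


@dataclass
class PipelineConfig:
    """All pipeline knobs in one place; unknown YAML keys are rejected."""

    out_dir: str = "phytoplex_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # simulation
    n_cultivars: int = 18
    n_vintages: int = 2
    n_replicates: int = 3
    replicate_cv: float = 0.10
    vintage_shift_sd: float = 0.05
    n_noise_features: int = 104
    response_noise_sd: float = 0.5
    # assay
    assay_noise_sd: float = 0.005
    # modelling
    folds: int = 7
    max_components: int = 5
    n_perm: int = 1000
    response_transform: str = "log10"
    # stability selection
    n_subsamples: int = 1000
    inclusion_prob: float = 0.70
    freq_threshold: float = 0.5
    # synergy
    alpha: float = 0.05
    n_boot: int = 10_000
    designs_path: str | None = None
    plates_path: str | None = None
    curve_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        keys = [f.name for f in dataclasses.fields(cls)]
        return cls(**pio.load_yaml_config(path, keys))

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise DesignError(f"unknown stage(s): {unknown}")
        if "synergy" in self.stages and "simulate" not in self.stages:
            if not (self.designs_path and self.plates_path and self.curve_path):
                raise DesignError(
                    "synergy stage needs designs/plates/curve files when the "
                    "simulate stage is disabled"
                )

    def stage_seed(self, stage: str) -> int:
        # deterministic fan-out: one sub-stream per stage index
        idx = _STAGES.index(stage)
        return int(
            np.random.default_rng(np.random.SeedSequence((self.seed, 100 + idx)))
            .integers(2**31)
        )


def _log_stage(stage: str, t0: float, **shapes) -> None:
    desc = ", ".join(f"{k}={v}" for k, v in shapes.items())
    logger.info("stage %-9s %-40s %.2fs", stage, desc, time.perf_counter() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the report bundle.

    Returns the summary report as a dict (also written as report.json).
    A stage failure aborts with the failing stage named; artifacts written
    before the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_json(dataclasses.asdict(config), out / "resolved_config.json")
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    state: dict = {}
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _RUNNERS[stage](config, state, report, out)
        except PhytoplexError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PhytoplexError(f"stage {stage!r} failed: {exc}") from exc
        _log_stage(stage, t0, **state.get("_shapes", {}))
    pio.write_json(report, out / "report.json")
    return report


def _run_simulate(config, state, report, out) -> None:
    sim = SimulationConfig(
        n_cultivars=config.n_cultivars,
        n_vintages=config.n_vintages,
        n_replicates=config.n_replicates,
        replicate_cv=config.replicate_cv,
        vintage_shift_sd=config.vintage_shift_sd,
        n_noise_features=config.n_noise_features,
        response_noise_sd=config.response_noise_sd,
        seed=config.stage_seed("simulate"),
    )
    table = generate_metabolite_table(sim)
    responses = generate_responses(table, sim)
    features = generate_feature_matrix(table, sim)
    curve = fit_standard_curve(
        [(c, 0.05 + 0.5 * c) for c in DEFAULT_TROLOX_STANDARDS_MM],
        analyte="trolox", wavelength=593.0,
    )
    protocol = ExtractionProtocol()
    plate = simulate_assay_plate(
        responses.set_index("sample_id")["teac"], curve, protocol,
        noise_sd=config.assay_noise_sd, seed=sim.seed,
    )
    designs, syn_plate = simulate_depletion_panel(
        design_name="demo",
        composition={"cyanidin_3_rutinoside": 0.8, "quercetin_3_rutinoside": 0.05,
                     "chlorogenic_acid": 0.4, "ascorbic_acid": 0.1},
        component_classes={"cyanidin_3_rutinoside": "anthocyanin",
                           "quercetin_3_rutinoside": "quercetin",
                           "chlorogenic_acid": "hydroxycinnamic_acid",
                           "ascorbic_acid": "ascorbic_acid"},
        unit_activities={"cyanidin_3_rutinoside": 20.0, "quercetin_3_rutinoside": 8.0,
                         "chlorogenic_acid": 5.0, "ascorbic_acid": 15.0},
        synergy_terms=[("cyanidin_3_rutinoside", "quercetin_3_rutinoside", 40.0),
                       ("cyanidin_3_rutinoside", "ascorbic_acid", 30.0)],
        curve=curve, protocol=protocol,
        noise_sd=config.assay_noise_sd, seed=sim.seed + 1,
    )
    state.update(table=table, responses=responses, features=features,
                 curve=curve, protocol=protocol, plate=plate,
                 designs=designs, syn_plate=syn_plate)
    pio.write_table(table, out / "metabolites.csv")
    pio.write_table(responses, out / "responses.csv")
    pio.write_table(plate, out / "plate.csv")
    pio.write_table(designs, out / "designs.csv")
    pio.write_curve(curve, out / "trolox_curve.json")
    state["_shapes"] = {"samples": len(table), "features": len(features.features)}


def _run_calibrate(config, state, report, out) -> None:
    curve = state.get("curve")
    protocol = state.get("protocol", ExtractionProtocol())
    if curve is None:
        curve = pio.read_curve(config.curve_path)
        state["curve"], state["protocol"] = curve, protocol
    plate = state.get("plate")
    if plate is None:
        plate = pio.read_table(config.plates_path, pio.PLATE_SCHEMA)
    samples = plate[plate["role"] == "sample"]
    rows = []
    for sid, grp in samples.groupby("sample_id", sort=False):
        res = teac_from_absorbance(
            grp["absorbance"].to_list(), curve, protocol, sample_id=str(sid)
        )
        rows.append({"sample_id": sid, "teac": res.teac, "sd": res.sd,
                     "n": res.n, "clamped": res.clamped})
    measured = pd.DataFrame(rows)
    state["measured_teac"] = measured
    pio.write_table(measured, out / "measured_teac.csv")
    report["calibration"] = {
        "curve_r_squared": state["curve"].r_squared,
        "n_samples_measured": len(measured),
    }
    state["_shapes"] = {"wells": len(plate), "samples": len(measured)}


def _run_normalize(config, state, report, out) -> None:
    features = state["features"]
    normalized, factors, reference = median_fold_change_normalize(features.values)
    mm = log_mean_center(normalized, pseudo=1.0)
    state["normalized"], state["factors"], state["model_matrix"] = normalized, factors, mm
    pio.write_table(
        factors.rename("factor").rename_axis("sample_id").reset_index(),
        out / "normalization_factors.csv",
    )
    scores, loadings, explained = pca(mm.X, n_components=4)
    report["pca_explained_4pc_percent"] = float(100 * explained.sum())
    state["_shapes"] = {"matrix": mm.X.shape}


def _run_model(config, state, report, out) -> None:
    measured = state.get("measured_teac", state["responses"])
    mm = build_model_inputs(
        state["model_matrix"], measured, response_transform=config.response_transform
    )
    seed = config.stage_seed("model")
    sel = select_by_vip(mm.X, mm.y, folds=config.folds, seed=seed,
                        max_a=config.max_components)
    p = permutation_test(mm.X, mm.y, n_perm=config.n_perm, folds=config.folds,
                         seed=seed, n_components=sel.model.n_components)
    sel.permutation_p = p
    state["model_matrix_y"] = mm
    state["selection"] = sel
    report["model"] = {
        "response_transform": config.response_transform,
        "n_components": sel.model.n_components,
        "r2": sel.model.r2,
        "q2": sel.model.q2,
        "sdecv": sel.model.sdecv,
        "vip_threshold": sel.threshold,
        "n_selected": len(sel.selected),
        "selected": sel.selected,
        "permutation_p": p,
    }
    pio.write_json(sel.model.to_dict(), out / "pls_model.json")
    state["_shapes"] = {"X": mm.X.shape, "A": sel.model.n_components}


def _run_stability(config, state, report, out) -> None:
    mm = state["model_matrix_y"]
    res = stability_select_pls(
        mm.X, mm.y,
        n_subsamples=config.n_subsamples,
        inclusion_prob=config.inclusion_prob,
        freq_threshold=config.freq_threshold,
        seed=config.stage_seed("stability"),
        folds=config.folds,
        max_a=config.max_components,
    )
    state["stability"] = res
    pio.write_table(res.report(), out / "stability_frequencies.csv")
    report["stability"] = {
        "n_subsamples": res.n_subsamples,
        "inclusion_prob": res.inclusion_prob,
        "mean_sdep": res.mean_sdep,
        "n_relevant": len(res.relevant),
        "relevant": res.relevant,
    }
    state["_shapes"] = {"subsamples": res.n_subsamples,
                        "relevant": len(res.relevant)}


def _run_synergy(config, state, report, out) -> None:
    if "designs" in state:
        designs, plates = state["designs"], state["syn_plate"]
        curve, protocol = state["curve"], state["protocol"]
    else:
        designs = pio.read_table(config.designs_path, pio.DESIGN_SCHEMA)
        plates = pio.read_table(config.plates_path, pio.PLATE_SCHEMA)
        curve = pio.read_curve(config.curve_path)
        protocol = state.get("protocol", ExtractionProtocol())
    panel = run_depletion_panel(
        designs, plates, curve, protocol,
        n_boot=config.n_boot, alpha=config.alpha,
        seed=config.stage_seed("synergy"),
    )
    rows = [a.to_row() for a in panel]
    pio.write_table(pd.DataFrame(rows), out / "synergy_assessments.csv")
    report["synergy"] = {
        r["class_tested"]: r["classification"] for r in rows
    }
    state["_shapes"] = {"assessments": len(panel)}


_RUNNERS = {
    "simulate": _run_simulate,
    "calibrate": _run_calibrate,
    "normalize": _run_normalize,
    "model": _run_model,
    "stability": _run_stability,
    "synergy": _run_synergy,
}
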
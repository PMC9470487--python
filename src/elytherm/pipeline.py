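"""End-to-end orchestration: cohort inputs → report tables.

Consumes a directory of spectra, traces, a trial plan and metadata (the
layout :func:`elytherm.simulate.gen_cohort` emits, or any archive arranged
the same way) and produces:

1. the per-specimen × band optics table (R, T, A);
2. the per-specimen × band heating-metrics table (ΔT₅, maxHR);
3. six additive heating models (2 responses × 3 bands) with partial R²;
4. the Pearson correlation table (optics × optics, bands, size);
5. the species-level repeatability table;
6. optionally, the paired elytra-open/closed bootstrap results.

Every run is seed-deterministic and serialises its configuration into the
results bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import heating as hm
from . import spectra as sp
from . import stats as st

__all__ = ["RunConfig", "run_full_analysis", "load_config", "heating_metrics_table"]

log = logging.getLogger("elytherm")

_SEED_OFFSETS = {"repeatability": 101, "paired": 211}


@dataclass
class RunConfig:
    """Validated run configuration; serialized into every results bundle."""

    input_dir: str
    output_dir: str
    seed: int = 0
    quadrature_step_nm: float = 1.0
    dt5_baseline: str = "phase_onset"  # or "cooling_plateau"
    n_boot_repeatability: int = 1000
    n_boot_paired: int = 10_000
    paired_file: str | None = None  # CSV with individual, band, open_dt5, closed_dt5
    bands: Sequence[sp.BandDefinition] = sp.DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.dt5_baseline not in ("phase_onset", "cooling_plateau"):
            raise ValueError("dt5_baseline must be 'phase_onset' or 'cooling_plateau'")
        if self.quadrature_step_nm <= 0:
            raise ValueError("quadrature step must be positive")
        if self.n_boot_repeatability < 0 or self.n_boot_paired < 1:
            raise ValueError("bootstrap counts must be positive")
        if not (0 <= int(self.seed) < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")
        self.bands = tuple(
            b if isinstance(b, sp.BandDefinition) else sp.BandDefinition(**b)
            for b in self.bands
        )

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = [dataclasses.asdict(b) for b in self.bands]
        return d


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from YAML; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def _derived_seed(base: int, name: str) -> int:
    return (int(base) + _SEED_OFFSETS[name]) % (2**31)


# --------------------------------------------------------------------------
# stage helpers
# --------------------------------------------------------------------------

def load_cohort_inputs(input_dir: str | Path, bands: Sequence[sp.BandDefinition]):
    """Read metadata, irradiance, per-band filters, spectra and traces."""
    d = Path(input_dir)
    metadata = pd.read_csv(d / "metadata.csv")
    irr = sp.read_spectrum(d / "irradiance.csv", kind="I")
    filters = {
        b.name: sp.read_spectrum(d / f"filter_{b.name}.csv", kind="F") for b in bands
    }
    plan = hm.read_plan(d / "plan.yml")
    specimens, traces = [], {}
    for sid in metadata["specimen_id"]:
        E = sp.read_spectrum(d / "spectra" / f"{sid}_reflectance.csv", kind="E", label=sid)
        S = sp.read_spectrum(d / "spectra" / f"{sid}_transmittance.csv", kind="S", label=sid)
        specimens.append((sid, E, S))
        trace_path = d / "traces" / f"{sid}.csv"
        if trace_path.exists():
            traces[sid] = hm.read_trace(trace_path)
    return metadata, irr, filters, plan, specimens, traces


def heating_metrics_table(
    traces: dict[str, hm.ThermalTrace],
    plan: hm.TrialPlan,
    dt5_baseline: str = "phase_onset",
) -> pd.DataFrame:
    """Tidy (specimen_id, phase, delta_t5_C, max_hr_C_per_s) table.

    ``dt5_baseline='cooling_plateau'`` replaces the onset temperature with
    the mean of the last three samples of the preceding cooling phase.
    """
    rows = []
    for sid, trace in traces.items():
        try:
            segments = hm.segment_trial(trace, plan)
        except ValueError as exc:
            log.warning("specimen %s skipped: %s", sid, exc)
            continue
        for i, (phase, slc) in enumerate(segments):
            if phase.label == "COOL":
                continue
            metrics = hm.compute_heating_metrics(phase, slc)
            dt5 = metrics.delta_t5_C
            if dt5_baseline == "cooling_plateau" and i > 0:
                prev_phase, prev_slc = segments[i - 1]
                if prev_phase.label == "COOL":
                    plateau = float(np.mean(prev_slc.temps_C[-3:]))
                    dt5 = (metrics.onset_temp_C + metrics.delta_t5_C) - plateau
            rows.append(
                {
                    "specimen_id": sid,
                    "phase": phase.label,
                    "delta_t5_C": dt5,
                    "max_hr_C_per_s": metrics.max_hr_C_per_s,
                    "onset_temp_C": metrics.onset_temp_C,
                }
            )
    return pd.DataFrame(rows)


def _model_table(models: list[st.HeatingModelResult]) -> pd.DataFrame:
    """Report-table shape: one row per model term with partial R²."""
    rows = []
    for m in models:
        for term in ("intercept", "absorptivity", "size", "side"):
            est, se, p = m.coefficients[term]
            rows.append(
                {
                    "response": m.response,
                    "band": m.band,
                    "overall_R2_pct": m.overall_R2,
                    "parameter": term,
                    "partial_R2_pct": m.partial_R2.get(term, float("nan")),
                    "estimate": est,
                    "std_error": se,
                    "p_value": p,
                    "n": m.n,
                }
            )
    return pd.DataFrame(rows)


def correlation_table(
    optics: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlations in the published report shape: transmissivity ×
    reflectivity per band, NIR–VIS per optical property, and size × each
    optical property per band."""
    wide = optics.pivot(index="specimen_id", columns="band")
    size = metadata.set_index("specimen_id")["length_cm"].reindex(wide.index)
    rows = []

    def add(group: str, parameters: str, band: str, x, y):
        res = st.pearson_with_ci(np.asarray(x, float), np.asarray(y, float))
        rows.append(
            {
                "correlation_group": group,
                "parameters": parameters,
                "band": band,
                "pearson_r": res.r,
                "ci_lo": res.ci_95[0],
                "ci_hi": res.ci_95[1],
                "p_value": res.p_value,
                "n": res.n,
            }
        )

    for band in ("TOTAL", "NIR", "VIS"):
        add(
            "optical_properties", "transmissivity_x_reflectivity", band,
            wide[("transmissivity_T", band)], wide[("reflectivity_R", band)],
        )
    for prop, col in (
        ("transmissivity", "transmissivity_T"),
        ("reflectivity", "reflectivity_R"),
        ("absorptivity", "absorptivity_A"),
    ):
        add("NIR_vs_VIS", f"NIR_VIS_{prop}", "-", wide[(col, "NIR")], wide[(col, "VIS")])
    for prop, col in (
        ("reflectivity", "reflectivity_R"),
        ("transmissivity", "transmissivity_T"),
        ("absorptivity", "absorptivity_A"),
    ):
        for band in ("TOTAL", "NIR", "VIS"):
            add("size_x_optical", f"size_x_{prop}", band, size, wide[(col, band)])
    return pd.DataFrame(rows)


def repeatability_table(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    n_boot: int,
    seed: int,
) -> pd.DataFrame:
    """Species-level repeatability of ΔT₅ and maxHR per band."""
    merged = metrics.merge(metadata[["specimen_id", "species"]], on="specimen_id")
    rows = []
    for response, col in (("delta_t5", "delta_t5_C"), ("max_hr", "max_hr_C_per_s")):
        for band in ("TOTAL", "NIR", "VIS"):
            sub = merged[merged["phase"] == band]
            res = st.gaussian_repeatability(
                sub[col].to_numpy(), sub["species"].to_numpy(),
                n_boot=n_boot, seed=seed,
            )
            rows.append(
                {
                    "response": response,
                    "band": band,
                    "R": res.R_point,
                    "ci_lo": res.ci_95[0],
                    "ci_hi": res.ci_95[1],
                    "p_lrt": res.p_lrt,
                    "n_groups": res.n_groups,
                    "n_obs": res.n_obs,
                    "n_boot": res.n_boot,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)


def paired_table(paired: pd.DataFrame, n_boot: int, seed: int) -> pd.DataFrame:
    rows = []
    for band, sub in paired.groupby("band", sort=False):
        res = st.paired_bootstrap_dt(
            sub["open_dt5"].to_numpy(), sub["closed_dt5"].to_numpy(),
            n_boot=n_boot, seed=seed, band=str(band),
        )
        rows.append(
            {
                "band": band,
                "mean_D_C": res.mean_D,
                "ci_lo": res.ci_95[0],
                "ci_hi": res.ci_95[1],
                "n_individuals": res.n_individuals,
                "n_boot": res.n_boot,
                "seed": res.seed,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage; write CSV tables + a JSON bundle; return the bundle.

    Specimens with unreadable or incomplete data are skipped with a logged
    reason; the run fails only if nothing remains.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> dict:
    log.info("config: %s", json.dumps(config.to_jsonable(), sort_keys=True))
    metadata, irr, filters, plan, specimens, traces = load_cohort_inputs(
        config.input_dir, config.bands
    )
    log.info("loaded %d specimens, %d traces", len(specimens), len(traces))
    if not specimens:
        raise ValueError("no specimens found in input directory")

    # 1. optics
    summaries = sp.summarize_optics(
        specimens, irr, filters, config.bands, step_nm=config.quadrature_step_nm
    )
    optics = sp.optics_to_frame(summaries)
    for s in summaries:
        if "out_of_physical_range" in s.qc_flags:
            log.warning("specimen %s band %s: absorptivity outside [0,100]", s.specimen_id, s.band)
    optics.to_csv(out / "optics.csv", index=False)

    # 2. heating metrics (ΔT₅ baseline rule is logged, not silent)
    log.info("ΔT5 baseline rule: %s", config.dt5_baseline)
    metrics = heating_metrics_table(traces, plan, config.dt5_baseline)
    if metrics.empty:
        raise ValueError("no usable heating traces")
    metrics.to_csv(out / "heating_metrics.csv", index=False)

    # 3. six heating models
    model_rows = metrics.merge(
        optics[["specimen_id", "band", "absorptivity_A"]],
        left_on=["specimen_id", "phase"],
        right_on=["specimen_id", "band"],
    ).merge(metadata[["specimen_id", "length_cm", "side"]], on="specimen_id")
    models = []
    for response, col in (("delta_t5", "delta_t5_C"), ("max_hr", "max_hr_C_per_s")):
        for band in ("TOTAL", "NIR", "VIS"):
            sub = model_rows[model_rows["phase"] == band]
            df = pd.DataFrame(
                {
                    "response": sub[col],
                    "absorptivity": sub["absorptivity_A"],
                    "size": sub["length_cm"],
                    "side": sub["side"],
                }
            )
            models.append(st.fit_heating_model(df, response, band))
    model_table = _model_table(models)
    model_table.to_csv(out / "heating_models.csv", index=False)

    # 4. correlations
    corr = correlation_table(optics, metadata)
    corr.to_csv(out / "correlations.csv", index=False)

    # 5. repeatability (species as the grouping factor)
    rep = repeatability_table(
        metrics, metadata, config.n_boot_repeatability,
        _derived_seed(config.seed, "repeatability"),
    )
    rep.to_csv(out / "repeatability.csv", index=False)

    # 6. paired body experiment, when supplied
    paired = None
    paired_path = (
        Path(config.paired_file)
        if config.paired_file
        else Path(config.input_dir) / "paired_body.csv"
    )
    if paired_path.exists():
        paired = paired_table(
            pd.read_csv(paired_path), config.n_boot_paired,
            _derived_seed(config.seed, "paired"),
        )
        paired.to_csv(out / "paired_bootstrap.csv", index=False)
    else:
        log.info("no paired body dataset at %s; stage skipped", paired_path)

    bundle = {
        "config": config.to_jsonable(),
        "n_specimens": int(len(specimens)),
        "tables": {
            "optics": "optics.csv",
            "heating_metrics": "heating_metrics.csv",
            "heating_models": "heating_models.csv",
            "correlations": "correlations.csv",
            "repeatability": "repeatability.csv",
            **({"paired_bootstrap": "paired_bootstrap.csv"} if paired is not None else {}),
        },
    }
    with open(out / "results.json", "w") as fhj:
        json.dump(bundle, fhj, indent=1, sort_keys=True)
    log.info("run complete: %s", out)
    return bundle
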
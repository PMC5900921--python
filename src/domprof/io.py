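"""Reading/writing patient tables, run configuration and the pipeline.

The patient table is a CSV with one row per patient: ``patient_id``,
``provider_id``, one column per outcome dimension, the risk-adjustment
covariates, and optionally ``dist_to_<provider>`` columns for the selection
correction. Empty cells and "NA" are read as missing; missing values are
written as empty cells.

Every random draw in a pipeline run traces to a single master seed via
documented sub-seeding: stage s uses ``SeedSequence(master, spawn_key=(s,))``
with stages 0=simulate, 1=fit, 2=assess, 3=compare, 4=selection.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dimensions import DimensionSpec, ModelSpec
from .gibbs import McmcSettings
from .model import MultivariateMultilevelModel
from .dominance import Benchmark, assess_providers, compare_approaches
from .selection import attach_residuals, second_stage_test
from .simulate import SelectionConfig, default_config, simulate

logger = logging.getLogger(__name__)

_STAGES = {"simulate": 0, "fit": 1, "assess": 2, "compare": 3, "selection": 4}


def stage_seed(master: int, stage: str) -> int:
    """Derived 31-bit seed for a named pipeline stage."""
    ss = np.random.SeedSequence(master, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def read_patient_table(path, spec: ModelSpec, centre: bool = True,
                       provider_col: str = "provider_id") -> pd.DataFrame:
    """Read and validate a patient-table CSV against a model spec.

    Binary outcome columns may contain only {0, 1, missing}; violations are
    rejected naming the column and the first offending row. With
    ``centre=True`` continuous covariates (float-valued columns with more
    than two distinct values) are mean-centred on load.
    """
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
    if provider_col not in df.columns:
        raise ValueError(f"column {provider_col!r} missing from {path}")
    spec.validate_against(df)
    for d in spec.dimensions:
        if d.is_probit:
            col = df[d.name]
            bad = col.dropna()[~col.dropna().isin([0, 1])]
            if len(bad):
                raise ValueError(
                    f"binary outcome column {d.name!r} contains value "
                    f"{bad.iloc[0]!r} at row {bad.index[0]}"
                )
    if centre:
        covs = sorted({c for d in spec.dimensions for c in d.covariates})
        for c in covs:
            x = df[c]
            if pd.api.types.is_numeric_dtype(x) and x.nunique() > 2:
                df[c] = x - x.mean()
    return df


def write_patient_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep="")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; flags of the CLI mirror this."""

    seed: int = 0
    input_csv: Optional[str] = None      # None -> simulate
    output_dir: str = "domprof_run"
    # synthetic-data block (used when input_csv is None)
    J: int = 50
    n_j: int = 80
    selection_lambda: float = 0.0        # >0 turns on confounded choice
    # estimation
    iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 1
    # assessment
    S: int = 10_000
    thresholds: tuple[float, ...] = (0.5, 0.8, 0.9, 0.99)
    benchmark_mode: str = "conditional_mean"
    run_comparison: bool = True
    correct_selection: bool = False
    min_patients: int = 30
    allow_unconverged: bool = True

    def __post_init__(self):
        for t in self.thresholds:
            if not (0.5 <= t <= 1.0):
                raise ValueError(f"threshold {t} outside [0.5, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(d["thresholds"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> (selection) -> fit -> assess -> (compare), as configured.

    Writes ``providers.csv``, ``counts.json``, ``diagnostics.json``,
    ``selection_test.json`` (when enabled), the effective config and a run
    log under ``config.output_dir``. Reproducible given ``config.seed``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"domprof {__version__} on {platform.python_version()}",
                 f"master seed {config.seed}"]

    def fail(stage, err):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    spec = None
    try:
        if config.input_csv is None:
            sel = (SelectionConfig(lam=config.selection_lambda)
                   if (config.selection_lambda > 0 or config.correct_selection)
                   else None)
            syn = default_config(J=config.J, n_j=config.n_j,
                                 seed=stage_seed(config.seed, "simulate"),
                                 selection=sel)
            dataset = simulate(syn)
            data = dataset.patients
            spec = ModelSpec(dimensions=syn.dimensions)
            dataset.write(out / "synthetic")
            log_lines.append(f"simulated J={config.J} n_j={config.n_j} "
                             f"(stage seed {syn.seed})")
        else:
            spec = ModelSpec(dimensions=default_config(J=2, n_j=2).dimensions)
            data = read_patient_table(config.input_csv, spec)
            log_lines.append(f"read {config.input_csv}: {len(data)} rows")
    except RuntimeError:
        raise
    except Exception as e:
        fail("simulate/read", e)

    selection_report = None
    if config.correct_selection:
        try:
            data = attach_residuals(data, min_patients=config.min_patients)
            log_lines.append(f"selection: residuals attached ({len(data)} rows kept)")
        except Exception as e:
            fail("selection", e)

    settings = McmcSettings(iterations=config.iterations, burn_in=config.burn_in,
                            thinning=config.thinning,
                            seed=stage_seed(config.seed, "fit"))
    try:
        if config.correct_selection:
            selection_report = second_stage_test(data, spec, settings)
            results = selection_report.corrected
            (out / "selection_test.json").write_text(
                json.dumps(selection_report.to_dict(), indent=1))
            log_lines.append(
                f"selection Wald chi2({selection_report.df}) = "
                f"{selection_report.statistic:.2f}, p = {selection_report.p_value:.4f}")
        else:
            results = MultivariateMultilevelModel(data, spec).fit(settings)
    except RuntimeError:
        raise
    except Exception as e:
        fail("fit", e)

    try:
        bench = Benchmark.from_spec(spec, mode=config.benchmark_mode)
        table = assess_providers(
            results, bench, S=config.S, seed=stage_seed(config.seed, "assess"),
            thresholds=config.thresholds,
            require_convergence=not config.allow_unconverged)
        table.to_csv(out / "providers.csv", index=False)
    except RuntimeError:
        raise
    except Exception as e:
        fail("assess", e)

    counts = None
    if config.run_comparison:
        try:
            cmp_settings = dataclasses.replace(
                settings, seed=stage_seed(config.seed, "compare"))
            cmp = compare_approaches(data, spec, cmp_settings,
                                     thresholds=config.thresholds, S=config.S,
                                     seed=stage_seed(config.seed, "compare"))
            counts = cmp["counts"]
            (out / "counts.json").write_text(json.dumps(
                {str(t): v for t, v in counts.items()}, indent=1))
        except RuntimeError:
            raise
        except Exception as e:
            fail("compare", e)

    diag = results.diagnostics()
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=1, default=float))
    config.to_yaml(out / "config.yaml")
    log_lines.append(f"max split-R-hat {diag['max_rhat']:.4f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return {"results": results, "providers": table, "counts": counts,
            "selection": selection_report, "output_dir": str(out)}
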
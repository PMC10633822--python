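"""End-to-end pipeline: simulate -> WHAM -> association thermo -> Van't Hoff.

A :class:`PipelineConfig` describes every stage; :func:`run_pipeline`
executes the stages, writes all intermediate artifacts under the output
directory and returns a manifest (also written as ``manifest.json``) with
SHA-256 hashes of every output, so identical config + seed give identical
manifests.  A thermo-only mode accepts (T, dG) or (T, K_d) tables directly,
skipping sampling, which is how printed literature tables are re-analysed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc_thermo, io, speciation, synthetic_umbrella, wham

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class SamplerStage:
    r_start: float = 15.0
    r_end: float = 3.5
    spacing: float = synthetic_umbrella.DEFAULT_SPACING
    spring: float = synthetic_umbrella.DEFAULT_SPRING_KCAL
    n_samples: int = synthetic_umbrella.DEFAULT_N_SAMPLES
    n_equilibration: int = 2000
    proposal_step: float = 0.3
    steps_per_sample: int = 10


@dataclass(frozen=True)
class WhamStage:
    bin_width: float = 0.05
    tolerance: float = 1e-7
    max_iterations: int = 100_000
    bootstrap_replicates: int = 0
    zero_region_start: float = 10.0


@dataclass(frozen=True)
class ThermoStage:
    r0: float = assoc_thermo.DEFAULT_R0
    r1: float = assoc_thermo.DEFAULT_R1
    standard_state: str = "molar_1M"
    v_s: float | None = None
    T0: float = 298.0
    # thermo-only mode: list of {"T": .., "dG": ..} or {"T": .., "K_d": ..}
    table: tuple = ()


@dataclass(frozen=True)
class SpeciationStage:
    enabled: bool = False
    C_values: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    W_total: float = 0.0
    K_h: float | None = None
    convention: str = "paper_C_eq_M_plus_D"


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline description; round-trips losslessly through YAML."""

    output_dir: str = "pipeline_out"
    seed: int = 0
    temperatures: tuple = (300.0, 323.0, 345.0)
    pmf_model: str = "acid_acid"  # acid_acid | water_COH | water_CO
    sampler: SamplerStage = field(default_factory=SamplerStage)
    wham: WhamStage = field(default_factory=WhamStage)
    thermo: ThermoStage = field(default_factory=ThermoStage)
    speciation: SpeciationStage = field(default_factory=SpeciationStage)
    verbosity: int = 1


_STAGE_TYPES = {
    "sampler": SamplerStage,
    "wham": WhamStage,
    "thermo": ThermoStage,
    "speciation": SpeciationStage,
}


def _from_mapping(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise PipelineError(f"unknown config keys in {context}: {sorted(unknown)}")
    clean = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**clean)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    stages = {k: _from_mapping(t, raw.pop(k, {}) or {}, k) for k, t in _STAGE_TYPES.items()}
    cfg = _from_mapping(PipelineConfig, raw, "top level")
    return dataclasses.replace(cfg, **stages)


def config_to_dict(config: PipelineConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config)))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _make_model(name: str):
    if name == "acid_acid":
        return synthetic_umbrella.make_default_pmf()
    if name == "water_COH":
        return synthetic_umbrella.make_water_pmf("COH")
    if name == "water_CO":
        return synthetic_umbrella.make_water_pmf("CO")
    raise PipelineError(f"unknown pmf_model {name!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the output manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    log = print if config.verbosity > 0 else (lambda *a, **k: None)

    def record(path: Path) -> None:
        outputs[str(path.relative_to(out))] = _sha256(path)

    assoc_rows = []
    if config.thermo.table:
        # thermo-only mode: (T, dG) or (T, K_d) pairs given directly
        try:
            for row in config.thermo.table:
                row = dict(row)
                T = float(row["T"])
                if "dG" in row:
                    dg = float(row["dG"])
                    kd = assoc_thermo.kd_from_dG(dg, T)
                elif "K_d" in row:
                    kd = float(row["K_d"])
                    dg = assoc_thermo.dG_from_kd(kd, T)
                else:
                    raise KeyError("each thermo table row needs 'dG' or 'K_d'")
                assoc_rows.append({"T_K": T, "dG_d_kJ_per_mol": dg, "K_d_mM": kd})
        except (KeyError, ValueError) as exc:
            raise PipelineError(f"thermo stage failed: {exc}") from exc
    else:
        model = _make_model(config.pmf_model)
        for t_idx, T in enumerate(config.temperatures):
            log(f"[simulate] {config.pmf_model} at {T} K")
            s = config.sampler
            try:
                ds = synthetic_umbrella.run_schedule(
                    model, s.r_start, s.r_end, s.spacing, s.spring, T,
                    synthetic_umbrella.SamplerConfig(
                        n_samples=s.n_samples,
                        n_equilibration=s.n_equilibration,
                        proposal_step=s.proposal_step,
                        seed=config.seed + 1000 * t_idx,
                        steps_per_sample=s.steps_per_sample,
                    ),
                )
            except Exception as exc:
                raise PipelineError(f"simulate stage failed at {T} K: {exc}") from exc
            meta = io.write_windows(ds, out / f"windows_T{T:g}")
            record(meta)
            for p in sorted(meta.parent.glob("window_*.dat")):
                record(p)

            log(f"[wham] {len(ds.windows)} windows at {T} K")
            w = config.wham
            wcfg = wham.WhamConfig(
                bin_width=w.bin_width, tolerance=w.tolerance,
                max_iterations=w.max_iterations,
                bootstrap_replicates=w.bootstrap_replicates,
                seed=config.seed + 1000 * t_idx + 500,
                zero_region_start=w.zero_region_start,
            )
            try:
                if w.bootstrap_replicates >= 2:
                    profile = wham.bootstrap_error(ds, wcfg)
                else:
                    profile = wham.solve_wham(ds, wcfg)
            except wham.WhamConvergenceError as exc:
                raise PipelineError(f"wham stage failed at {T} K: {exc}") from exc
            record(io.write_pmf_table(profile, out / f"pmf_T{T:g}.dat"))

            log(f"[thermo] well [{config.thermo.r0}, {config.thermo.r1}] A at {T} K")
            try:
                res = assoc_thermo.integrate_association(
                    profile, config.thermo.r0, config.thermo.r1,
                    standard_state=config.thermo.standard_state,
                    v_s=config.thermo.v_s,
                )
            except ValueError as exc:
                raise PipelineError(f"thermo stage failed at {T} K: {exc}") from exc
            assoc_rows.append({
                "T_K": T,
                "dG_d_kJ_per_mol": res.dG_dissociation,
                "K_d_mM": res.K_d,
            })

    assoc_df = pd.DataFrame(assoc_rows)
    record(io.write_table(assoc_df, out / "association.csv"))

    if len(assoc_df) >= 2:
        log("[vanthoff] fitting ln K_d vs 1/T")
        fit = assoc_thermo.vant_hoff_fit(
            list(zip(assoc_df["T_K"], assoc_df["K_d_mM"])), T0=config.thermo.T0
        )
        vh = {
            "K_d0_mM": fit.K_d0, "T0_K": fit.T0, "dH_kJ_per_mol": fit.dH,
            "fit_method": fit.fit_method, "K_d0_method": fit.K_d0_method,
            "ln_residuals": list(fit.residuals),
        }
        p = out / "vant_hoff.json"
        p.write_text(json.dumps(vh, indent=1, sort_keys=True))
        record(p)

    if config.speciation.enabled:
        log("[speciate] speciation curve")
        sp = config.speciation
        if not config.thermo.table and not assoc_rows:
            raise PipelineError("speciation stage needs a K_d source")
        kd = assoc_rows[0]["K_d_mM"]
        consts = speciation.EquilibriumConstants(
            K_d=kd, K_h=sp.K_h if sp.K_h else np.inf,
            temperature=assoc_rows[0]["T_K"],
        )
        curve = speciation.speciation_curve(sp.C_values, sp.W_total, consts, sp.convention)
        record(io.write_table(pd.DataFrame(curve), out / "speciation.csv"))

    manifest = {
        "config": config_to_dict(config),
        "seed": config.seed,
        "outputs": dict(sorted(outputs.items())),
        "package": "acidassoc 0.1.0",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
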
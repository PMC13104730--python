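"""End-to-end analysis: records in, Table-style plateau estimates out.

For every clone x trait (somatic growth rate ``g``, early-life intrinsic
rate of increase ``r``) x model (quadratic plateau, hockey stick) the
pipeline computes the point fit, the derived quantities (ILL = break-point,
plateau elevation, TFL = x-intercept) and stratified-bootstrap percentile
confidence intervals, then renders CI-overlap orderings of the clones per
trait. All randomness flows from the single configured seed; rerunning an
identical configuration reproduces the output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (BootstrapConfig, CloneOrdering, bootstrap_growth_fit,
                        bootstrap_r_fit, compare_by_ci)
from .exceptions import IllfitError, InvalidInputError
from .life_history import compute_r_observations, growth_observations
from .plateau import (HOCKEY_STICK, QUADRATIC_PLATEAU, fit_hockey_stick,
                      fit_quadratic_plateau)
from .records import RECORD_COLUMNS, check_records
from .simulate import (CloneSpec, ExperimentDesign, default_clone_specs,
                       default_design, generate_dataset)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "read_records_csv",
    "write_records_csv",
    "run_pipeline",
    "write_results",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "clone_id", "trait", "model", "b0", "b1", "ill", "plateau", "tfl",
    "rss", "n_obs", "converged", "optimizer", "at_boundary",
    "ill_lo", "ill_hi", "plateau_lo", "plateau_hi", "tfl_lo", "tfl_hi",
    "n_failed_resamples",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    input_path: str | None = None          # None -> simulate
    design: ExperimentDesign | None = None
    clone_specs: tuple[CloneSpec, ...] | None = None
    traits: tuple[str, ...] = ("g", "r")
    models: tuple[str, ...] = (QUADRATIC_PLATEAU, HOCKEY_STICK)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    lx_scope: str = "stratum"              # or "clone"
    fit_scope: str = "individual_points"   # or "stratum_means"
    output_dir: str = "illfit_output"
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.traits or not set(self.traits) <= {"g", "r"}:
            raise InvalidInputError("traits must be a non-empty subset of {'g','r'}")
        if not self.models or not set(self.models) <= {QUADRATIC_PLATEAU,
                                                       HOCKEY_STICK}:
            raise InvalidInputError("models must be a non-empty subset of the "
                                    "two plateau models")
        if self.fit_scope not in ("individual_points", "stratum_means"):
            raise InvalidInputError(f"unknown fit_scope {self.fit_scope!r}")


@dataclass
class PipelineResult:
    results: pd.DataFrame
    orderings: dict[tuple[str, str], CloneOrdering]
    report: str
    records: pd.DataFrame
    accounting: pd.DataFrame


def read_records_csv(path) -> pd.DataFrame:
    """Read and validate a per-individual records CSV.

    Expects the canonical header (clone_id, concentration_mgC_per_L,
    initial_mass_ug, final_mass_ug, age_first_repro_d, clutch_size,
    survived); empty cells map to missing fields. Every schema violation is
    reported with its row number in a single SchemaError.
    """
    df = pd.read_csv(path, dtype={"clone_id": str})
    if "survived" in df.columns:
        df["survived"] = df["survived"].map(_parse_bool)
    return check_records(df)


def _parse_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise InvalidInputError(f"cannot parse {v!r} as a survived flag")


def write_records_csv(records: pd.DataFrame, path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def _observations(records, trait, lx_scope):
    if trait == "g":
        obs = growth_observations(records)
        return obs["concentration_mgC_per_L"].to_numpy(), obs["g"].to_numpy()
    obs = compute_r_observations(records, lx_scope=lx_scope)
    return obs["concentration_mgC_per_L"].to_numpy(), obs["r"].to_numpy()


def _maybe_stratum_means(x, y, fit_scope):
    if fit_scope == "individual_points":
        return x, y
    df = pd.DataFrame({"x": x, "y": y}).groupby("x", sort=True)["y"].mean()
    return df.index.to_numpy(), df.to_numpy()


_FITTERS = {QUADRATIC_PLATEAU: fit_quadratic_plateau,
            HOCKEY_STICK: fit_hockey_stick}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config``.

    Returns the per-(clone, trait, model) results table, CI-overlap clone
    orderings keyed by (trait, model), a plain-text run report, the input
    records, and a per-individual accounting table.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    lines = [f"illfit {__version__} run report", "", "configuration:"]
    lines += [f"  {k}: {v}" for k, v in _config_echo(config).items()]

    if config.input_path is not None:
        records = read_records_csv(config.input_path)
        lines.append(f"input: {config.input_path} ({len(records)} records)")
    else:
        design = config.design or default_design()
        specs = list(config.clone_specs) if config.clone_specs \
            else default_clone_specs()
        records = generate_dataset(design, specs)
        lines.append(f"input: simulated, seed {design.seed} "
                     f"({len(records)} records)")
    records = check_records(records)

    accounting = _account_individuals(records)
    warnings_log: list[str] = []
    rows = []
    orderings: dict[tuple[str, str], CloneOrdering] = {}
    clones = sorted(records["clone_id"].unique())
    ss = np.random.SeedSequence(config.bootstrap.seed)
    # one independent child stream per clone x trait x model, fixed order
    streams = iter(ss.spawn(len(clones) * len(config.traits) * len(config.models)))

    for trait in config.traits:
        for model in config.models:
            cis = {}
            for clone in clones:
                sub = records[records["clone_id"] == clone]
                x, y = _observations(sub, trait, config.lx_scope)
                x, y = _maybe_stratum_means(x, y, config.fit_scope)
                seed = int(next(streams).generate_state(1)[0] % (2 ** 31))
                row, ci = _fit_one(sub, clone, trait, model, x, y, seed,
                                   config, warnings_log)
                rows.append(row)
                if ci is not None:
                    cis[clone] = ci
            if len(cis) >= 2:
                orderings[(trait, model)] = compare_by_ci(cis)

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    lines.append("")
    lines.append("individual accounting:")
    for _, r in accounting.iterrows():
        lines.append(f"  {r['category']}: {r['count']}")
    lines.append("")
    lines.append("CI-overlap clone orderings (by ILL):")
    for (trait, model), o in sorted(orderings.items()):
        lines.append(f"  {trait} / {model}: {o}")
    if warnings_log:
        lines.append("")
        lines.append("warnings:")
        lines += [f"  {w}" for w in warnings_log]
    report = "\n".join(lines) + "\n"
    return PipelineResult(results, orderings, report, records, accounting)


def _fit_one(sub, clone, trait, model, x, y, seed, config, warnings_log):
    fitter = _FITTERS[model]
    try:
        fit = fitter(x, y)
    except IllfitError as exc:
        raise type(exc)(f"clone {clone}, trait {trait}, model {model}: {exc}") \
            from exc
    if fit.optimizer_tag == "fallback":
        warnings_log.append(
            f"{clone}/{trait}/{model}: primary optimizer failed, "
            "grid fallback used")
    if fit.at_boundary:
        warnings_log.append(
            f"{clone}/{trait}/{model}: break-point at the design boundary")
    logger.info("fit %s/%s/%s: ILL=%.4g plateau=%.4g rss=%.4g (%s)",
                clone, trait, model, fit.ill, fit.plateau_elevation,
                fit.rss, fit.optimizer_tag)

    scheme = "growth_stratified" if trait == "g" else "r_individual"
    bcfg = dataclasses.replace(config.bootstrap, seed=seed, scheme=scheme)
    if trait == "g":
        boot = bootstrap_growth_fit(sub, bcfg, model_tag=model, point_fit=fit)
    else:
        boot = bootstrap_r_fit(sub, bcfg, model_tag=model, point_fit=fit,
                               lx_scope=config.lx_scope)
    n_failed = boot["ill"][0].n_failed
    if n_failed:
        warnings_log.append(
            f"{clone}/{trait}/{model}: {n_failed} bootstrap refits failed")

    def bounds(tag):
        ci = boot[tag][1]
        return (np.nan, np.nan) if ci is None else (ci.lower, ci.upper)

    ill_lo, ill_hi = bounds("ill")
    pl_lo, pl_hi = bounds("plateau")
    tfl_lo, tfl_hi = bounds("tfl")
    row = {
        "clone_id": clone, "trait": trait, "model": model,
        "b0": fit.params.b0, "b1": fit.params.b1, "ill": fit.ill,
        "plateau": fit.plateau_elevation,
        "tfl": np.nan if fit.tfl is None else fit.tfl,
        "rss": fit.rss, "n_obs": fit.n_obs, "converged": fit.converged,
        "optimizer": fit.optimizer_tag, "at_boundary": fit.at_boundary,
        "ill_lo": ill_lo, "ill_hi": ill_hi,
        "plateau_lo": pl_lo, "plateau_hi": pl_hi,
        "tfl_lo": tfl_lo, "tfl_hi": tfl_hi,
        "n_failed_resamples": n_failed,
    }
    return row, boot["ill"][1]


def _account_individuals(records: pd.DataFrame) -> pd.DataFrame:
    """Every animal is used-in-g-and-r, l_x-only, or zero-clutch (l_x only)."""
    survived = records["survived"]
    repro = survived & (records["clutch_size"] >= 1)
    zero_clutch = survived & (records["clutch_size"] < 1)
    rows = [
        ("used_in_g_and_r", int(repro.sum())),
        ("zero_clutch_lx_only", int(zero_clutch.sum())),
        ("died_lx_only", int((~survived).sum())),
        ("total", len(records)),
    ]
    return pd.DataFrame(rows, columns=["category", "count"])


def _config_echo(config: PipelineConfig) -> dict:
    b = config.bootstrap
    echo = {
        "input_path": config.input_path,
        "traits": ",".join(config.traits),
        "models": ",".join(config.models),
        "bootstrap_n_resamples": b.n_resamples,
        "bootstrap_ci_level": b.ci_level,
        "bootstrap_seed": b.seed,
        "bootstrap_lx_mode": b.lx_mode,
        "lx_scope": config.lx_scope,
        "fit_scope": config.fit_scope,
    }
    if config.input_path is None:
        d = config.design or default_design()
        echo["design_seed"] = d.seed
        echo["design_replicates"] = d.replicates_per_cell
        echo["design_concentrations"] = ",".join(f"{c:g}" for c in d.concentrations)
    return echo


def write_results(result: PipelineResult, output_dir) -> dict[str, Path]:
    """Write results.csv and run_report.txt; byte-identical across reruns.

    Not-estimable quantities (e.g. a TFL when the fitted curve is positive
    at zero food) are written as "NA", never left blank. No timestamps or
    machine identifiers are written, so identical configurations yield
    identical bytes.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"results": out / "results.csv", "report": out / "run_report.txt"}
    buf = io.StringIO()
    result.results.to_csv(buf, index=False, float_format="%.10g", na_rep="NA")
    paths["results"].write_text(buf.getvalue())
    paths["report"].write_text(result.report)
    return paths
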
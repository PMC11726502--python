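"""End-to-end orchestration: base-case runs, validation, and file outputs.

`run_base_case` simulates both arms with common random numbers under the
central (point-value) parameters and emits a rescaled incident-event table
(cases per category/disease and cases prevented, in millions) plus the
cost-effectiveness summary per perspective.  `run_psa_analysis` wraps the
probabilistic sensitivity analysis and writes the per-iteration draws and
the acceptability curve.  `validate_internal` compares the simulated
baseline weight distribution against its survey calibration targets.
All monetary outputs are 2022 USD.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, economics, psa as psa_mod
from .engine import STATUS_QUO, Trace, simulate, soda_tax_arm
from .parameters import ModelConfig, ParameterSet, load_parameters
from .population import CalibrationTargets, Cohort, PopulationSpec, calibrate, generate_cohort
from .states import HealthState

#: Table rows of the comparative event summary, with the trace event feeding each.
_EVENT_ROWS = (
    ("overweight", "new_overweight", HealthState.OVERWEIGHT),
    ("obesity", "new_obesity", HealthState.OBESITY),
    ("diabetes", "new_diabetes", None),
    ("stroke", "new_stroke", None),
    ("mi", "new_mi", None),
    ("esrd", "new_esrd", None),
    ("death", "deaths", None),
)


@dataclass
class RunManifest:
    """Provenance record written next to every batch of outputs."""

    config_source: str
    seed: int
    version: str = __version__
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat())
    outputs: list[str] = field(default_factory=list)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def validate_internal(cohort: Cohort, targets: CalibrationTargets | None = None,
                      z: float = 2.0) -> pd.DataFrame:
    """Compare simulated baseline moments with the survey calibration targets.

    Pass/fail is judged at ``z`` Monte-Carlo standard errors for the cohort
    size at hand.
    """
    targets = targets or CalibrationTargets()
    n = cohort.n
    rows = []
    checks = [
        ("mean_weight_kg", cohort.mean_weight(), targets.mean_weight,
         targets.sd_weight / np.sqrt(n)),
        ("sd_weight_kg", cohort.sd_weight(), targets.sd_weight,
         targets.sd_weight / np.sqrt(2.0 * (n - 1))),
        ("obesity_prevalence", cohort.obesity_prevalence(), targets.obesity_prev,
         np.sqrt(targets.obesity_prev * (1 - targets.obesity_prev) / n)),
    ]
    for name, sim, tgt, se in checks:
        diff = sim - tgt
        rows.append({
            "quantity": name, "simulated": sim, "target": tgt,
            "abs_diff": diff, "rel_diff": diff / tgt if tgt else np.nan,
            "tolerance": z * se, "pass": bool(abs(diff) <= z * se),
        })
    return pd.DataFrame(rows)


def events_table(trace_sq: Trace, trace_tax: Trace, baseline: Cohort,
                 factor: float) -> pd.DataFrame:
    """Comparative case counts (millions, population-rescaled) per arm.

    Weight-category rows count individuals ever classified in the category
    (baseline members plus first-ever entries); disease rows count incident
    first events; the death row counts cumulative deaths.
    """
    base_counts = baseline.state_counts()
    rows = []
    for label, event, base_state in _EVENT_ROWS:
        base_n = int(base_counts[base_state]) if base_state is not None else 0
        sq = (base_n + trace_sq.total_events(event)) * factor / 1e6
        tax = (base_n + trace_tax.total_events(event)) * factor / 1e6
        rows.append({"item": f"number_of_{label}_cases_million",
                     "soda_tax": tax, "status_quo": sq, "prevented": sq - tax})
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, out_dir: Path, name: str, manifest: RunManifest):
    path = Path(out_dir) / name
    df.to_csv(path, index=False)
    manifest.outputs.append(name)


def run_base_case(config_source=None, seed: int | None = None, n: int | None = None,
                  horizon: int | None = None, out_dir=None,
                  pop_spec: PopulationSpec | None = None) -> dict:
    """Deterministic-parameter run of both arms; optionally write CSV outputs.

    Returns a dict with the baseline cohort, both traces, the event table,
    the CEAResult, and the validation table.
    """
    pset, config = load_parameters(config_source)
    if seed is not None:
        config = config.replace(seed=int(seed))
    if n is not None:
        # keep population-scale totals invariant to the simulated cohort size
        factor = config.rescale_factor * config.n_individuals / int(n)
        config = config.replace(n_individuals=int(n), rescale_factor=factor)
    if horizon is not None:
        config = config.replace(horizon_years=int(horizon))

    base = np.random.default_rng(config.seed)
    cal_seed = int(base.integers(2**31 - 1))
    cohort_seed = int(base.integers(2**31 - 1))
    sim_seed = int(base.integers(2**31 - 1))

    if pop_spec is None:
        pop_spec = calibrate(seed=cal_seed)
    baseline = generate_cohort(pop_spec.with_n(config.n_individuals), cohort_seed)

    drawn = pset.central()
    trace_sq, final_sq = simulate(baseline, STATUS_QUO, drawn.transition_probs,
                                  config, seed=sim_seed,
                                  costs=drawn.costs, utilities=drawn.utilities)
    trace_tax, final_tax = simulate(baseline, soda_tax_arm(drawn.weight_effect),
                                    drawn.transition_probs, config, seed=sim_seed,
                                    costs=drawn.costs, utilities=drawn.utilities)
    cea = economics.evaluate_cea(trace_sq, trace_tax, drawn, config)
    events = events_table(trace_sq, trace_tax, baseline, config.rescale_factor)
    validation = validate_internal(baseline)

    result = {
        "config": config, "parameters": pset, "pop_spec": pop_spec,
        "baseline": baseline, "trace_status_quo": trace_sq, "trace_soda_tax": trace_tax,
        "final_status_quo": final_sq, "final_soda_tax": final_tax,
        "cea": cea, "events": events, "validation": validation,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(config_source=str(config_source or "packaged defaults"),
                               seed=config.seed)
        _write_csv(cea.to_frame(), out_dir, "cea_summary.csv", manifest)
        _write_csv(events, out_dir, "events_table.csv", manifest)
        _write_csv(validation, out_dir, "validation.csv", manifest)
        for arm_name, trace in (("status_quo", trace_sq), ("soda_tax", trace_tax)):
            states_long, events_long = trace.to_long_frames()
            _write_csv(states_long, out_dir, f"trace_states_{arm_name}.csv", manifest)
            _write_csv(events_long, out_dir, f"trace_events_{arm_name}.csv", manifest)
        result["manifest"] = manifest.write(out_dir)
        manifest.outputs.append("manifest.json")
    return result


def run_psa_analysis(config_source=None, seed: int = 0, iterations: int = 200,
                     n_individuals: int = 2_000, full_scale: bool = False,
                     out_dir=None, plots: bool = False) -> dict:
    """Run the PSA (desk profile by default) and optionally write outputs."""
    pset, config = load_parameters(config_source)
    if full_scale:
        iterations, n_individuals = 1_000, 20_000
    result = psa_mod.run_psa(pset, config, n_iterations=iterations,
                             n_individuals=n_individuals, seed=seed)
    curve = psa_mod.ceac(result)
    out = {"psa": result, "ceac": curve,
           "p_ce_at_wtp": result.probability_cost_effective()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = RunManifest(config_source=str(config_source or "packaged defaults"),
                               seed=seed)
        _write_csv(result.to_frame(), out_dir, "psa_draws.csv", manifest)
        _write_csv(curve, out_dir, "ceac.csv", manifest)
        _write_csv(result.summaries(), out_dir, "psa_summaries.csv", manifest)
        if plots:
            for name in _plot_psa(result, curve, out_dir):
                manifest.outputs.append(name)
        out["manifest"] = manifest.write(out_dir)
        manifest.outputs.append("manifest.json")
    return out


def _plot_psa(result: psa_mod.PSAResult, curve: pd.DataFrame, out_dir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = []
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_qaly / 1e6, result.delta_cost_healthcare / 1e9,
               s=8, alpha=0.5)
    lim = np.array(ax.get_xlim())
    ax.plot(lim, result.wtp * lim * 1e6 / 1e9, "k--", lw=1,
            label=f"WTP ${result.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs (millions)")
    ax.set_ylabel("Incremental health care cost (billion 2022 USD)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "ce_plane.png", dpi=150)
    plt.close(fig)
    names.append("ce_plane.png")

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"] / 1000, curve["probability"])
    ax.set_xlabel("Willingness to pay (thousand 2022 USD / QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(out_dir / "ceac.png", dpi=150)
    plt.close(fig)
    names.append("ceac.png")
    return names
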
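"""Pipeline orchestration and rendering of the standard output tables.

``run_pipeline`` drives simulate (optional) -> preprocess -> univariate ->
network -> mediation from a single :class:`RunConfig`, writing each stage's
outputs under the run directory together with a manifest recording seeds,
package versions, SHA-256 hashes of every written file and per-stage
convergence status.  ``render_tables`` produces publication-style descriptive
tables: site-stratified biomarker and intake summaries, the screening OR /
mean-effect tables with significance stars, prevalence tables (inflammation-
adjusted for reporting, never for modelling), and the significant-arc graph
in DOT and GraphML form.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .config import NETWORK_NUTRIENTS, NUTRIENTS, SimConfig, load_calibration
from .mediation import sensitivity_fever, total_vs_direct
from .network import MCMCConfig, build_network, fit_network, significant_arcs
from .preprocess import AnalyticResult, build_analytic
from .simulate import RawCohort, generate_cohort, read_cohort, write_cohort
from .truth import TruthDAG, default_truth
from .univariate import correlation_summary, screen_all

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_tables"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``simulate=True`` (a synthetic cohort is drawn) or ``input_dir``
    must point at a cohort directory in the simulator's CSV layout.
    """

    out_dir: str | Path
    seed: int = 0
    simulate: bool = True
    input_dir: str | Path | None = None
    sim: SimConfig | None = None
    truth: TruthDAG | None = None
    mcmc: MCMCConfig | None = None
    diet_vars: list[str] = field(default_factory=lambda: list(NETWORK_NUTRIENTS))
    run_sensitivity: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.simulate and self.input_dir is None:
            raise ValueError("simulation disabled but no input_dir given")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input_dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = SimConfig(**raw["sim"]) if "sim" in raw else None
        mcmc = MCMCConfig(**raw["mcmc"]) if "mcmc" in raw else None
        kwargs = {k: v for k, v in raw.items() if k not in ("sim", "mcmc")}
        return cls(sim=sim, mcmc=mcmc, **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; return (and write) the run manifest."""
    import eednet

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "versions": {"eednet": eednet.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
    }

    def record(stage: str, files: list[Path], **extra: Any) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files}, **extra}

    # --- stage 1: cohort ----------------------------------------------------
    try:
        if config.simulate:
            sim = config.sim or SimConfig(seed=config.seed)
            truth = config.truth or default_truth(sim.calibration, sim.sites)
            cohort = generate_cohort(sim, truth)
            cohort_dir = out / "cohort"
            write_cohort(cohort, cohort_dir)
            record("simulate", sorted(cohort_dir.glob("*.csv")) + [cohort_dir / "truth.json"],
                   n_children=int(len(cohort.children)))
        else:
            cohort = read_cohort(config.input_dir)
            record("simulate", [], skipped=True, input_dir=str(config.input_dir))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # --- stage 2: preprocess ------------------------------------------------
    try:
        prep = build_analytic(cohort, reference_site=cohort.children["site"].iloc[0]
                              if "BRF" not in set(cohort.children["site"]) else "BRF")
        prep.analytic.to_csv(out / "analytic.csv", index=False)
        prep.prevalence.to_csv(out / "prevalence.csv", index=False)
        (out / "exclusions.json").write_text(json.dumps(prep.exclusions, indent=1))
        record("preprocess", [out / "analytic.csv", out / "prevalence.csv",
                              out / "exclusions.json"],
               n_analytic=int(len(prep.analytic)), exclusions=prep.exclusions)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    analytic = prep.analytic
    sites = sorted(analytic["site"].unique())
    exposures = [f"diet_{v}" for v in NUTRIENTS if f"diet_{v}" in analytic.columns]
    binary = [c for c in ("anemia", "low_ferritin", "high_tfr", "low_retinol", "low_zinc")
              if c in analytic.columns]
    continuous = [c for c in ("mpo", "neo", "aat", "lmz", "agp") if c in analytic.columns]

    # --- stage 3: univariate screens ---------------------------------------
    try:
        screens = screen_all(analytic, exposures, binary, continuous)
        t3 = screens[screens["family"] == "logistic"]
        t4 = screens[screens["family"] == "linear"]
        t3.to_csv(out / "deficiency_or_screens.csv", index=False)
        t4.to_csv(out / "biomarker_effect_screens.csv", index=False)
        corr = correlation_summary(analytic, ["ferritin_ug_l", "tfr_mg_l",
                                              "hemoglobin_adj_g_dl"]
                                   if "ferritin_ug_l" in analytic.columns else continuous,
                                   seed=config.seed)
        corr.to_csv(out / "correlations.csv", index=False)
        record("univariate", [out / "deficiency_or_screens.csv", out / "biomarker_effect_screens.csv",
                              out / "correlations.csv"],
               n_fits=int(len(screens)),
               n_converged=int(screens["converged"].sum()))
    except Exception as exc:
        raise RuntimeError(f"stage 'univariate' failed: {exc}") from exc

    # --- stage 4: network ---------------------------------------------------
    try:
        spec = build_network(diet_vars=config.diet_vars, sites=sites,
                             reference_site=sites[0],
                             outcome_nodes=binary)
        mcmc = config.mcmc or MCMCConfig(seed=config.seed)
        summary = fit_network(analytic, spec, mcmc)
        summary.table.to_csv(out / "network_arcs.csv", index=False)
        sig = significant_arcs(summary)
        sig.to_csv(out / "significant_arcs.csv", index=False)
        _write_graphs(sig, spec, out)
        record("network", [out / "network_arcs.csv", out / "significant_arcs.csv",
                           out / "significant_arcs.dot", out / "significant_arcs.graphml"],
               converged=bool(summary.converged),
               n_significant=int(len(sig)))
    except Exception as exc:
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    # --- stage 5: mediation -------------------------------------------------
    try:
        med = total_vs_direct(t3, summary)
        med.to_csv(out / "mediation_table.csv", index=False)
        files = [out / "mediation_table.csv"]
        if config.run_sensitivity and "fever_prop" in analytic.columns:
            comp, _ = sensitivity_fever(analytic, summary)
            comp.to_csv(out / "sensitivity_comparison.csv", index=False)
            files.append(out / "sensitivity_comparison.csv")
            record("mediation", files, n_rows=int(len(med)),
                   fever_max_abs_shift=comp.attrs["max_abs_shift"])
        else:
            record("mediation", files, n_rows=int(len(med)))
    except Exception as exc:
        raise RuntimeError(f"stage 'mediation' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_graphs(sig: pd.DataFrame, spec, out: Path) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(spec.nodes)
    for r in sig.itertuples():
        g.add_edge(r.parent, r.child, weight=abs(float(r.mean)),
                   sign=int(r.sign), scale=r.scale)
    nx.write_graphml(g, out / "significant_arcs.graphml")
    lines = ["digraph significant_arcs {"]
    for n in g.nodes:
        lines.append(f'  "{n}";')
    for u, v, d in g.edges(data=True):
        color = "red" if d["sign"] > 0 else "blue"
        style = "dashed" if d["scale"] == "log_odds" else "solid"
        lines.append(f'  "{u}" -> "{v}" [color={color}, style={style}, '
                     f'penwidth={1 + 4 * d["weight"]:.2f}];')
    lines.append("}")
    (out / "significant_arcs.dot").write_text("\n".join(lines) + "\n")


def render_tables(cohort: RawCohort, prep: AnalyticResult) -> dict[str, pd.DataFrame]:
    """Site-stratified descriptive tables from the preprocessed cohort.

    ``biomarkers`` mirrors the gut-function/status table (mean +/- SD of the
    transformed per-child summaries); ``intake`` mirrors the diet table
    (energy mean +/- SD, density median (IQR)); ``prevalence`` carries a
    provenance column distinguishing inflammation-adjusted reporting values
    from the unadjusted values the network consumes.
    """
    cs = prep.child_summaries
    bio_vars = ["lacz", "manz", "lmz", "mpo", "neo", "aat",
                "hemoglobin_adj_g_dl", "retinol_umol_l", "tfr_mg_l",
                "ferritin_ug_l", "zinc_umol_l", "agp_g_l"]
    rows = []
    for site, grp in cs.groupby("site"):
        row: dict[str, Any] = {"site": site, "n": len(grp)}
        for v in bio_vars:
            if v in grp.columns:
                row[v] = f"{grp[v].mean():.2f} ± {grp[v].std(ddof=1):.2f}"
        rows.append(row)
    biomarkers = pd.DataFrame(rows)

    intake_rows = []
    for site, grp in cohort.recalls.merge(
            cohort.children[["child_id", "site"]], on="child_id").groupby("site"):
        per_child = grp.groupby("child_id")["energy_kcal"].mean()
        row = {"site": site, "energy_kcal": f"{per_child.mean():.0f} ± {per_child.std(ddof=1):.0f}"}
        for v in NUTRIENTS:
            col = f"diet_{v}"
            if col in cs.columns:
                sub = cs.loc[cs["site"] == site, col] ** 2  # back to density units
                q1, q2, q3 = sub.quantile([0.25, 0.5, 0.75])
                row[v] = f"{q2:.1f} ({q1:.1f}, {q3:.1f})"
        intake_rows.append(row)
    intake = pd.DataFrame(intake_rows)
    return {"biomarkers": biomarkers, "intake": intake, "prevalence": prep.prevalence}
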
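"""Config-driven end-to-end orchestration.

``run_pipeline`` executes the enabled stages in dependency order
(indices / coda / network / pca are independent; PMF must precede the
source-risk stage; the deterministic risk engine feeds the Monte Carlo
stage), writes every stage's CSV outputs and a JSON run manifest listing
versions, seeds, parameters and produced files.

A single global seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence(global_seed, spawn_key=(stage_index,))`` with
a fixed stage numbering, so toggling one stage never shifts another
stage's random stream.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coda, indices, mc_risk, network, receptors, source_risk
from .hra import ADULT, AGE_ADJUSTED, CHILD, DEFAULT_TOXICITY
from .mc_risk import McConfig
from .receptors import UncertaintySpec
from .sampletable import SampleTable
from .synthetic import generate_dataset, study_config

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "STAGES"]

# fixed numbering: stage toggling must not shift other stages' streams
STAGES = {
    "simulate": 0,
    "indices": 1,
    "coda": 2,
    "network": 3,
    "pca": 4,
    "pmf": 5,
    "hra": 6,
    "mc": 7,
    "source_risk": 8,
}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(STAGES[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    out_dir: str | Path
    sample_csv: str | Path | None = None  # None -> simulate the default survey
    stages: tuple[str, ...] = (
        "indices", "coda", "network", "pca", "pmf", "hra", "mc", "source_risk"
    )
    seed: int = 0
    n_factors: int = 5
    pmf_runs: int = 20
    mc_iterations: int = 1000
    uncertainty: UncertaintySpec | None = None
    mdl_substitute: dict[str, float] | None = None

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {', '.join(unknown)}")
        if "source_risk" in self.stages and "pmf" not in self.stages:
            raise ValueError("source_risk requires the pmf stage")
        if "mc" in self.stages and "hra" not in self.stages:
            raise ValueError("mc requires the hra stage")


def _write(frame: pd.DataFrame, path: Path, manifest: dict) -> None:
    frame.to_csv(path)
    manifest["outputs"].append(path.name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest dict (also written as
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "soilrisk_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "parameters": {
            "n_factors": config.n_factors,
            "pmf_runs": config.pmf_runs,
            "mc_iterations": config.mc_iterations,
        },
        "outputs": [],
    }

    if config.sample_csv is None:
        cfg = study_config(seed=stage_seed(config.seed, "simulate"))
        table, true_g, true_f = generate_dataset(cfg)
        table.to_csv(out / "samples.csv")
        manifest["outputs"] += ["samples.csv", "samples.censored.csv"]
        mdl = dict(cfg.mdl)
    else:
        table = SampleTable.from_csv(config.sample_csv, config.mdl_substitute)
        mdl = config.mdl_substitute or {}

    if config.uncertainty is not None:
        spec = config.uncertainty
    else:
        spec = UncertaintySpec(
            sigma={e: 0.1 for e in table.elements},
            mdl={e: mdl.get(e, 0.0) for e in table.elements},
        )

    if "indices" in config.stages:
        _write(indices.summarize(table), out / "summary_stats.csv", manifest)

    if "coda" in config.stages:
        clrm = coda.clr_table(table, mdl=spec.mdl)
        biplot = coda.clr_biplot(clrm)
        labels = coda.kmeans_clusters(
            clrm.values, k=3, seed=stage_seed(config.seed, "coda")
        )
        _write(biplot.scores, out / "coda_scores.csv", manifest)
        _write(biplot.rays, out / "coda_rays.csv", manifest)
        _write(
            pd.DataFrame({"cluster": labels}, index=table.conc.index),
            out / "coda_clusters.csv",
            manifest,
        )

    if "network" in config.stages:
        net = network.build_network(table)
        ei = network.expected_influence(net, standardize=True)
        _write(net.adjacency, out / "network_adjacency.csv", manifest)
        _write(ei.to_frame(), out / "network_ei.csv", manifest)

    if "pca" in config.stages:
        pca = receptors.pca_varimax(table)
        _write(pca.loadings, out / "pca_loadings.csv", manifest)
        _write(pca.scores, out / "pca_scores.csv", manifest)

    model = None
    if "pmf" in config.stages:
        mu = receptors.uncertainty_matrix(table.conc, spec)
        model = receptors.pmf_fit(
            table.conc,
            mu,
            config.n_factors,
            n_runs=config.pmf_runs,
            seed=stage_seed(config.seed, "pmf"),
        )
        _write(model.G, out / "pmf_contributions.csv", manifest)
        _write(model.F, out / "pmf_profiles.csv", manifest)
        _write(model.profile_pct, out / "pmf_profile_pct.csv", manifest)
        _write(model.diagnostics, out / "pmf_diagnostics.csv", manifest)
        manifest["pmf_Q"] = model.Q

    populations = {"child": CHILD, "adult": ADULT}
    if "hra" in config.stages:
        from . import hra as hra_mod

        rows = []
        means = table.conc.mean()
        for pop_name, params in populations.items():
            for el in table.elements:
                tox = DEFAULT_TOXICITY.get(el)
                if tox is None:
                    continue
                c = float(means[el])
                if tox.RfDo is not None or tox.RfC is not None:
                    hi = float(np.asarray(hra_mod.hazard_quotients(c, params, tox).total))
                    rows.append((pop_name, el, "HI", hi, hra_mod.classify_risk(hi, "HI")))
                if tox.is_carcinogen:
                    tcr = float(
                        np.asarray(hra_mod.cancer_risks(c, AGE_ADJUSTED, tox).total)
                    )
                    rows.append((pop_name, el, "TCR", tcr, hra_mod.classify_risk(tcr, "TCR")))
        _write(
            pd.DataFrame(
                rows, columns=["population", "element", "kind", "value", "band"]
            ).set_index("population"),
            out / "hra_deterministic.csv",
            manifest,
        )

    if "mc" in config.stages:
        mc_cfg = McConfig(
            n_iter=config.mc_iterations, seed=stage_seed(config.seed, "mc")
        )
        dists = {
            el: mc_risk.fit_concentration_distribution(table.conc[el].to_numpy())
            for el in table.elements
            if el in DEFAULT_TOXICITY
        }
        summaries = []
        for pop_name, params in populations.items():
            hi = mc_risk.monte_carlo_risk(dists, params, DEFAULT_TOXICITY, mc_cfg, "HI")
            summaries.append(hi.summary())
        tcr = mc_risk.monte_carlo_risk(
            dists, AGE_ADJUSTED, DEFAULT_TOXICITY, mc_cfg, "TCR"
        )
        summaries.append(tcr.summary())
        _write(
            pd.concat(summaries, ignore_index=True).set_index("population"),
            out / "mc_summary.csv",
            manifest,
        )

    if "source_risk" in config.stages:
        assert model is not None
        apportioned = source_risk.apportion(model)
        sr_cfg = McConfig(
            n_iter=config.mc_iterations, seed=stage_seed(config.seed, "source_risk")
        )
        results = source_risk.source_health_risk(
            apportioned, CHILD, DEFAULT_TOXICITY, sr_cfg, kind="HI"
        )
        rows = [
            (
                name,
                dist.mean,
                dist.percentile,
                source_risk.no_risk_probability(dist),
            )
            for name, dist in results.items()
        ]
        _write(
            pd.DataFrame(
                rows, columns=["factor", "hi_mean", "hi_p95", "p_no_risk"]
            ).set_index("factor"),
            out / "source_risk_hi.csv",
            manifest,
        )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
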
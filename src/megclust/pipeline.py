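"""End-to-end orchestration: simulate/load -> cluster test -> trial stats.

One :class:`PipelineConfig` (usually parsed from YAML) drives the full
analysis and writes a report directory of plain-text artifacts:

    report/
      manifest.json     every parameter, seed included
      baseline.tsv      between-arm baseline comparison table
      model.json        mixed-model interaction results + effect sizes
      respondents.tsv   respondent counts per arm
      clusters.json     observed clusters: members, mass, span, p
      null_max.txt      permutation null of the max |mass|
      summary.tsv       per-cluster marker correlations (all/exp/control)
      occupancy.tsv     ROI occupancy of the top cluster (labels permitting)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cluster import SpectralClusterModel
from .datatypes import ClusterParams
from .io import load_dataset
from .simulate import (
    CohortSpec,
    EffectSpec,
    make_freq_axis,
    simulate_dataset,
    write_dataset,
)
from .trial import TrialOutcomeModel

log = logging.getLogger("megclust")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; exactly one data source."""

    out_dir: str
    dataset_dir: str | None = None
    simulation: dict | None = None  # keys: cohort, effect, n_nodes, spacing, freq
    cluster: ClusterParams = field(default_factory=ClusterParams)
    respondent_threshold_sd: float = 0.64
    power_sims: int = 200
    power_effect_sd: float = 0.64
    prestudy_odds: float = 0.5
    seed: int = 0
    write_simulated_dataset: bool = False

    def __post_init__(self) -> None:
        if (self.dataset_dir is None) == (self.simulation is None):
            raise ValueError("config needs exactly one of dataset_dir / simulation")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cluster = ClusterParams(**raw.pop("cluster", {}))
        return cls(cluster=cluster, **raw)


def _simulate_from_config(cfg: PipelineConfig):
    sim = dict(cfg.simulation or {})
    cohort_kwargs = dict(sim.get("cohort", {}))
    cohort_kwargs.setdefault("seed", cfg.seed)
    effect_kwargs = dict(sim.get("effect", {}))
    if "band" in effect_kwargs:
        effect_kwargs["band"] = tuple(effect_kwargs["band"])
    freq_kwargs = dict(sim.get("freq", {}))
    freq_axis = make_freq_axis(**freq_kwargs) if freq_kwargs else None
    return simulate_dataset(
        cohort_spec=CohortSpec(**cohort_kwargs),
        effect=EffectSpec(**effect_kwargs),
        n_nodes=int(sim.get("n_nodes", 1200)),
        spacing=float(sim.get("spacing", 10.0)),
        freq_axis=freq_axis,
        seed=cfg.seed,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the consolidated report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: data
    try:
        if config.dataset_dir is not None:
            log.info("loading dataset from %s", config.dataset_dir)
            cohort, pre, post, graph = load_dataset(config.dataset_dir)
            truth = None
        else:
            log.info("simulating dataset (seed=%d)", config.seed)
            cohort, pre, post, graph, truth = _simulate_from_config(config)
            if config.write_simulated_dataset:
                write_dataset(out / "dataset", cohort, pre, post, graph,
                              truth=truth, seed=config.seed, overwrite=True)
    except Exception as err:
        raise RuntimeError(f"stage 'data' failed: {err}") from err

    # -- stage 2: trial analytics
    try:
        log.info("trial analytics (n=%d)", cohort.n)
        trial_model = TrialOutcomeModel(
            cohort, respondent_threshold_sd=config.respondent_threshold_sd
        )
        trial_res = trial_model.fit()
        power_res = trial_res.power_ppv(
            effect_sd=config.power_effect_sd,
            alpha=0.05,
            n_sims=config.power_sims,
            seed=config.seed + 1,
            prestudy_odds=config.prestudy_odds,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'trial-stats' failed: {err}") from err

    # -- stage 3: cluster statistics
    try:
        params = dataclasses.replace(config.cluster, seed=config.seed + 2)
        log.info(
            "cluster permutation test (%d nodes, %d steps, %d permutations)",
            graph.n_nodes, pre.n_steps, params.n_permutations,
        )
        cl_model = SpectralClusterModel.from_dataset(cohort, pre, post, graph)
        cl_res = cl_model.fit(params)
    except Exception as err:
        raise RuntimeError(f"stage 'cluster-test' failed: {err}") from err

    # -- stage 4: report
    try:
        _write_report(out, config, cohort, cl_res, trial_res, power_res, truth)
    except Exception as err:
        raise RuntimeError(f"stage 'report' failed: {err}") from err
    log.info("report written to %s", out)
    return out


def _write_report(out, config, cohort, cl_res, trial_res, power_res, truth):
    trial_res.baseline.to_csv(out / "baseline.tsv", sep="\t", index=False,
                              float_format="%.6g")

    m = trial_res.mixed
    model_payload = {
        "interaction": {
            "beta": m.beta_interaction, "se": m.se, "t": m.t_value,
            "df": m.df, "p": m.p,
        },
        "lr_test": {"chi2": m.lr_chi2, "df": 1, "p": m.lr_p},
        "fit": {"aic": m.aic, "bic": m.bic, "r2": m.r2,
                "r2_adjusted": m.r2_adjusted, "age_included": m.age_included},
        "hedges_g": trial_res.hedges_g,
        "power_ppv": {
            "power": power_res.power, "n_sims": power_res.n_sims,
            "alpha": power_res.alpha, "prestudy_odds": power_res.prestudy_odds,
            "ppv": power_res.ppv,
        },
    }
    _dump_json(model_payload, out / "model.json")

    with open(out / "respondents.tsv", "w") as fh:
        fh.write("arm\tcount\tn\tproportion\n")
        for arm, (count, frac) in trial_res.respondents.items():
            n_arm = int(cohort.arm_mask(arm).sum())
            fh.write(f"{arm}\t{count}\t{n_arm}\t{frac:.6g}\n")

    freq = cl_res.model.ratio.freq_axis
    clusters_payload = []
    for c, p in zip(cl_res.clusters, cl_res.p_values):
        clusters_payload.append(
            {
                "members": sorted([int(a), int(b)] for a, b in c.members),
                "sign": c.sign,
                "mass": c.mass,
                "freq_span_steps": list(c.freq_span),
                "freq_span_hz": [float(freq[c.freq_span[0]]),
                                 float(freq[c.freq_span[1]])],
                "extent_per_step": list(c.extent_per_step),
                "p": float(p),
            }
        )
    _dump_json(
        {"clusters": clusters_payload,
         "n_permutations": cl_res.inference.n_permutations},
        out / "clusters.json",
    )
    np.savetxt(out / "null_max.txt", cl_res.inference.null_max_mass, fmt="%.17g")

    rows = []
    for i in range(len(cl_res.clusters)):
        info = cl_res.cluster_summary(i, cohort)
        for group in ("all", "experimental", "control"):
            g = info["correlation"][group]
            rows.append(
                f"{i}\t{group}\t{g['rho']:.6g}\t{g['p']:.6g}\t{g['n']}"
            )
    with open(out / "summary.tsv", "w") as fh:
        fh.write("cluster\tgroup\trho\tp\tn\n")
        for row in rows:
            fh.write(row + "\n")

    if cl_res.clusters and cl_res.model.graph.roi_labels is not None:
        occ = cl_res.roi_occupancy(0)
        occ.to_csv(out / "occupancy.tsv", sep="\t", index=False,
                   float_format="%.2f")

    manifest = {
        "seed": config.seed,
        "data_source": config.dataset_dir or "simulation",
        "simulation": config.simulation,
        "cluster_params": dataclasses.asdict(config.cluster),
        "respondent_threshold_sd": config.respondent_threshold_sd,
        "power_sims": config.power_sims,
        "power_effect_sd": config.power_effect_sd,
        "prestudy_odds": config.prestudy_odds,
        "n_participants": cohort.n,
        "n_nodes": cl_res.model.graph.n_nodes,
        "n_freq_steps": int(freq.size),
        "planted_truth_available": truth is not None,
    }
    _dump_json(manifest, out / "manifest.json")


def _json_default(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
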
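"""End-to-end orchestration: stratify, fit per group, infer, stabilize, compare.

``run_pipeline`` takes a :class:`RunConfig`, executes every stage of the
analysis on one panel, and writes a run directory in which every number in
the human-readable summary is traceable to a machine-readable CSV/JSON file.
A manifest records package versions, the seed and a config hash so identical
configurations reproduce bit-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SymptomPanel, load_panel, write_edgelist, cronbach_alpha
from .trajectory import TRAJECTORY_LABELS, stratify_cohort, split_by_trajectory
from .estimation import fit_clpn, edge_summary
from .centrality import expected_influence, network_correlation
from .stability import bootstrap_edge_ci, case_drop_cs


@dataclass
class RunConfig:
    input_path: str | None = None  # wide CSV; alternatively pass panel= to run_pipeline
    output_dir: str = "clpn_run"
    cutoff: int = 7
    covariate_columns: list = field(default_factory=list)
    use_covariates: bool = True
    seed: int = 0
    n_boot: int = 1000
    cs_reps_per_level: int = 100
    cs_threshold: float = 0.7
    cs_confidence: float = 0.95
    min_group_size: int = 50
    fast_resampling: bool = False
    run_stability: bool = True
    make_plots: bool = False
    plot_threshold: float = 0.025  # display-only edge threshold

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig, panel: SymptomPanel | None = None) -> Path:
    """Run every stage and return the run directory path."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if panel is None:
            if config.input_path is None:
                raise ValueError("either input_path or panel must be given")
            panel = load_panel(config.input_path, covariate_columns=config.covariate_columns)

        stage = "stratify"
        summary, assignments = stratify_cohort(panel, cutoff=config.cutoff)
        assignments.to_csv(outdir / "trajectory_labels.csv", index=False)
        reliability = {}
        for wave in ("t1", "t2"):
            try:
                reliability[wave] = cronbach_alpha(panel, wave)
            except ValueError:
                reliability[wave] = None
        _write_json(outdir / "cohort_summary.json", {
            "counts": summary.counts,
            "percentages": summary.percentages,
            "total_n": summary.total_n,
            "cronbach_alpha": reliability,
        })

        stage = "fit"
        groups = split_by_trajectory(panel, cutoff=config.cutoff)
        fits = {}
        for label in TRAJECTORY_LABELS:
            g = groups[label]
            if g.n_subjects < config.min_group_size:
                print(f"[clpnet] skipping group {label!r}: n={g.n_subjects} "
                      f"< min_group_size={config.min_group_size}")
                continue
            fit = fit_clpn(g, covariates=config.use_covariates, seed=config.seed)
            fits[label] = fit
            _write_json(outdir / f"fit_{label}.json", fit.to_dict())
            write_edgelist(fit, outdir / f"edges_{label}.csv")
            _write_json(outdir / f"edge_summary_{label}.json", edge_summary(fit))

        stage = "centrality"
        for label, fit in fits.items():
            tables = []
            for variant in ("overall", "cross_lagged"):
                tables.append(expected_influence(fit, variant=variant).table)
            pd.concat(tables, ignore_index=True).to_csv(outdir / f"centrality_{label}.csv", index=False)

        stage = "compare"
        labels = list(fits)
        for diag in (True, False):
            mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
            pmat = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
            for a in labels:
                for b in labels:
                    if a == b:
                        continue
                    cmp_ = network_correlation(fits[a], fits[b], include_diagonal=diag)
                    mat.loc[a, b] = cmp_.r
                    pmat.loc[a, b] = cmp_.p_value
            suffix = "with_diagonal" if diag else "off_diagonal"
            mat.to_csv(outdir / f"network_correlation_{suffix}.csv")
            pmat.to_csv(outdir / f"network_correlation_p_{suffix}.csv")

        if config.run_stability and config.n_boot > 0:
            stage = "stability"
            for label, _fit in fits.items():
                g = groups[label]
                boot = bootstrap_edge_ci(
                    g, n_boot=config.n_boot, seed=config.seed,
                    covariates=config.use_covariates, fast=config.fast_resampling,
                )
                boot.ci_table().to_csv(outdir / f"bootstrap_ci_{label}.csv", index=False)
                cs = {}
                for index in ("in_ei", "out_ei"):
                    res = case_drop_cs(
                        g, index=index, reps_per_level=config.cs_reps_per_level,
                        seed=config.seed, correlation_threshold=config.cs_threshold,
                        confidence=config.cs_confidence,
                        covariates=config.use_covariates, fast=config.fast_resampling,
                    )
                    cs[index] = {"cs": res.cs_value,
                                 "quantiles": {str(q): v for q, v in res.quantiles.items()}}
                _write_json(outdir / f"cs_{label}.json", cs)

        if config.make_plots:
            stage = "plot"
            from .plotting import plot_network
            for label, fit in fits.items():
                plot_network(fit, threshold=config.plot_threshold,
                             path=outdir / f"network_{label}.png")

        stage = "manifest"
        import clpnet
        import sklearn
        import scipy
        _write_json(outdir / "manifest.json", {
            "clpnet_version": clpnet.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "groups_fit": list(fits),
        })
    except PipelineError:
        raise
    except Exception as exc:  # preserve partial outputs, name the stage
        raise PipelineError(stage, exc) from exc
    return outdir
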
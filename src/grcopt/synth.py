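"""Synthetic ground truth and parameter-recovery experiments.

The original discharge recordings behind the feature templates are not
available, so the pipeline's accuracy is assessed on synthetic ground
truth instead: a known conductance vector G* is drawn from the
experimental search ranges, its model is simulated to produce feature
templates with the same statistical structure as the experimental table
(10 features x 3 current steps, with the experimental standard
deviations), and the optimizer must recover G* from those features
alone.  Percent errors of the recovered conductances are the headline
statistic, mirroring the deviation-from-experiment analysis of real
optimization runs.

Noise-free templates are the default (template means equal the ground
truth's features exactly; the sds only normalize the objectives), which
separates algorithmic correctness from noise robustness; Gaussian
template noise with the experimental sds is available as ``noise="sd"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .engine import simulate_batch
from .features import (FEATURE_NAMES, FeatureTemplate, detect_spikes,
                       extract_features)
from .ibea import (OptimizationConfig, Population, filter_valid,
                   run_optimization)
from .kinetics import packaged_data_path
from .morphology import CellModel
from .protocols import OPT_STEP_AMPLITUDES_PA, step_protocol
from .validation import gmax_deviation

__all__ = ["GroundTruth", "sample_ground_truth", "make_templates",
           "parameter_recovery", "experimental_sds"]


@dataclass
class GroundTruth:
    """A known conductance vector with provenance."""

    genes: np.ndarray
    names: list[str]
    seed: int
    mode: str

    def to_json(self, path: str | Path) -> None:
        d = {"genes": list(map(float, self.genes)), "names": self.names,
             "seed": self.seed, "mode": self.mode}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["genes"]), d["names"], d["seed"], d["mode"])


def _spike_counts(model: CellModel, genes: np.ndarray,
                  stimuli=OPT_STEP_AMPLITUDES_PA, duration_ms: float = 1500.0,
                  dt: float = 0.05) -> np.ndarray:
    proto = step_protocol(1.0, duration_ms=duration_ms, pre_ms=100.0,
                          post_ms=0.0)
    t, vmat = simulate_batch(model, np.tile(genes, (len(stimuli), 1)),
                             proto, dt=dt, settle_ms=400.0,
                             stim_scale=np.array(stimuli))
    return np.array([detect_spikes((t, vmat[i])).n
                     for i in range(len(stimuli))])


def sample_ground_truth(model: CellModel, seed: int, margin: float = 0.05,
                        max_tries: int = 100, min_spikes: int = 3
                        ) -> GroundTruth:
    """Draw a valid ground-truth vector from the search ranges.

    Sampling is uniform inside each range shrunk by ``margin`` of its
    width on both sides (so recovery is never a boundary artifact);
    candidates are rejected until the model fires at least
    ``min_spikes`` spikes at each of the three test amplitudes (three
    spikes guarantee every ISI-based feature is defined).
    """
    rng = np.random.default_rng(seed)
    ranges = model.parameter_ranges()
    lo = np.array([r.lo + margin * (r.hi - r.lo) for r in ranges])
    hi = np.array([r.hi - margin * (r.hi - r.lo) for r in ranges])
    for _ in range(max_tries):
        g = lo + (hi - lo) * rng.random(len(ranges))
        if (_spike_counts(model, g) >= min_spikes).all():
            return GroundTruth(g, model.gene_names(), seed, model.mode)
    raise RuntimeError(
        f"no valid ground truth in {max_tries} draws; inspect the "
        "parameter ranges (the mid-range model may not satisfy the "
        "spiking criterion)")


def experimental_sds() -> FeatureTemplate:
    """The experimental feature table (means and sds) shipped with the
    package."""
    return FeatureTemplate.from_csv(packaged_data_path(
        "experimental_features.csv"))


def make_templates(model: CellModel, gt: GroundTruth, noise: str = "none",
                   noise_seed: int = 0, cfg: OptimizationConfig | None = None
                   ) -> FeatureTemplate:
    """Feature templates derived from a ground-truth simulation.

    Means are the features extracted from G*'s traces at 10/16/22 pA
    (plus Gaussian noise scaled by the experimental sds when
    ``noise="sd"``); sds are always the experimental ones, so objective
    normalization matches the real optimization setup.
    """
    if cfg is None:
        cfg = OptimizationConfig()
    stimuli = tuple(sorted(cfg.stimuli_pA))
    proto = step_protocol(1.0, duration_ms=cfg.trace_ms, pre_ms=cfg.pre_ms,
                          post_ms=0.0)
    t, vmat = simulate_batch(model, np.tile(gt.genes, (len(stimuli), 1)),
                             proto, dt=cfg.dt_ms, settle_ms=cfg.settle_ms,
                             stim_scale=np.array(stimuli))
    exp = experimental_sds()
    rng = np.random.default_rng(noise_seed)
    table: dict = {}
    for k, stim in enumerate(stimuli):
        sp = detect_spikes((t, vmat[k]))
        fs = extract_features((t, vmat[k]), sp,
                              (cfg.pre_ms, cfg.pre_ms + cfg.trace_ms),
                              stimulus_pA=stim)
        if fs.missing():
            raise ValueError(
                f"ground truth misses features {fs.missing()} at "
                f"{stim} pA; re-sample it")
        table[stim] = {}
        for name in FEATURE_NAMES:
            sd = exp.sd(stim, name)
            mu = fs.value(name)
            if noise == "sd":
                mu += rng.normal(0.0, sd)
            elif noise != "none":
                raise ValueError(f"unknown noise mode {noise!r}")
            table[stim][name] = (mu, sd)
    return FeatureTemplate(table)


def parameter_recovery(model: CellModel, gt: GroundTruth,
                       cfg: OptimizationConfig,
                       template: FeatureTemplate | None = None,
                       progress=None) -> dict:
    """Run the optimizer against ground-truth templates and score it.

    Returns a report with the per-gene percent error of the best valid
    individual, the valid-population mean deviation, the valid fraction
    and the fitness trajectories.  ``failed`` is set when no individual
    of the final population passes the three-step spiking criterion.
    """
    if template is None:
        template = make_templates(model, gt, cfg=cfg)
    results, pop = run_optimization(model, template, cfg,
                                    progress=progress)
    valid, frac = filter_valid(pop)
    report: dict = {
        "gene_names": gt.names,
        "ground_truth": gt.genes.tolist(),
        "valid_fraction": frac,
        "cycles": [{"best_fitness": r.best_fitness,
                    "mean_fitness": r.mean_fitness,
                    "best_objective_sum": r.best_objective_sum,
                    "evaluations": r.evaluations} for r in results],
    }
    if valid.size == 0:
        report["failed"] = True
        report["diagnostics"] = ("no valid individual in the final "
                                 "population; all failed the three-step "
                                 "spiking criterion")
        return report
    report["failed"] = False
    best_idx = int(np.argmin(valid.objective_sum()))
    best = valid.genes[best_idx]
    dev_best = gmax_deviation(best, gt.genes, gt.names)
    dev_pop = gmax_deviation(valid.genes, gt.genes, gt.names)
    report.update({
        "best_genes": best.tolist(),
        "best_objective_sum": float(valid.objective_sum()[best_idx]),
        "best_per_gene_percent": dev_best.per_gene_percent.tolist(),
        "best_mean_percent": dev_best.mean_percent,
        "best_median_percent": float(np.median(dev_best.per_gene_percent)),
        "population_per_gene_percent": dev_pop.per_gene_percent.tolist(),
        "population_mean_percent": dev_pop.mean_percent,
    })
    return report
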
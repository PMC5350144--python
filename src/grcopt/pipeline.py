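"""End-to-end pipeline: synthesize -> optimize -> filter -> validate.

Everything a run needs is declared in a :class:`RunConfig`; outputs are
written only under the run's output directory together with a manifest
recording versions, seeds, configs and output checksums, so a run can be
audited and reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FeatureTemplate
from .ibea import OptimizationConfig, filter_valid, run_optimization
from .morphology import build_model
from .kinetics import packaged_data_path
from .synth import GroundTruth, make_templates, parameter_recovery, \
    sample_ground_truth
from .validation import (fi_curve, gmax_deviation, inward_rectification,
                         input_resistance, near_threshold_oscillations,
                         zap_resonance)

log = logging.getLogger("grcopt")

__all__ = ["RunConfig", "run_pipeline", "load_opt_config"]


@dataclass
class RunConfig:
    model: str = "mono"
    template: str | None = None      # None -> synthetic ground truth
    opt: str | None = None           # YAML path or None for defaults
    out_dir: str = "run"
    seed: int = 0
    verbosity: int = 1
    synth: bool = True
    validate: bool = True

    def check(self) -> None:
        for p in (self.template, self.opt):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.model not in ("mono", "multi") and \
                not Path(self.model).exists():
            raise FileNotFoundError(self.model)


def load_opt_config(path: str | None, seed: int | None = None,
                    **overrides) -> OptimizationConfig:
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    if seed is not None:
        data["seed"] = seed
    if "stimuli_pA" in data:
        data["stimuli_pA"] = tuple(data["stimuli_pA"])
    return OptimizationConfig(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest dict.

    Any stage failure is recorded in the manifest (with the failing
    stage) before the exception propagates; partial artifacts are kept.
    """
    cfg.check()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.DEBUG if cfg.verbosity > 1 else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    manifest: dict = {
        "grcopt_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "seed": cfg.seed,
        "model": cfg.model,
        "stages": [],
        "outputs": {},
    }

    def record(stage: str):
        manifest["stages"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        model = build_model(cfg.model)
        opt = load_opt_config(cfg.opt, seed=cfg.seed)
        manifest["opt_config"] = {k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in vars(opt).items()}

        if cfg.template is not None:
            template = FeatureTemplate.from_csv(cfg.template)
            gt = None
        elif cfg.synth:
            log.info("sampling synthetic ground truth (seed %d)", cfg.seed)
            gt = sample_ground_truth(model, cfg.seed)
            gt.to_json(out / "gt.json")
            template = make_templates(model, gt, cfg=opt)
            template.to_csv(out / "templates.csv")
            record("synth")
        else:
            raise ValueError("no template given and synth disabled")

        log.info("optimizing: pop %d, %d generations x %d cycles",
                 opt.population_size, opt.generations, opt.cycles)

        def progress(cycle, gen, res):
            log.info("cycle %d gen %d: best fitness %.4g, best objective "
                     "sum %.4g", cycle, gen, res.best_fitness[-1],
                     res.best_objective_sum[-1])

        results, pop = run_optimization(model, template, opt,
                                        progress=progress)
        stats = []
        for ci, r in enumerate(results):
            for gi in range(len(r.best_fitness)):
                stats.append({"cycle": ci, "generation": gi,
                              "best_fitness": r.best_fitness[gi],
                              "mean_fitness": r.mean_fitness[gi],
                              "best_objective_sum": r.best_objective_sum[gi]})
        pd.DataFrame(stats).to_csv(out / "generations.csv", index=False)
        record("optimize")

        valid, frac = filter_valid(pop)
        final = {
            "gene_names": model.gene_names(),
            "valid_fraction": frac,
            "population": [{"genes": g.tolist(), "objective_sum": float(s)}
                           for g, s in zip(pop.genes, pop.objective_sum())],
        }
        if gt is not None and valid.size:
            best = valid.genes[int(np.argmin(valid.objective_sum()))]
            dev = gmax_deviation(best, gt.genes, gt.names)
            final["best_vs_ground_truth_percent"] = \
                dev.per_gene_percent.tolist()
            final["best_mean_deviation_percent"] = dev.mean_percent
        (out / "final_population.json").write_text(
            json.dumps(final, indent=1))
        record("filter_valid")

        if cfg.validate and valid.size:
            best = valid.genes[int(np.argmin(valid.objective_sum()))]
            log.info("validating best valid individual")
            fi = fi_curve(model, gvec=best)
            rect = inward_rectification(model, gvec=best)
            rin = input_resistance(model, gvec=best)
            report = {
                "fi_slope_hz_per_pA": fi.slope_hz_per_pA,
                "fi_frequencies_hz": fi.frequency_hz.tolist(),
                "fi_delays_ms": fi.first_spike_delay_ms.tolist(),
                "rectification_index": rect["rectification_index"],
                "input_resistance_GOhm": rin,
            }
            (out / "validation.json").write_text(json.dumps(report,
                                                            indent=1))
            record("validate")
    except Exception as exc:
        manifest["failed_at"] = manifest["stages"][-1] if \
            manifest["stages"] else "setup"
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
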
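"""Run configuration and the end-to-end pipeline.

A YAML file drives a full run: simulate a seascape (or point at raster and
table files), derive covariates, filter the count matrix, fit the joint
model, run diagnostics and evaluation, screen associations, and map
predictions.  Every stage writes its artifact into the run directory with a
manifest recording the configuration hash and seeds, so a rerun with the
same file reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("seascapejsdm")


@dataclass
class RunConfig:
    output_dir: str = "run"
    seed: int = 0
    # either simulate ...
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)
    # ... or read these inputs
    bathymetry_path: str | None = None
    substratum_paths: list[str] = field(default_factory=list)
    substratum_classes: list[str] = field(default_factory=list)
    deployments_path: str | None = None
    counts_path: str | None = None
    # analysis settings
    cutoffs: dict = field(default_factory=dict)
    radii_m: list[float] = field(default_factory=lambda: [500.0, 1000.0, 1500.0])
    rare_fraction: float = 0.10
    model: dict = field(default_factory=dict)  # ModelSpec kwargs
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)  # MCMCSettings kwargs
    cv_folds: int = 5
    run_cv: bool = False
    run_selection: bool = False
    selection_pool: list = field(default_factory=lambda: ["depth", "boundary_dist",
                                                          "diversity", "substratum"])
    prediction_year: int | str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for p in [cfg.bathymetry_path, cfg.deployments_path, cfg.counts_path,
                  *cfg.substratum_paths]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig, until: str | None = None) -> Path:
    """Execute the pipeline and return the run directory.

    ``until`` stops after the named stage (one of simulate/load, metrics,
    counts, filter, select, fit, diagnose, evaluate, associations,
    predict).
    """
    from . import (
        associations,
        community,
        design,
        diagnostics,
        evaluation,
        io,
        metrics,
        prediction,
        synthetic,
    )
    from .mcmc import MCMCSettings, PriorSpec

    import sys

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    log.propagate = False
    fh = logging.FileHandler(out / "run.log")
    sh = logging.StreamHandler(sys.stderr)
    log.addHandler(fh)
    log.addHandler(sh)
    manifest: dict = {"config_digest": config.digest(), "seed": config.seed,
                      "stages": {}}

    class _Stop(Exception):
        pass

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    def stop_after(name):
        if until == name:
            raise _Stop

    try:
        if config.simulate:
            stage("simulate")
            sc = synthetic.SyntheticConfig(**{"seed": config.seed, **config.synthetic})
            bathy = synthetic.generate_bathymetry(sc)
            sub = synthetic.generate_substratum_probabilities(bathy, sc)
            deployments = synthetic.sample_deployments(bathy, sc)
            io.write_substratum_rasters(out / "rasters", sub)
            from .raster import write_ascii_grid
            write_ascii_grid(out / "rasters" / "bathymetry.asc", bathy)
            io.write_deployments(out / "deployments.csv", deployments)
            cutoffs = config.cutoffs or synthetic.default_cutoffs(sc.classes)
        else:
            stage("load")
            from .raster import read_ascii_grid
            bathy = read_ascii_grid(config.bathymetry_path)
            sub = io.read_substratum_rasters(
                config.substratum_paths, config.substratum_classes
            )
            deployments = io.read_deployments(config.deployments_path)
            cutoffs = config.cutoffs
            if not cutoffs:
                raise ValueError("cutoffs required when reading external rasters")
        stop_after("simulate")
        stop_after("load")

        stage("metrics")
        patchmap = metrics.classify_patches(sub, cutoffs)
        features = metrics.deployment_features(
            deployments, sub, patchmap, bathy, radii_m=tuple(config.radii_m)
        )
        features.to_csv(out / "deployment_features.csv", index=False)
        stop_after("metrics")

        stage("counts")
        if config.counts_path:
            counts = io.read_counts(config.counts_path)
            counts = counts.loc[features["deployment_id"]]
        else:
            import numpy as np

            spec0 = design.ModelSpec.final_model(
                diversity_radius_m=min(config.radii_m), n_factors=1
            )
            dm = design.build_design_matrix(features, spec0)
            true = synthetic.TrueParameters(
                species=[f"sp{j}" for j in range(5)],
                alpha=[0.8] * 5,
                beta=np.random.default_rng(config.seed).normal(
                    0, 0.3, size=(dm.n_columns - 1, 5)
                ),
                beta_columns=dm.columns[1:],
                sigma_site=0.3,
                sigma_year=0.3,
                loadings=[[0.7], [0.5], [-0.6], [0.2], [0.1]],
            )
            sim = synthetic.simulate_counts(
                dm.matrix[:, 1:], true, features["site"], features["year"],
                seed=config.seed + 1,
            )
            counts = sim.counts
            counts.index = dm.index
        io.write_counts(out / "counts.csv", counts)
        stop_after("counts")

        stage("filter")
        counts, report = community.filter_rare_species(
            counts, features["site"], features["year"], fraction=config.rare_fraction
        )
        (out / "removed_species.txt").write_text("\n".join(report.removed) + "\n")
        stop_after("filter")

        spec = design.ModelSpec(**config.model) if config.model else (
            design.ModelSpec.final_model(diversity_radius_m=min(config.radii_m),
                                         n_factors=2)
        )
        priors = PriorSpec(**config.priors)
        if config.run_selection or until == "select":
            stage("select")
            search = MCMCSettings(chains=2, iterations=1200, burn_in=400,
                                  seed=config.seed)
            spec, trace = evaluation.stepwise_select(
                pool=list(config.selection_pool), counts=counts,
                features=features,
                base=design.ModelSpec.intercept_only(n_factors=1),
                priors=priors, settings=search,
            )
            trace.to_frame().to_csv(out / "selection_trace.csv", index=False)
        stop_after("select")

        stage("fit")
        settings = MCMCSettings(**{"seed": config.seed, **config.mcmc})
        post = evaluation.fit_model(counts, features, spec, priors, settings)
        io.write_posterior(out / "posterior", post)
        stop_after("fit")

        stage("diagnose")
        conv = diagnostics.summarize_convergence(post)
        (out / "convergence.json").write_text(json.dumps(
            {k: (v.tolist() if hasattr(v, "tolist") else v) for k, v in conv.items()},
            indent=2,
        ))
        stop_after("diagnose")

        stage("evaluate")
        w = evaluation.waic(post, counts)
        vp = evaluation.variance_partition(post)
        vp.to_csv(out / "variance_partition.csv")
        results = {"waic": w}
        if config.run_cv:
            cv = evaluation.kfold_cv(counts, features, spec, k=config.cv_folds,
                                     priors=priors, seed=config.seed)
            cv.rmse.to_csv(out / "cv_rmse.csv")
            results["mean_cv_rmse"] = cv.mean_rmse
        (out / "evaluation.json").write_text(json.dumps(results, indent=2))
        stop_after("evaluate")

        stage("associations")
        if spec.n_factors:
            R = associations.residual_correlation_draws(post.loading_draws())
            assoc = associations.screen_associations(R, species=post.species)
            assoc.to_frame().to_csv(out / "associations.csv", index=False)
        stop_after("associations")

        stage("predict")
        conditioning = {}
        if config.prediction_year is not None:
            conditioning["year"] = config.prediction_year
        pred = prediction.predict_grid(post, patchmap, bathy, spec, conditioning)
        area = prediction.percent_area_present(pred)
        area.to_csv(out / "percent_area_present.csv")
        for sp in pred.species:
            from .raster import write_ascii_grid
            write_ascii_grid(out / f"prediction_{sp}.asc", pred.as_raster(sp))
    except _Stop:
        pass
    except Exception as exc:  # noqa: BLE001
        failed = [s for s in manifest["stages"]][-1] if manifest["stages"] else "load"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc
    finally:
        log.removeHandler(fh)
        log.removeHandler(sh)
        fh.close()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
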
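"""Experiment orchestration: simulate -> graphs -> train -> predict ->
bias-correct -> stats, with a thin click CLI on top.

The experiment shape mirrors the study design: several structure
configurations (all structures together, cortex only, subcortical only, or
one subcortical structure), several training seeds per configuration,
ensemble + test-time-augmentation inference, per-configuration bias
correction fitted on the validation set, and cross-sectional plus
longitudinal statistics on the test set.  Subjects with repeated scans are
routed to the test set; training and validation draw from single-scan
subjects, and the split is at the subject level so no subject leaks across
sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias_correction import apply_bias, fit_bias
from .coarsening import binary_partition
from .gcnn import (
    AgeNetwork,
    AgeNetworkConfig,
    InferenceConfig,
    ScanDataset,
    TrainingConfig,
    evaluate_predictions,
    predict_cohort,
    train,
)
from .mesh_graph import (
    STRUCTURE_LABELS,
    build_features,
    merge_graphs,
    mesh_to_graph,
    scan_centering_offset,
)
from .stats import (
    aging_slope_percent,
    fit_cross_sectional,
    fit_longitudinal,
    select_longitudinal_cohort,
)
from .synthetic_data import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

__all__ = [
    "ExperimentConfig",
    "structures_for_config",
    "split_cohort",
    "run_experiment",
    "load_experiment_config",
    "cli",
]

logger = logging.getLogger(__name__)

SUBCORTICAL = tuple(s for s in STRUCTURE_LABELS if s != "cortex")


def configure_logging(debug: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if debug else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


def structures_for_config(name: str) -> tuple[str, ...]:
    """Map a structure-configuration name to the structures it feeds."""
    if name == "all":
        return STRUCTURE_LABELS
    if name == "subcortical":
        return SUBCORTICAL
    if name in STRUCTURE_LABELS:
        return (name,)
    raise ValueError(f"unknown structure configuration {name!r}")


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs, serializable to YAML."""

    structure_configs: tuple[str, ...] = ("accumbens",)
    seeds: tuple[int, ...] = (0, 1)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    network: AgeNetworkConfig = field(default_factory=AgeNetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    split_fractions: tuple[float, float, float] = (0.7, 0.3, 0.0)

    def __post_init__(self) -> None:
        if not self.structure_configs:
            raise ValueError("at least one structure configuration is required")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    """Read an experiment config from a YAML file (missing keys default)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("cohort", CohortConfig),
        ("network", AgeNetworkConfig),
        ("training", TrainingConfig),
        ("inference", InferenceConfig),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = kwargs[key]
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            kwargs[key] = cls(**sub)
    for key in ("structure_configs", "seeds", "split_fractions"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return ExperimentConfig(**kwargs)


def split_cohort(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float],
    seed: int,
) -> dict[str, list[str]]:
    """Subject-level train/validation/test split.

    Subjects with repeated scans go to the test set; train and validation
    are drawn at random from single-scan subjects (remaining single-scan
    subjects join the test set).  Fractions apply to the single-scan pool
    and must sum to 1.
    """
    if abs(sum(fractions) - 1) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts = manifest.groupby("subject_id")["scan_id"].count()
    multi = sorted(counts[counts > 1].index)
    single = sorted(counts[counts == 1].index)
    if not single and (fractions[0] > 0 or fractions[1] > 0):
        raise ValueError("no single-scan subjects available for train/validation")
    rng = np.random.default_rng(seed)
    single = list(np.array(single)[rng.permutation(len(single))])
    n_train = int(round(fractions[0] * len(single)))
    n_val = int(round(fractions[1] * len(single)))
    n_val = min(n_val, len(single) - n_train)
    split = {
        "train": sorted(single[:n_train]),
        "validation": sorted(single[n_train : n_train + n_val]),
        "test": sorted(single[n_train + n_val :] + multi),
    }
    assert not (set(split["train"]) & set(split["validation"]))
    assert not (set(split["train"]) & set(split["test"]))
    assert not (set(split["validation"]) & set(split["test"]))
    return split


def cohort_dataset(cohort: SyntheticCohort, structures: tuple[str, ...]) -> ScanDataset:
    """Features for every scan of the manifest under one structure
    configuration, with per-scan centering shared across structures."""
    missing = [s for s in structures if s not in cohort.templates]
    if missing:
        raise ValueError(f"cohort was not generated with structures {missing}")
    graphs = [mesh_to_graph(cohort.templates[s].mesh) for s in structures]
    by_id = {s.subject_id: s for s in cohort.subjects}
    feats, ages, sids, scids = [], [], [], []
    for row in cohort.manifest.itertuples():
        subj = by_id[row.subject_id]
        meshes = [cohort.scan_mesh(subj, int(row.scan_index), s) for s in structures]
        offset = scan_centering_offset(meshes)
        fmats = [build_features([m], centering_offset=offset) for m in meshes]
        _, stacked = merge_graphs(graphs, fmats)
        feats.append(stacked)
        ages.append(row.age_at_scan)
        sids.append(row.subject_id)
        scids.append(row.scan_id)
    return ScanDataset(np.stack(feats), np.array(ages), sids, scids)


def _subset(dataset: ScanDataset, subjects: set[str]) -> ScanDataset:
    idx = [i for i, s in enumerate(dataset.subject_ids) if s in subjects]
    return ScanDataset(
        dataset.features[idx],
        dataset.ages[idx],
        [dataset.subject_ids[i] for i in idx],
        [dataset.scan_ids[i] for i in idx],
    )


def run_experiment(
    config: ExperimentConfig,
    output_dir: str | Path,
    resume: bool = False,
) -> dict:
    """Run the full pipeline; returns a summary dict and writes a
    deterministic result tree (cohort/, models/, predictions/, bias/,
    stats/) plus a provenance manifest."""
    out = Path(output_dir)
    if out.exists() and any(out.iterdir()) and not resume:
        if not (out / "experiment.json").exists():
            raise FileExistsError(
                f"{out} is non-empty; pass resume=True to continue a prior run"
            )
    for sub in ("cohort", "models", "predictions", "bias", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    logger.info("generating cohort (seed %d)", config.cohort.seed)
    cohort = generate_cohort(config.cohort)
    write_cohort(cohort, out / "cohort", meshes=False)
    split = split_cohort(cohort.manifest, config.split_fractions, config.cohort.seed)
    with open(out / "cohort" / "split.json", "w") as fh:
        json.dump(split, fh, indent=1)

    summary: dict = {"structure_configs": {}, "config_hash": config.config_hash()}
    all_predictions = []
    for name in config.structure_configs:
        pred_path = out / "predictions" / f"{name}.csv"
        if resume and pred_path.exists():
            logger.info("%s: predictions exist, skipping (resume)", name)
            all_predictions.append(pd.read_csv(pred_path))
            continue
        structures = tuple(
            s for s in structures_for_config(name) if s in cohort.templates
        )
        if not structures:
            raise ValueError(
                f"configuration {name!r} needs structures absent from the cohort"
            )
        logger.info("%s: building graph and hierarchy", name)
        graphs = [mesh_to_graph(cohort.templates[s].mesh) for s in structures]
        graph, _ = merge_graphs(graphs)
        n_levels = config.network.n_residual_blocks + 1
        hierarchy = binary_partition(graph, n_levels)
        hierarchy.save(out / "models" / f"{name}_hierarchy.npz")

        dataset = cohort_dataset(cohort, structures)
        train_set = _subset(dataset, set(split["train"]))
        val_set = _subset(dataset, set(split["validation"]))
        test_set = _subset(dataset, set(split["test"]))

        networks = []
        for seed in config.seeds:
            logger.info("%s: training seed %d", name, seed)
            net = AgeNetwork(
                hierarchy,
                dataset.features.shape[2],
                config.network,
                seed=seed,
                structure_config=name,
            )
            cfg = dataclasses.replace(config.training, seed=seed)
            history = train(net, train_set, val_set, cfg)
            np.save(
                out / "models" / f"{name}_seed{seed}_history.npy",
                np.array(history["val_mae"]),
            )
            networks.append(net)

        logger.info("%s: validation predictions for bias model", name)
        val_preds = predict_cohort(
            networks,
            val_set,
            config.inference,
            np.random.default_rng(config.cohort.seed + 101),
        )
        raw_val = np.array([p.aggregated for p in val_preds])
        bias_model = fit_bias(val_set.ages, raw_val, structure_config=name)
        bias_model.save(out / "bias" / f"{name}_bias.pkl")

        logger.info("%s: test predictions (%d nets x TTA %d)", name,
                    len(networks), config.inference.test_tta)
        test_preds = predict_cohort(
            networks,
            test_set,
            config.inference,
            np.random.default_rng(config.cohort.seed + 202),
        )
        rows = []
        for p, true_age in zip(test_preds, test_set.ages):
            corrected = apply_bias(bias_model, p)  # deployment: reference = predicted
            corrected_eval = apply_bias(bias_model, p.aggregated, reference_age=true_age)
            rows.append(
                {
                    "scan_id": p.scan_id,
                    "structure_config": name,
                    "n_estimates": p.n_estimates,
                    "age_pred_raw_mean": p.aggregated,
                    "age_pred_corrected": corrected,
                    # evaluation-style correction (reference = true age), the
                    # variant the statistical analyses consume
                    "age_pred_corrected_eval": corrected_eval,
                    "age_true": true_age,
                }
            )
        pred_df = pd.DataFrame(rows)
        pred_df.to_csv(pred_path, index=False)
        all_predictions.append(pred_df)
        metrics = evaluate_predictions(
            pred_df["age_pred_corrected"], pred_df["age_true"]
        )
        summary["structure_configs"][name] = metrics
        logger.info("%s: test MAE %.2f y, r %.3f", name, metrics["MAE"], metrics["pearson_r"])

    stats_summary = _run_stats(cohort, all_predictions, out / "stats")
    summary["stats"] = stats_summary
    with open(out / "experiment.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config": dataclasses.asdict(config),
                "config_hash": config.config_hash(),
                "summary": summary,
            },
            fh,
            indent=1,
            default=str,
        )
    return summary


def _run_stats(cohort, prediction_frames, stats_dir: Path) -> dict:
    """Join predictions to the manifest and run both analyses on the test
    scans, writing tidy CSV tables."""
    stats_dir.mkdir(exist_ok=True)
    wide = None
    for df in prediction_frames:
        name = df["structure_config"].iloc[0]
        col = (
            "age_pred_corrected_eval"
            if "age_pred_corrected_eval" in df.columns
            else "age_pred_corrected"
        )
        piv = df[["scan_id", col]].rename(columns={col: f"pa_{name}"})
        wide = piv if wide is None else wide.merge(piv, on="scan_id")
    merged = cohort.manifest.merge(wide, on="scan_id")
    structure_cols = [c for c in merged.columns if c.startswith("pa_")]
    out: dict = {}

    baseline = merged[merged["delta_scan"] == 0]
    if set(baseline["diagnosis"].unique()) >= {"healthy", "MCI", "ADD"}:
        fits = fit_cross_sectional(baseline, structure_cols)
        rows = []
        for col, fit in fits.items():
            for term in ("MCI", "ADD"):
                r = fit.coefficients.loc[fit.coefficients["term"] == term].iloc[0]
                rows.append(
                    {
                        "structure": col[3:],
                        "contrast": term,
                        "estimate": r["estimate"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p": r["p"],
                        "p_fdr": r["p_fdr"],
                    }
                )
        pd.DataFrame(rows).to_csv(stats_dir / "cross_sectional.csv", index=False)
        out["cross_sectional"] = {
            f"{r['structure']}_{r['contrast']}": r["estimate"] for r in rows
        }
    else:
        logger.info("cross-sectional analysis skipped: missing diagnosis levels at baseline")

    groups = select_longitudinal_cohort(merged)
    if len(groups) and groups["group"].nunique() == 3:
        fits = fit_longitudinal(merged, groups, structure_cols)
        rows = []
        for col, fit in fits.items():
            slopes = aging_slope_percent(fit)
            for conv in ("MCI_converter", "ADD_converter"):
                r = fit.coefficients.loc[
                    fit.coefficients["term"] == f"contrast_{conv}_minus_non"
                ].iloc[0]
                rows.append(
                    {
                        "structure": col[3:],
                        "contrast": conv,
                        "slope_per_year": fit.group_slopes[conv],
                        "slope_percent": slopes[conv],
                        "estimate": r["estimate"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p": r["p"],
                        "p_fdr": r["p_fdr"],
                    }
                )
        pd.DataFrame(rows).to_csv(stats_dir / "longitudinal.csv", index=False)
        out["longitudinal"] = {
            f"{r['structure']}_{r['contrast']}": r["slope_percent"] for r in rows
        }
    else:
        logger.info("longitudinal analysis skipped: not all conversion groups present")
    return out


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--debug", is_flag=True, help="verbose shape/spectrum logging")
def cli(debug: bool) -> None:
    """Structure-wise brain-age estimation on surface meshes."""
    configure_logging(debug)


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", required=True, type=click.Path())
@click.option("--meshes/--no-meshes", default=True, help="write per-scan PLY files")
def simulate(config_path, out, meshes):
    """Generate a synthetic cohort (meshes + manifest + truth table)."""
    cfg = load_experiment_config(config_path) if config_path else ExperimentConfig()
    cohort = generate_cohort(cfg.cohort)
    write_cohort(cohort, out, meshes=meshes)
    click.echo(f"cohort written to {out} ({len(cohort.manifest)} scans)")


@cli.command("prepare-graphs")
@click.option("--structures", default="accumbens", help="comma-separated structure list")
@click.option("--levels", default=4, type=int)
@click.option("--seed", default=0, type=int)
@click.option("--out", required=True, type=click.Path())
def prepare_graphs(structures, levels, seed, out):
    """Build and save the coarsening hierarchy of a structure configuration."""
    from .synthetic_data import make_template

    names = tuple(structures.split(","))
    graphs = [mesh_to_graph(make_template(s, seed=seed).mesh) for s in names]
    graph, _ = merge_graphs(graphs)
    hierarchy = binary_partition(graph, levels)
    hierarchy.save(out)
    click.echo(f"hierarchy with scales {hierarchy.node_counts} saved to {out}")


@cli.command()
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--fractions", default="0.7,0.3,0.0")
@click.option("--seed", default=0, type=int)
@click.option("--out", required=True, type=click.Path())
def split(manifest, fractions, seed, out):
    """Subject-level train/validation/test split of a cohort manifest."""
    df = pd.read_csv(manifest, comment="#")
    fracs = tuple(float(x) for x in fractions.split(","))
    result = split_cohort(df, fracs, seed)
    with open(out, "w") as fh:
        json.dump(result, fh, indent=1)
    click.echo(
        "split sizes: "
        + ", ".join(f"{k}={len(v)}" for k, v in result.items())
    )


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", required=True, type=click.Path())
@click.option("--resume", is_flag=True)
def run(config_path, out, resume):
    """Run the full experiment: simulate, train, predict, correct, stats."""
    cfg = load_experiment_config(config_path) if config_path else ExperimentConfig()
    summary = run_experiment(cfg, out, resume=resume)
    click.echo(json.dumps(summary, indent=1, default=str))


def _stage_inputs(cfg: ExperimentConfig, name: str):
    """Cohort, split and hierarchy shared by the train/predict stages."""
    cohort = generate_cohort(cfg.cohort)
    sp = split_cohort(cohort.manifest, cfg.split_fractions, cfg.cohort.seed)
    structures = tuple(s for s in structures_for_config(name) if s in cohort.templates)
    graphs = [mesh_to_graph(cohort.templates[s].mesh) for s in structures]
    graph, _ = merge_graphs(graphs)
    hierarchy = binary_partition(graph, cfg.network.n_residual_blocks + 1)
    dataset = cohort_dataset(cohort, structures)
    return cohort, sp, hierarchy, dataset


@cli.command("train")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--structure", default="accumbens",
              help="structure configuration: a structure name, 'all' or 'subcortical'")
@click.option("--seed", default=0, type=int)
@click.option("--out", required=True, type=click.Path(), help="model output directory")
def train_cmd(config_path, structure, seed, out):
    """Train one network (one structure configuration, one seed)."""
    cfg = load_experiment_config(config_path) if config_path else ExperimentConfig()
    cohort, sp, hierarchy, dataset = _stage_inputs(cfg, structure)
    train_set = _subset(dataset, set(sp["train"]))
    val_set = _subset(dataset, set(sp["validation"]))
    net = AgeNetwork(hierarchy, dataset.features.shape[2], cfg.network,
                     seed=seed, structure_config=structure)
    history = train(net, train_set, val_set,
                    dataclasses.replace(cfg.training, seed=seed))
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    hierarchy.save(out_dir / f"{structure}_hierarchy.npz")
    net.save(out_dir / f"{structure}_seed{seed}.pkl")
    click.echo(
        f"trained {structure} seed {seed}: best val MAE "
        f"{min(history['val_mae']):.2f} y over {len(history['val_mae'])} epochs"
    )


@cli.command("predict")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--models", "models_dir", required=True, type=click.Path(exists=True))
@click.option("--structure", default="accumbens")
@click.option("--tta", default=None, type=int, help="override test-time augmentations")
@click.option("--out", required=True, type=click.Path())
def predict_cmd(config_path, models_dir, structure, tta, out):
    """Ensemble + TTA predictions for the test scans, written as CSV."""
    from .coarsening import CoarseningHierarchy

    cfg = load_experiment_config(config_path) if config_path else ExperimentConfig()
    if tta is not None:
        cfg = dataclasses.replace(cfg, inference=dataclasses.replace(cfg.inference, test_tta=tta))
    models_dir = Path(models_dir)
    hierarchy = CoarseningHierarchy.load(models_dir / f"{structure}_hierarchy.npz")
    networks = [
        AgeNetwork.load(p, hierarchy)
        for p in sorted(models_dir.glob(f"{structure}_seed*.pkl"))
    ]
    if not networks:
        raise click.ClickException(f"no checkpoints for {structure} in {models_dir}")
    cohort, sp, _, dataset = _stage_inputs(cfg, structure)
    test_set = _subset(dataset, set(sp["test"]))
    preds = predict_cohort(networks, test_set, cfg.inference,
                           np.random.default_rng(cfg.cohort.seed + 202))
    pd.DataFrame(
        {
            "scan_id": [p.scan_id for p in preds],
            "structure_config": structure,
            "n_estimates": [p.n_estimates for p in preds],
            "age_pred_raw_mean": [p.aggregated for p in preds],
            "age_true": test_set.ages,
        }
    ).to_csv(out, index=False)
    click.echo(f"{len(preds)} predictions written to {out}")


@cli.command("stats-cross")
@click.option("--predictions", required=True, type=click.Path(exists=True),
              help="CSV joining scan_id to corrected structure ages (pa_* columns)")
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def stats_cross(predictions, manifest, out):
    """Cross-sectional OLS of structure age on age + diagnosis (baseline scans)."""
    pred = pd.read_csv(predictions)
    man = pd.read_csv(manifest, comment="#")
    merged = man.merge(pred, on="scan_id")
    cols = [c for c in merged.columns if c.startswith("pa_")]
    baseline = merged[merged["delta_scan"] == 0]
    fits = fit_cross_sectional(baseline, cols)
    rows = []
    for col, fit in fits.items():
        for term in ("MCI", "ADD"):
            r = fit.coefficients.loc[fit.coefficients["term"] == term].iloc[0]
            rows.append({"structure": col[3:], "contrast": term, **r.to_dict()})
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(f"cross-sectional table written to {out}")


@cli.command("stats-long")
@click.option("--predictions", required=True, type=click.Path(exists=True))
@click.option("--manifest", required=True, type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def stats_long(predictions, manifest, out):
    """Longitudinal mixed model of structure age and aging-pace ratios."""
    pred = pd.read_csv(predictions)
    man = pd.read_csv(manifest, comment="#")
    merged = man.merge(pred, on="scan_id")
    cols = [c for c in merged.columns if c.startswith("pa_")]
    groups = select_longitudinal_cohort(merged)
    fits = fit_longitudinal(merged, groups, cols)
    rows = []
    for col, fit in fits.items():
        slopes = aging_slope_percent(fit)
        for conv in ("MCI_converter", "ADD_converter"):
            r = fit.coefficients.loc[
                fit.coefficients["term"] == f"contrast_{conv}_minus_non"
            ].iloc[0]
            rows.append(
                {
                    "structure": col[3:],
                    "contrast": conv,
                    "slope_percent": slopes[conv],
                    **r.to_dict(),
                }
            )
    pd.DataFrame(rows).to_csv(out, index=False)
    click.echo(f"longitudinal table written to {out}")


@cli.command("bias-fit")
@click.option("--predictions", required=True, type=click.Path(exists=True),
              help="CSV with age_true and age_pred_raw_mean columns")
@click.option("--name", default="structure")
@click.option("--out", required=True, type=click.Path())
def bias_fit(predictions, name, out):
    """Fit a bias model from validation predictions."""
    df = pd.read_csv(predictions)
    model = fit_bias(df["age_true"], df["age_pred_raw_mean"], structure_config=name)
    model.save(out)
    lo, hi = model.age_range
    click.echo(f"bias model fitted over ages [{lo:.1f}, {hi:.1f}], saved to {out}")


@cli.command()
@click.option("--experiment", required=True, type=click.Path(exists=True),
              help="output directory of a completed run")
def report(experiment):
    """Print the summary tables of a completed experiment run."""
    exp = Path(experiment)
    for table in ("cross_sectional", "longitudinal"):
        path = exp / "stats" / f"{table}.csv"
        if path.exists():
            click.echo(f"== {table} ==")
            click.echo(pd.read_csv(path).to_string(index=False))
        else:
            click.echo(f"== {table}: not computed ==")


if __name__ == "__main__":
    cli()
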
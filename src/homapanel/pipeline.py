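"""End-to-end orchestration: simulate/load -> preprocess -> select -> score
-> validate -> longitudinal -> report.

The pipeline mirrors the design/validation split of a two-cohort biomarker
study: the panel is selected on the training cohort only; the validation
cohort is preprocessed with its own centers and SDs and dichotomized at its
own median; external validation both transfers the training weights and
refits them on the validation data.  Every stage seeds its randomness from
``master_seed`` and every output artifact embeds the config hash, seed and
software version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clinical import cohort_table
from .enet import EnetConfig
from .errors import ConfigurationError, SchemaError
from .longitudinal import compute_changes, longitudinal_auc
from .preprocess import dichotomize_by_median, preprocess_cohort
from .scoring import (
    ScoreModel,
    ValidationReport,
    auc_with_ci,
    compute_score,
    continuous_validation,
    external_validate,
    loo_cv_scores,
)
from .stability import StabilitySummary, stability_select
from .synthetic import (
    CohortDataset,
    CohortSpec,
    FollowupParams,
    PhenotypeParams,
    read_cohort,
    simulate_cohort,
    simulate_followup,
    write_cohort,
)

logger = logging.getLogger(__name__)

_PRESETS = {
    "satin_like": PhenotypeParams.satin_like,
    "glyndiet_like": PhenotypeParams.glyndiet_like,
}


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (see the demo config)."""

    master_seed: int = 0
    output_dir: str = "runs/out"
    cohorts: dict = field(default_factory=lambda: {
        "train": {"simulate": {"preset": "satin_like", "n_subjects": 236}},
        "validation": {"simulate": {"preset": "glyndiet_like", "n_subjects": 102}},
    })
    followup: dict | None = field(default_factory=lambda: {
        "coef_weight": 0.05, "coef_baseline": -0.4, "coef_latent": 0.3,
        "noise_sd": 0.5,
    })
    preprocess: dict = field(default_factory=lambda: {
        "threshold": 0.20, "rf_trees": 100, "max_iter": 10,
    })
    enet: dict = field(default_factory=lambda: {
        "alpha": 0.5, "n_folds": 10, "n_lambda": 50,
        "lambda_min_ratio": 1e-3, "cv_criterion": "mse",
    })
    stability: dict = field(default_factory=lambda: {"n_runs": 100})
    validation: dict = field(default_factory=lambda: {"mode": "refit"})
    sensitivity: dict | None = field(default_factory=lambda: {"exclude": ["met_glucose"]})
    loo: dict = field(default_factory=lambda: {"enabled": True})
    longitudinal: dict = field(default_factory=lambda: {"enabled": True})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _derived_seed(master_seed: int, *keys: str) -> int:
    h = hashlib.sha256(("/".join(keys) + f"#{master_seed}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _load_cohort(entry: dict, master_seed: int, role: str) -> CohortDataset:
    if "path" in entry:
        return read_cohort(entry["path"])
    if "simulate" not in entry:
        raise ConfigurationError(f"cohort {role!r} needs 'path' or 'simulate'")
    sim = dict(entry["simulate"])
    preset = sim.pop("preset", "satin_like")
    if preset not in _PRESETS:
        raise ConfigurationError(f"unknown phenotype preset {preset!r}")
    sim.setdefault("seed", _derived_seed(master_seed, "cohort", role))
    spec = CohortSpec(phenotype_params=_PRESETS[preset](), **sim)
    return simulate_cohort(spec)


def _prepare(cohort: CohortDataset, cfg: RunConfig, seed: int):
    """Preprocess one cohort: scaled metabolite matrix, binary labels from
    the cohort's own median, and the autoscaled continuous outcome."""
    pp = cfg.preprocess
    X, report = preprocess_cohort(
        cohort.metabolites,
        threshold=pp.get("threshold", 0.20),
        seed=seed,
        max_iter=pp.get("max_iter", 10),
        n_estimators=pp.get("rf_trees", 100),
    )
    labels, cutoff = dichotomize_by_median(cohort.homa_ir)
    y_center = float(np.mean(cohort.homa_ir))
    y_sd = float(np.std(cohort.homa_ir, ddof=1))
    y_scaled = (cohort.homa_ir - y_center) / y_sd
    return {
        "X": X,
        "report": report,
        "labels": labels,
        "cutoff": cutoff,
        "y_scaled": y_scaled,
        "y_center": y_center,
        "y_sd": y_sd,
    }


def _score_from_stability(summary: StabilitySummary) -> ScoreModel:
    """Training score model: the consistent panel weighted by each feature's
    median coefficient over the runs."""
    panel = summary.consistent_set
    weights = summary.table.loc[panel, "coefficient_median"].to_numpy()
    return ScoreModel(
        feature_names=panel, weights=weights, intercept=0.0,
        provenance="training", family=summary.family,
    )


def _family_analysis(
    family: str,
    train: dict,
    val: dict,
    cfg: RunConfig,
    excluded: list[str],
    seed_tag: str,
) -> dict:
    """Selection, internal LOO and external validation for one family."""
    enet_kwargs = dict(cfg.enet)
    config = EnetConfig(family=family, **enet_kwargs)
    Xtr = train["X"].drop(columns=excluded, errors="ignore")
    Xval = val["X"].drop(columns=[c for c in excluded if c in val["X"].columns])
    ytr = train["labels"] if family == "binomial" else train["y_scaled"]
    yval = val["labels"] if family == "binomial" else val["y_scaled"]

    summary = stability_select(
        Xtr, ytr, config,
        n_runs=cfg.stability.get("n_runs", 100),
        master_seed=_derived_seed(cfg.master_seed, "stability", family, seed_tag),
    )
    panel = summary.consistent_set
    out: dict = {"stability": summary, "panel": panel}

    model = _score_from_stability(summary) if panel else None
    out["score_model"] = model

    if cfg.loo.get("enabled", True):
        loo = loo_cv_scores(
            Xtr, ytr, config,
            master_seed=_derived_seed(cfg.master_seed, "loo", family, seed_tag),
        )
        rep = ValidationReport(mode="internal-loo", family=family, n=len(loo),
                               excluded_features=list(excluded))
        if family == "binomial":
            auc, lo, hi = auc_with_ci(loo, ytr)
            rep.auc, rep.auc_ci = auc, (lo, hi)
        else:
            r, r_ci, r2, adj = continuous_validation(
                loo, ytr, n_model_features=max(len(panel), 1)
            )
            rep.pearson_r, rep.r_ci, rep.r2, rep.adjusted_r2 = r, r_ci, r2, adj
        out["internal"] = rep

    if panel:
        missing = [f for f in panel if f not in Xval.columns]
        if missing:
            raise SchemaError(f"validation cohort lacks panel features: {missing}")
        for mode in ("refit", "transfer"):
            rep = external_validate(
                panel, model, Xval, yval, mode=mode, family=family,
                n_model_features=len(panel),
            )
            rep.excluded_features = list(excluded)
            out[f"external_{mode}"] = rep
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; writes artifacts to ``cfg.output_dir`` and
    returns the in-memory results dictionary."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("homapanel")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    provenance = {
        "config_hash": cfg.hash(),
        "version": __version__,
        "master_seed": cfg.master_seed,
    }
    try:
        logger.info("stage: cohorts")
        train_cohort = _load_cohort(cfg.cohorts["train"], cfg.master_seed, "train")
        val_cohort = _load_cohort(cfg.cohorts["validation"], cfg.master_seed, "validation")
        if cfg.followup is not None:
            fu = FollowupParams(**cfg.followup)
            if train_cohort.followup is None:
                train_cohort = simulate_followup(
                    train_cohort, fu, _derived_seed(cfg.master_seed, "followup", "train")
                )
            if val_cohort.followup is None:
                val_cohort = simulate_followup(
                    val_cohort, fu, _derived_seed(cfg.master_seed, "followup", "validation")
                )
        for role, cohort in (("train", train_cohort), ("validation", val_cohort)):
            write_cohort(cohort, outdir / f"cohort_{role}.csv")

        logger.info("stage: table1")
        table1 = cohort_table(train_cohort, val_cohort)
        table1.to_csv(outdir / "table1.csv")

        logger.info("stage: preprocess")
        train = _prepare(train_cohort, cfg, _derived_seed(cfg.master_seed, "impute", "train"))
        val = _prepare(val_cohort, cfg, _derived_seed(cfg.master_seed, "impute", "validation"))

        results: dict = {"table1": table1, "provenance": provenance}
        for family in ("binomial", "gaussian"):
            logger.info("stage: analysis (%s)", family)
            results[family] = _family_analysis(family, train, val, cfg, [], "main")

        if cfg.sensitivity is not None and cfg.sensitivity.get("exclude"):
            drop = list(cfg.sensitivity["exclude"])
            logger.info("stage: sensitivity excluding %s", drop)
            missing = [f for f in drop if f not in train["X"].columns]
            if missing:
                raise SchemaError(f"sensitivity exclusions not in panel: {missing}")
            results["sensitivity"] = {
                family: _family_analysis(family, train, val, cfg, drop, "sens")
                for family in ("binomial", "gaussian")
            }

        if cfg.longitudinal.get("enabled", True):
            logger.info("stage: longitudinal")
            model = results["binomial"]["score_model"]
            longi = {}
            if model is not None:
                for role, cohort, prep in (
                    ("train", train_cohort, train),
                    ("validation", val_cohort, val),
                ):
                    if cohort.followup is None:
                        continue
                    changes = compute_changes(cohort)
                    scores = compute_score(prep["X"], model).loc[changes.index]
                    longi[role] = longitudinal_auc(scores.to_numpy(), changes)
            results["longitudinal"] = longi

        _write_reports(results, outdir, provenance)
        logger.info("pipeline complete")
        return results
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_reports(results: dict, outdir: Path, provenance: dict) -> None:
    def dump(name, payload):
        payload = {"provenance": provenance, **payload}
        (outdir / name).write_text(json.dumps(payload, indent=2, default=str))

    stability_payload = {}
    score_payload = {}
    report_payload = {}
    for family in ("binomial", "gaussian"):
        fam = results[family]
        stability_payload[family] = fam["stability"].to_dict()
        if fam["score_model"] is not None:
            score_payload[family] = fam["score_model"].to_dict()
        report_payload[family] = {
            key: fam[key].to_dict()
            for key in ("internal", "external_refit", "external_transfer")
            if key in fam
        }
    if "sensitivity" in results:
        report_payload["sensitivity"] = {
            family: {
                key: fam[key].to_dict()
                for key in ("internal", "external_refit", "external_transfer")
                if key in fam
            }
            for family, fam in results["sensitivity"].items()
        }
    dump("stability.json", stability_payload)
    dump("score.json", score_payload)
    dump("report.json", report_payload)
    if "longitudinal" in results:
        dump(
            "longitudinal.json",
            {role: res.to_dict() for role, res in results["longitudinal"].items()},
        )


# --------------------------------------------------------------------------
# test fixtures
# --------------------------------------------------------------------------


def make_fixtures(seed: int = 0, outdir=None):
    """Deterministic tiny cohorts (n = 60/30, p = 25) with three planted
    signal features, for fast tests and demos.

    Returns ``(train, validation)``; when ``outdir`` is given the cohorts are
    also written as CSV.
    """
    train_spec = CohortSpec(
        n_subjects=60,
        n_metabolites=25,
        n_high_missing=3,
        n_signal=3,
        effect_sizes=(1.2, -1.0, 0.9),
        block_structure=((6, 0.6), (5, 0.4)),
        missing_rate=0.05,
        high_missing_rate=0.34,
        phenotype_params=PhenotypeParams.satin_like(),
        seed=_derived_seed(seed, "fixture", "train"),
    )
    val_spec = CohortSpec(
        n_subjects=30,
        n_metabolites=25,
        n_high_missing=3,
        n_signal=3,
        effect_sizes=(1.2, -1.0, 0.9),
        block_structure=((6, 0.6), (5, 0.4)),
        missing_rate=0.05,
        high_missing_rate=0.34,
        phenotype_params=PhenotypeParams.glyndiet_like(),
        seed=_derived_seed(seed, "fixture", "validation"),
    )
    train = simulate_cohort(train_spec)
    val = simulate_cohort(val_spec)
    fu = FollowupParams(coef_latent=0.3)
    train = simulate_followup(train, fu, _derived_seed(seed, "fixture-fu", "train"))
    val = simulate_followup(val, fu, _derived_seed(seed, "fixture-fu", "validation"))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(train, outdir / "fixture_train.csv")
        write_cohort(val, outdir / "fixture_validation.csv")
    return train, val
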
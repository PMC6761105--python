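"""Synthetic cohort generation for metabolomics studies of insulin resistance.

The generator emulates two overweight/obese weight-loss cohorts of the kind
used to train and externally validate multi-metabolite HOMA-IR models: a
subjects x metabolites concentration matrix with lipid-family block
correlation, clinical phenotypes (fasting glucose, insulin, HOMA-IR, body
weight, age, sex, lipid panel), missing values (including features missing
badly enough to be excluded), and a sparse planted association between the
metabolite panel and a latent insulin-resistance factor.

The planted structure is a single latent factor ``u`` per subject: fasting
insulin is log-normal with log-mean increasing in ``u``, glucose is normal
(truncated at 40 mg/dL) with mean increasing in ``u``, and each designated
signal metabolite receives an additive standardized loading times ``u``.
Routing all signal through one shared factor induces the collinearity between
metabolites and phenotype that penalized selection methods are designed for.

HOMA-IR is always computed from its defining identity
``glucose [mg/dL] x insulin [mIU/L] / 405``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InvalidInputError

HOMA_DENOMINATOR = 405.0

#: Reserved phenotype column names in cohort CSV files; every other column is
#: treated as a metabolite.
RESERVED_COLUMNS = (
    "subject_id",
    "glucose",
    "insulin",
    "homa_ir",
    "body_weight",
    "age",
    "sex",
    "tc",
    "hdl",
    "ldl",
    "tg",
    "followup_homa_ir",
    "followup_body_weight",
)

_UNITS = {
    "glucose": "mg/dL",
    "insulin": "mIU/L",
    "homa_ir": "unitless",
    "body_weight": "kg",
    "age": "years",
    "sex": "1=female",
    "tc": "mg/dL",
    "hdl": "mg/dL",
    "ldl": "mg/dL",
    "tg": "mg/dL",
}


def compute_homa_ir(glucose, insulin):
    """HOMA-IR from fasting glucose (mg/dL) and fasting insulin (mIU/L).

    Vectorized; returns ``glucose * insulin / 405``.

    Raises
    ------
    InvalidInputError
        If any glucose value is non-positive or any insulin value negative.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(~np.isfinite(glucose)) or np.any(glucose <= 0):
        raise InvalidInputError("glucose must be positive and finite (mg/dL)")
    if np.any(~np.isfinite(insulin)) or np.any(insulin < 0):
        raise InvalidInputError("insulin must be non-negative and finite (mIU/L)")
    return glucose * insulin / HOMA_DENOMINATOR


def _lognormal_params(mean, sd):
    """Log-scale (mu, sigma) of a log-normal with the given mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


@dataclass
class PhenotypeParams:
    """Clinical phenotype distribution parameters for one cohort.

    Defaults for the two bundled presets are calibrated to the published
    baseline characteristics of the SATIN (training) and GLYNDIET
    (validation) weight-loss studies.  ``latent_insulin_loading`` and
    ``latent_glucose_loading`` are the fractions of the log-insulin and
    glucose SD carried by the latent insulin-resistance factor; they set how
    predictable HOMA-IR is from the metabolite panel.
    """

    glucose_mean: float = 93.25
    glucose_sd: float = 11.03
    insulin_mean: float = 10.25
    insulin_sd: float = 8.88
    weight_mean: float = 87.48
    weight_sd: float = 11.16
    age_mean: float = 46.37
    age_sd: float = 10.65
    female_prop: float = 0.7881
    tc_mean: float = 196.01
    tc_sd: float = 34.88
    hdl_mean: float = 55.65
    hdl_sd: float = 15.27
    tg_mean: float = 102.34
    tg_sd: float = 48.90
    latent_insulin_loading: float = 0.75
    latent_glucose_loading: float = 0.40

    @classmethod
    def satin_like(cls) -> "PhenotypeParams":
        """Training-cohort preset (SATIN-like, n = 236 in the source study)."""
        return cls()

    @classmethod
    def glyndiet_like(cls) -> "PhenotypeParams":
        """Validation-cohort preset (GLYNDIET-like, n = 102)."""
        return cls(
            glucose_mean=101.57,
            glucose_sd=14.67,
            insulin_mean=5.08,
            insulin_sd=3.04,
            weight_mean=83.06,
            weight_sd=10.05,
            age_mean=44.01,
            age_sd=7.75,
            female_prop=0.8039,
            tc_mean=193.05,
            tc_sd=30.97,
            hdl_mean=54.89,
            hdl_sd=11.13,
            tg_mean=100.83,
            tg_sd=59.75,
        )


def _default_effect_sizes(n_signal: int) -> tuple[float, ...]:
    """Alternating-sign standardized loadings from 1.0 down to 0.5."""
    if n_signal == 0:
        return ()
    if n_signal == 1:
        mags = [1.0]
    else:
        mags = list(np.linspace(1.0, 0.5, n_signal))
    return tuple(m if k % 2 == 0 else -m for k, m in enumerate(mags))


#: Default lipid-family block structure: (block size, within-block correlation)
DEFAULT_BLOCKS = ((14, 0.7), (12, 0.6), (12, 0.5), (10, 0.5), (8, 0.4), (8, 0.3))

_BLOCK_FAMILIES = ("PC", "SM", "LPC", "TG", "PE", "CER")


@dataclass
class CohortSpec:
    """Specification for one simulated cohort.

    ``n_metabolites`` counts measured features; ``n_high_missing`` of them get
    a missingness fraction above the 20% exclusion threshold so that the
    default 133 measured features yield 123 analyzable ones.  One feature
    (``met_glucose``) duplicates the clinical glucose assay on the metabolite
    panel, supporting the glucose-exclusion sensitivity analysis.
    """

    n_subjects: int
    n_metabolites: int = 133
    n_high_missing: int = 10
    n_signal: int = 10
    effect_sizes: tuple[float, ...] | None = None
    block_structure: tuple[tuple[int, float], ...] = DEFAULT_BLOCKS
    missing_rate: float = 0.05
    high_missing_rate: float = 0.30
    phenotype_params: PhenotypeParams = field(default_factory=PhenotypeParams)
    seed: int = 0

    def __post_init__(self):
        if self.effect_sizes is None:
            self.effect_sizes = _default_effect_sizes(self.n_signal)
        self.effect_sizes = tuple(float(e) for e in self.effect_sizes)
        if self.n_subjects <= 0 or self.n_metabolites <= 0:
            raise ConfigurationError("n_subjects and n_metabolites must be positive")
        if self.n_high_missing < 0 or self.n_signal < 0:
            raise ConfigurationError("feature counts must be non-negative")
        if self.n_signal > self.n_metabolites:
            raise ConfigurationError("n_signal exceeds n_metabolites")
        if len(self.effect_sizes) != self.n_signal:
            raise ConfigurationError(
                f"effect_sizes has length {len(self.effect_sizes)}, expected {self.n_signal}"
            )
        for size, rho in self.block_structure:
            if size <= 0:
                raise ConfigurationError("block sizes must be positive")
            if not -1.0 < rho < 1.0:
                raise ConfigurationError(f"block correlation {rho} outside (-1, 1)")
        n_block = sum(size for size, _ in self.block_structure)
        if n_block > self.n_metabolites - 1:
            raise ConfigurationError(
                f"block sizes sum to {n_block}, exceeding the {self.n_metabolites - 1} "
                "non-glucose metabolite slots"
            )
        if not 0.0 <= self.missing_rate < 0.20:
            raise ConfigurationError("missing_rate must lie in [0, 0.20)")
        if not 0.20 < self.high_missing_rate <= 1.0:
            raise ConfigurationError("high_missing_rate must exceed 0.20")
        if self.n_signal + self.n_high_missing + 1 > self.n_metabolites:
            raise ConfigurationError(
                "signal, high-missing and glucose features exceed n_metabolites"
            )


@dataclass
class CohortDataset:
    """One cohort: metabolite concentrations plus clinical phenotypes.

    ``metabolites`` is an n x p DataFrame (NaN marks missing entries).
    Phenotype vectors are parallel arrays of length n; ``insulin`` may be
    absent (None) when loading partial data.  ``followup`` optionally holds
    end-of-intervention ``homa_ir`` and ``body_weight`` arrays (NaN where a
    subject missed follow-up).  ``truth`` records the planted-signal ground
    truth for simulated cohorts.
    """

    subject_ids: list[str]
    metabolites: pd.DataFrame
    glucose: np.ndarray | None
    insulin: np.ndarray | None
    homa_ir: np.ndarray | None
    body_weight: np.ndarray | None = None
    age: np.ndarray | None = None
    sex: np.ndarray | None = None
    tc: np.ndarray | None = None
    hdl: np.ndarray | None = None
    ldl: np.ndarray | None = None
    tg: np.ndarray | None = None
    followup: dict | None = None
    truth: dict | None = None

    def __post_init__(self):
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise FormatError("duplicate subject_ids")
        names = list(self.metabolites.columns)
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise FormatError(f"duplicate metabolite names: {dupes}")
        if len(self.metabolites) != n:
            raise FormatError(
                f"metabolite matrix has {len(self.metabolites)} rows, expected {n}"
            )
        for attr in ("glucose", "insulin", "homa_ir", "body_weight", "age",
                     "sex", "tc", "hdl", "ldl", "tg"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, attr, v)
                if len(v) != n:
                    raise FormatError(f"phenotype {attr} has length {len(v)}, expected {n}")
        if self.followup is not None:
            for key, v in self.followup.items():
                self.followup[key] = np.asarray(v, dtype=float)
                if len(self.followup[key]) != n:
                    raise FormatError(f"followup {key} has length {len(v)}, expected {n}")
        if (self.glucose is not None and self.insulin is not None
                and self.homa_ir is not None):
            expected = compute_homa_ir(self.glucose, self.insulin)
            if not np.allclose(self.homa_ir, expected, rtol=1e-9, atol=0.0):
                raise FormatError(
                    "homa_ir inconsistent with glucose * insulin / 405"
                )

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.metabolites.columns)


def _metabolite_names(spec: CohortSpec) -> list[str]:
    names = ["met_glucose"]
    for b, (size, _) in enumerate(spec.block_structure):
        fam = _BLOCK_FAMILIES[b % len(_BLOCK_FAMILIES)]
        suffix = "" if b < len(_BLOCK_FAMILIES) else str(b // len(_BLOCK_FAMILIES) + 1)
        names.extend(f"{fam}{suffix}_{i:02d}" for i in range(size))
    i = 0
    while len(names) < spec.n_metabolites:
        names.append(f"met_{i:03d}")
        i += 1
    return names


def _signal_indices(spec: CohortSpec) -> np.ndarray:
    """Signal feature positions, spread evenly over the non-glucose features."""
    p = spec.n_metabolites
    if spec.n_signal == 0:
        return np.array([], dtype=int)
    idx = np.unique(np.round(np.linspace(1, p - 1, spec.n_signal)).astype(int))
    # fill any collisions from rounding
    extra = 1
    while len(idx) < spec.n_signal:
        if extra not in idx:
            idx = np.sort(np.append(idx, extra))
        extra += 1
    return idx


def simulate_cohort(spec: CohortSpec) -> CohortDataset:
    """Draw one cohort from the generative model described in the module docs.

    Fully deterministic given ``spec.seed``: the same spec yields bit-identical
    datasets.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_metabolites
    ph = spec.phenotype_params

    u = rng.standard_normal(n)  # latent insulin-resistance factor

    li_mu, li_sd = _lognormal_params(ph.insulin_mean, ph.insulin_sd)
    a_ins = ph.latent_insulin_loading
    log_ins = li_mu + li_sd * (a_ins * u + math.sqrt(1 - a_ins**2) * rng.standard_normal(n))
    insulin = np.exp(log_ins)

    a_glu = ph.latent_glucose_loading
    glucose = ph.glucose_mean + ph.glucose_sd * (
        a_glu * u + math.sqrt(1 - a_glu**2) * rng.standard_normal(n)
    )
    glucose = np.maximum(glucose, 40.0)  # physiological floor, mg/dL
    homa_ir = compute_homa_ir(glucose, insulin)

    body_weight = ph.weight_mean + ph.weight_sd * rng.standard_normal(n)
    age = ph.age_mean + ph.age_sd * rng.standard_normal(n)
    sex = (rng.random(n) < ph.female_prop).astype(float)
    tc = ph.tc_mean + ph.tc_sd * rng.standard_normal(n)
    hdl = np.maximum(ph.hdl_mean + ph.hdl_sd * rng.standard_normal(n), 15.0)
    tg_mu, tg_sd = _lognormal_params(ph.tg_mean, ph.tg_sd)
    tg = np.minimum(np.exp(tg_mu + tg_sd * rng.standard_normal(n)), 399.0)
    ldl = tc - hdl - tg / 5.0  # Friedewald; TG kept below 400 by construction

    names = _metabolite_names(spec)
    sig_idx = _signal_indices(spec)
    loadings = np.zeros(p)
    loadings[sig_idx] = spec.effect_sizes

    # Standardized noise: block-correlated for block features, iid elsewhere.
    Z = rng.standard_normal((n, p))
    pos = 1  # feature 0 is met_glucose
    for size, rho in spec.block_structure:
        f = rng.standard_normal(n)
        Z[:, pos:pos + size] = (
            math.sqrt(rho) * f[:, None]
            + math.sqrt(1 - rho) * Z[:, pos:pos + size]
        )
        pos += size

    mu_j = rng.uniform(20.0, 200.0, size=p)
    sigma_j = 0.15 * mu_j
    M = mu_j + sigma_j * (Z + loadings * u[:, None])
    # met_glucose duplicates the clinical assay up to small measurement noise
    M[:, 0] = glucose + 0.05 * ph.glucose_sd * rng.standard_normal(n)

    # High-missing features: picked from the back, skipping signal features.
    high_idx = []
    j = p - 1
    sig_set = set(sig_idx.tolist())
    while len(high_idx) < spec.n_high_missing and j > 0:
        if j not in sig_set:
            high_idx.append(j)
        j -= 1
    if len(high_idx) < spec.n_high_missing:
        raise ConfigurationError("not enough non-signal features for high-missing set")
    high_set = set(high_idx)

    n_miss_low = int(round(spec.missing_rate * n))
    if n_miss_low / n >= 0.20:
        raise ConfigurationError("missing_rate rounds to >= 20% of subjects")
    n_miss_high = max(int(round(spec.high_missing_rate * n)), int(math.floor(0.20 * n)) + 1)
    n_miss_high = min(n_miss_high, n)
    for jcol in range(p):
        k = n_miss_high if jcol in high_set else n_miss_low
        if k > 0:
            rows = rng.choice(n, size=k, replace=False)
            M[rows, jcol] = np.nan

    subject_ids = [f"S{i:04d}" for i in range(n)]
    metabolites = pd.DataFrame(M, columns=names, index=subject_ids)

    truth = {
        "seed": spec.seed,
        "latent": u,
        "signal_indices": sig_idx.tolist(),
        "signal_names": [names[j] for j in sig_idx],
        "effect_sizes": list(spec.effect_sizes),
        "high_missing_names": [names[j] for j in sorted(high_idx)],
    }
    return CohortDataset(
        subject_ids=subject_ids,
        metabolites=metabolites,
        glucose=glucose,
        insulin=insulin,
        homa_ir=homa_ir,
        body_weight=body_weight,
        age=age,
        sex=sex,
        tc=tc,
        hdl=hdl,
        ldl=ldl,
        tg=tg,
        truth=truth,
    )


@dataclass
class FollowupParams:
    """Generative parameters for end-of-intervention changes.

    ``delta_homa = coef_weight * delta_bw + coef_baseline * (homa - mean(homa))
    + coef_latent * u + noise``.  A negative ``coef_baseline`` produces the
    regression-to-the-mean seen in weight-loss trials; ``coef_latent`` couples
    the change to the same latent factor that drives the metabolite panel.
    """

    weight_change_mean: float = -4.0
    weight_change_sd: float = 3.0
    coef_weight: float = 0.05
    coef_baseline: float = -0.4
    coef_latent: float = 0.0
    noise_sd: float = 0.5
    missing_rate: float = 0.0


def simulate_followup(cohort: CohortDataset, params: FollowupParams, seed: int) -> CohortDataset:
    """Attach a simulated follow-up block (HOMA-IR and body weight) to a cohort.

    Returns a new :class:`CohortDataset`; the input is not modified.
    Reproducible from ``seed``.
    """
    if cohort.homa_ir is None or cohort.body_weight is None:
        raise InvalidInputError("cohort lacks baseline homa_ir or body_weight")
    if params.coef_latent != 0.0 and (cohort.truth is None or "latent" not in cohort.truth):
        raise InvalidInputError("coef_latent requires a synthetic cohort with truth block")
    rng = np.random.default_rng(seed)
    n = cohort.n
    delta_bw = params.weight_change_mean + params.weight_change_sd * rng.standard_normal(n)
    delta = (
        params.coef_weight * delta_bw
        + params.coef_baseline * (cohort.homa_ir - cohort.homa_ir.mean())
        + params.noise_sd * rng.standard_normal(n)
    )
    if params.coef_latent != 0.0:
        delta = delta + params.coef_latent * np.asarray(cohort.truth["latent"])
    followup = {
        "homa_ir": cohort.homa_ir + delta,
        "body_weight": cohort.body_weight + delta_bw,
    }
    if params.missing_rate > 0.0:
        k = int(round(params.missing_rate * n))
        if k > 0:
            rows = rng.choice(n, size=k, replace=False)
            for key in followup:
                followup[key][rows] = np.nan
    return CohortDataset(
        subject_ids=list(cohort.subject_ids),
        metabolites=cohort.metabolites.copy(),
        glucose=cohort.glucose,
        insulin=cohort.insulin,
        homa_ir=cohort.homa_ir,
        body_weight=cohort.body_weight,
        age=cohort.age,
        sex=cohort.sex,
        tc=cohort.tc,
        hdl=cohort.hdl,
        ldl=cohort.ldl,
        tg=cohort.tg,
        followup=followup,
        truth=cohort.truth,
    )


def write_cohort(cohort: CohortDataset, path) -> None:
    """Write a cohort to CSV (missing entries as empty cells) plus a sidecar
    JSON (``<stem>.meta.json``) holding units and, for synthetic cohorts, the
    planted-signal truth block."""
    path = Path(path)
    data = {"subject_id": cohort.subject_ids}
    for attr in ("glucose", "insulin", "homa_ir", "body_weight", "age",
                 "sex", "tc", "hdl", "ldl", "tg"):
        v = getattr(cohort, attr)
        if v is not None:
            data[attr] = v
    if cohort.followup is not None:
        for key, v in cohort.followup.items():
            data[f"followup_{key}"] = v
    frame = pd.DataFrame(data)
    frame = pd.concat([frame, cohort.metabolites.reset_index(drop=True)], axis=1)
    frame.to_csv(path, index=False)  # default float repr round-trips exactly

    meta: dict = {"units": _UNITS}
    if cohort.truth is not None:
        truth = dict(cohort.truth)
        if "latent" in truth:
            truth["latent"] = np.asarray(truth["latent"]).tolist()
        meta["truth"] = truth
        meta["seed"] = truth.get("seed")
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(path) -> CohortDataset:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-prepared in
    the same layout).

    Raises :class:`FormatError` naming the offending cell for non-numeric
    metabolite values, and for duplicate column names.  Phenotype columns are
    optional: a file with ``homa_ir`` but no ``insulin`` loads with insulin
    absent.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"duplicate column names in {path.name}: {dupes}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed CSV {path.name}: {exc}") from exc
    if "subject_id" in raw.columns:
        subject_ids = raw["subject_id"].tolist()
    else:
        subject_ids = [f"S{i:04d}" for i in range(len(raw))]

    def numeric(col: str) -> np.ndarray:
        # element-wise float() parsing: correctly rounded (exact round-trip),
        # unlike pandas' fast string-to-double path
        vals = raw[col]
        out = np.empty(len(vals))
        for i, v in enumerate(vals):
            if v == "":
                out[i] = np.nan
                continue
            try:
                out[i] = float(v)
            except ValueError:
                raise FormatError(
                    f"non-numeric value {v!r} in column {col!r}, "
                    f"row {subject_ids[i]!r}"
                ) from None
        return out

    pheno = {}
    for attr in ("glucose", "insulin", "homa_ir", "body_weight", "age",
                 "sex", "tc", "hdl", "ldl", "tg"):
        pheno[attr] = numeric(attr) if attr in raw.columns else None
    followup = None
    fu_cols = [c for c in raw.columns if c.startswith("followup_")]
    if fu_cols:
        followup = {c[len("followup_"):]: numeric(c) for c in fu_cols}
    met_cols = [c for c in raw.columns if c not in RESERVED_COLUMNS]
    metabolites = pd.DataFrame(
        {c: numeric(c) for c in met_cols}, index=subject_ids
    )

    truth = None
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        truth = meta.get("truth")
        if truth is not None and "latent" in truth:
            truth["latent"] = np.asarray(truth["latent"], dtype=float)
    return CohortDataset(
        subject_ids=subject_ids,
        metabolites=metabolites,
        followup=followup,
        truth=truth,
        **pheno,
    )
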
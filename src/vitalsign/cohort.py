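"""Synthetic survey-cohort generator with planted, known risk structure.

Emulates the shape of a national health-survey cohort (one row per adult
subject; demographic, examination, laboratory and questionnaire features;
binary all-cause mortality labels at several follow-up horizons; an
enrollment-cycle column) while planting structure that every downstream
stage can be tested against:

* nonlinear risk effects — monotone, U-shaped (risk minimal at an optimum
  value), and saturating-threshold (risk flat above a knot) on the
  log-odds scale;
* effect-modifying interactions (e.g. an exposure whose risk contribution
  depends on age or on sex);
* a group of mutually redundant anthropometric features driven by one
  latent body-size variable;
* pure-noise features;
* per-feature reference-interval metadata: one interval covering the
  low-risk region of the true risk curve and one deliberately mis-set to
  cover the highest-risk region.

Mortality is a logistic mechanism: ``logit p = beta0(h) + sum_e w_e g_e(x)``
with a per-horizon baseline shift ``log(h / 5)`` so longer follow-up means
more events.  Labels across horizons are nested (one latent uniform per
subject), so each horizon's label is marginally Bernoulli(p_h) and a
1-year death is also a 5-year death.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ROLES, FeatureTable

DEFAULT_HORIZONS = (1, 3, 5, 10)


# ---------------------------------------------------------------------------
# spec types


@dataclass(frozen=True)
class FeatureDef:
    """Marginal sampling law for one independent feature.

    ``dist`` is one of ``("uniform", lo, hi)``, ``("normal", mu, sd)``,
    ``("lognormal", mu_log, sd_log)`` or ``("bernoulli", p)``.
    """

    name: str
    role: str
    dist: tuple

    def moments(self) -> tuple[float, float]:
        """Analytic (mean, sd) of the marginal — used to standardize effects."""
        kind = self.dist[0]
        if kind == "uniform":
            lo, hi = self.dist[1:]
            return (lo + hi) / 2.0, (hi - lo) / math.sqrt(12.0)
        if kind == "normal":
            return float(self.dist[1]), float(self.dist[2])
        if kind == "lognormal":
            mu, sd = self.dist[1:]
            mean = math.exp(mu + sd**2 / 2)
            var = (math.exp(sd**2) - 1) * math.exp(2 * mu + sd**2)
            return mean, math.sqrt(var)
        if kind == "bernoulli":
            p = float(self.dist[1])
            return p, math.sqrt(p * (1 - p))
        raise ValueError(f"unknown distribution {kind!r}")

    def sampling_range(self) -> tuple[float, float]:
        kind = self.dist[0]
        if kind == "uniform":
            return self.dist[1], self.dist[2]
        if kind == "normal":
            mu, sd = self.dist[1:]
            return mu - 4 * sd, mu + 4 * sd
        if kind == "lognormal":
            mu, sd = self.dist[1:]
            return math.exp(mu - 3 * sd), math.exp(mu + 3 * sd)
        if kind == "bernoulli":
            return 0.0, 1.0
        raise ValueError(f"unknown distribution {kind!r}")


@dataclass(frozen=True)
class Monotone:
    """Linear effect on the standardized feature value."""


@dataclass(frozen=True)
class UShape:
    """Quadratic effect, zero (hence risk-minimal) at ``optimum``."""

    optimum: float
    curvature: float = 0.3


@dataclass(frozen=True)
class Threshold:
    """Saturating ramp: increases with the value up to ``knot``, flat above."""

    knot: float
    plateau: float = 1.0


@dataclass(frozen=True)
class Interaction:
    """Multiplicative log-odds modifier: z(feature) * z(partner)."""

    partner: str
    form: str = "product"


EffectShape = Monotone | UShape | Threshold | Interaction


@dataclass(frozen=True)
class PlantedEffect:
    feature: str
    shape: EffectShape
    weight: float


@dataclass(frozen=True)
class RedundancyMember:
    """One observed proxy of a latent variable: loc + scale * L + noise."""

    name: str
    role: str
    loc: float
    scale: float
    noise_sd: float = 0.05  # in units of |scale| * latent sd


@dataclass(frozen=True)
class RedundancyGroup:
    latent: str
    members: tuple[RedundancyMember, ...]


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort; identical spec + seed gives
    byte-identical output."""

    n_subjects: int
    features: tuple[FeatureDef, ...]
    effects: tuple[PlantedEffect, ...]
    redundancy_groups: tuple[RedundancyGroup, ...] = ()
    n_noise_features: int = 8
    missing_rate: float = 0.05
    beta0: float = math.log(0.08 / 0.92)
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    n_cycles: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not math.isfinite(self.beta0):
            raise ValueError("beta0 must be finite")
        names = [f.name for f in self.features]
        member_of: dict[str, str] = {}
        for g in self.redundancy_groups:
            for m in g.members:
                if m.name in member_of:
                    raise ValueError(
                        f"feature {m.name!r} in more than one redundancy group"
                    )
                member_of[m.name] = g.latent
                names.append(m.name)
        names += [self._noise_name(i) for i in range(self.n_noise_features)]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        all_names = set(names)
        for e in self.effects:
            if not math.isfinite(e.weight):
                raise ValueError(f"non-finite weight for effect on {e.feature!r}")
            if e.feature not in all_names:
                raise ValueError(f"effect on unknown feature {e.feature!r}")
            if isinstance(e.shape, Interaction) and e.shape.partner not in all_names:
                raise ValueError(f"interaction partner {e.shape.partner!r} unknown")
            lo, hi = self._range(e.feature)
            if isinstance(e.shape, UShape) and not lo <= e.shape.optimum <= hi:
                raise ValueError(f"U-shape optimum outside range of {e.feature!r}")
            if isinstance(e.shape, Threshold) and not lo <= e.shape.knot <= hi:
                raise ValueError(f"threshold knot outside range of {e.feature!r}")
        for f in self.features:
            if f.role not in ROLES:
                raise ValueError(f"unknown role {f.role!r} for {f.name!r}")

    @staticmethod
    def _noise_name(i: int) -> str:
        return f"noise_lab_{i + 1:02d}"

    # -- lookup helpers -----------------------------------------------------

    def feature_names(self) -> list[str]:
        names = [f.name for f in self.features]
        for g in self.redundancy_groups:
            names += [m.name for m in g.members]
        names += [self._noise_name(i) for i in range(self.n_noise_features)]
        return names

    def role_of(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return f.role
        for g in self.redundancy_groups:
            for m in g.members:
                if m.name == name:
                    return m.role
        if name.startswith("noise_lab_"):
            return "laboratory"
        raise KeyError(name)

    def group_of(self, name: str) -> str | None:
        for g in self.redundancy_groups:
            if any(m.name == name for m in g.members):
                return g.latent
        return None

    def _moments(self, name: str) -> tuple[float, float]:
        for f in self.features:
            if f.name == name:
                return f.moments()
        for g in self.redundancy_groups:
            for m in g.members:
                if m.name == name:
                    sd = abs(m.scale) * math.sqrt(1.0 + m.noise_sd**2)
                    return m.loc, sd
        if name.startswith("noise_lab_"):
            return 0.0, 1.0
        raise KeyError(name)

    def _range(self, name: str) -> tuple[float, float]:
        for f in self.features:
            if f.name == name:
                return f.sampling_range()
        mu, sd = self._moments(name)
        return mu - 4 * sd, mu + 4 * sd


@dataclass
class GroundTruth:
    """Planted structure emitted alongside a generated cohort."""

    probabilities: pd.DataFrame  # subjects x horizons, true event probability
    effect_shapes: dict[str, str]  # feature -> shape tag
    redundancy_assignment: dict[str, str]  # member feature -> latent name
    reference_intervals: dict[str, dict[str, tuple[float, float]]]
    # feature -> {"optimal": (lo, hi), "mis_set": (lo, hi)}


# ---------------------------------------------------------------------------
# risk mechanism


def _effect_contribution(
    spec: CohortSpec, effect: PlantedEffect, values: Mapping[str, np.ndarray]
) -> np.ndarray:
    x = np.asarray(values[effect.feature], dtype=float)
    mu, sd = spec._moments(effect.feature)
    shape = effect.shape
    if isinstance(shape, Monotone):
        g = (x - mu) / sd
    elif isinstance(shape, UShape):
        g = shape.curvature * ((x - shape.optimum) / sd) ** 2
    elif isinstance(shape, Threshold):
        g = shape.plateau * (np.minimum(x, shape.knot) - shape.knot) / sd
    elif isinstance(shape, Interaction):
        pmu, psd = spec._moments(shape.partner)
        z_partner = (np.asarray(values[shape.partner], dtype=float) - pmu) / psd
        g = (x - mu) / sd * z_partner
    else:  # pragma: no cover - exhaustive by construction
        raise TypeError(f"unknown effect shape {shape!r}")
    return effect.weight * g


def _logit_risk(spec: CohortSpec, values: Mapping[str, np.ndarray]) -> np.ndarray:
    for e in spec.effects:
        if e.feature not in values:
            raise KeyError(f"feature {e.feature!r} required by an effect is missing")
        if isinstance(e.shape, Interaction) and e.shape.partner not in values:
            raise KeyError(f"partner {e.shape.partner!r} required by an effect is missing")
    n = len(next(iter(values.values()))) if values else 1
    logit = np.full(n, spec.beta0, dtype=float)
    for e in spec.effects:
        logit = logit + _effect_contribution(spec, e, values)
    return logit


def true_risk(
    spec: CohortSpec, values: Mapping[str, np.ndarray | float], horizon: int = 5
) -> np.ndarray:
    """Exact planted event probability for given feature values.

    ``values`` maps feature names to scalars or aligned vectors; every
    feature referenced by an effect (including interaction partners) must
    be present.  The per-horizon baseline shift is ``log(horizon / 5)``.
    """
    vec = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in values.items()}
    logit = _logit_risk(spec, vec) + math.log(horizon / 5.0)
    return 1.0 / (1.0 + np.exp(-logit))


# ---------------------------------------------------------------------------
# generation


def _sample_features(spec: CohortSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = spec.n_subjects
    out: dict[str, np.ndarray] = {}
    for f in spec.features:
        kind = f.dist[0]
        if kind == "uniform":
            out[f.name] = rng.uniform(f.dist[1], f.dist[2], size=n)
        elif kind == "normal":
            out[f.name] = rng.normal(f.dist[1], f.dist[2], size=n)
        elif kind == "lognormal":
            out[f.name] = rng.lognormal(f.dist[1], f.dist[2], size=n)
        elif kind == "bernoulli":
            out[f.name] = (rng.random(n) < f.dist[1]).astype(float)
        else:
            raise ValueError(f"unknown distribution {kind!r}")
    for g in spec.redundancy_groups:
        latent = rng.normal(0.0, 1.0, size=n)
        for m in g.members:
            noise = rng.normal(0.0, m.noise_sd * abs(m.scale), size=n)
            out[m.name] = m.loc + m.scale * latent + noise
    for i in range(spec.n_noise_features):
        out[spec._noise_name(i)] = rng.normal(0.0, 1.0, size=n)
    return out


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[FeatureTable, pd.DataFrame, GroundTruth]:
    """Draw one cohort: feature table, per-horizon labels, and ground truth.

    Returns
    -------
    table:
        :class:`FeatureTable` with roles and an enrollment ``cycle`` column.
    labels:
        DataFrame with one binary column ``death_{h}y`` per horizon.
    truth:
        :class:`GroundTruth` with true probabilities, effect shapes,
        redundancy assignments and reference-interval metadata.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    values = _sample_features(spec, rng)
    logit5 = _logit_risk(spec, values)

    probs = {}
    for h in spec.horizons:
        probs[f"death_{h}y"] = 1.0 / (1.0 + np.exp(-(logit5 + math.log(h / 5.0))))
    prob_df = pd.DataFrame(probs)
    # nested labels: one latent uniform per subject
    u = rng.random(spec.n_subjects)
    labels = pd.DataFrame(
        {c: (u < prob_df[c].to_numpy()).astype(int) for c in prob_df.columns}
    )

    cycle = rng.integers(1, spec.n_cycles + 1, size=spec.n_subjects)

    order = spec.feature_names()
    data = pd.DataFrame({k: values[k] for k in order})
    # MCAR missingness on everything except the demographic backbone
    if spec.missing_rate > 0:
        protect = {f.name for f in spec.features if f.role == "demographic"}
        maskable = [c for c in order if c not in protect]
        mask = rng.random((spec.n_subjects, len(maskable))) < spec.missing_rate
        block = data[maskable].to_numpy()
        block[mask] = np.nan
        data[maskable] = block

    roles = {name: spec.role_of(name) for name in order}
    table = FeatureTable(data, roles, cycle=cycle)

    effect_shapes = {e.feature: type(e.shape).__name__.lower() for e in spec.effects}
    assignment = {
        m.name: g.latent for g in spec.redundancy_groups for m in g.members
    }
    ris: dict[str, dict[str, tuple[float, float]]] = {}
    complete = pd.DataFrame(values)
    binary = {
        f.name for f in spec.features if f.dist[0] == "bernoulli"
    }
    for e in spec.effects:
        if isinstance(e.shape, Interaction) or e.weight == 0:
            continue
        if e.feature in ris or e.feature in binary:
            continue  # intervals are meaningless for binary items
        ris[e.feature] = make_reference_intervals(spec, e.feature, complete)

    truth = GroundTruth(prob_df, effect_shapes, assignment, ris)
    return table, labels, truth


# ---------------------------------------------------------------------------
# reference-interval metadata


def true_relative_risk_curve(
    spec: CohortSpec,
    feature: str,
    cohort_values: pd.DataFrame,
    horizon: int = 5,
    n_grid: int = 100,
    max_subjects: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth analogue of the model-based relative-risk curve.

    For each grid value v the feature is substituted into every (sub-sampled)
    subject, the true event probability is averaged, and the mean is divided
    by the unmodified cohort-mean probability.
    """
    sub = cohort_values.iloc[: min(max_subjects, len(cohort_values))]
    obs = cohort_values[feature].to_numpy()
    grid = np.quantile(obs, np.linspace(0.005, 0.995, n_grid))
    base = float(np.mean(true_risk(spec, {c: sub[c].to_numpy() for c in sub.columns}, horizon)))
    r = np.empty(n_grid)
    vals = {c: sub[c].to_numpy() for c in sub.columns}
    for k, v in enumerate(grid):
        mod = dict(vals)
        mod[feature] = np.full(len(sub), v)
        r[k] = float(np.mean(true_risk(spec, mod, horizon))) / base
    return grid, r


def make_reference_intervals(
    spec: CohortSpec,
    feature: str,
    cohort_values: pd.DataFrame,
    horizon: int = 5,
    flat_tol: float = 1e-3,
) -> dict[str, tuple[float, float]]:
    """Build one low-risk ("optimal") and one deliberately high-risk
    ("mis_set") reference interval from the true risk curve.

    The optimal interval is the contiguous run of grid values with relative
    risk <= 1 that contains the risk minimum.  The mis-set interval covers
    the top-risk plateau: the contiguous run around the argmax where the
    excess relative risk r - 1 stays above half its maximum, padded
    slightly, and extended past the sampling range when the plateau touches
    a boundary — so the maximal-risk values always fall inside it.  A
    feature with a flat true risk curve has no meaningful reference
    interval and is rejected.
    """
    if not any(
        e.feature == feature and not isinstance(e.shape, Interaction) and e.weight != 0
        for e in spec.effects
    ):
        raise ValueError(f"feature {feature!r} has no planted main effect")
    grid, r = true_relative_risk_curve(spec, feature, cohort_values, horizon)
    if r.max() - r.min() < flat_tol:
        raise ValueError(f"true risk curve of {feature!r} is flat")

    lo_risk = r <= 1.0
    imin = int(np.argmin(r))
    if not lo_risk[imin]:  # degenerate: everything above average
        lo, hi = grid[imin], grid[min(imin + 1, len(grid) - 1)]
    else:
        a = imin
        while a > 0 and lo_risk[a - 1]:
            a -= 1
        b = imin
        while b < len(grid) - 1 and lo_risk[b + 1]:
            b += 1
        lo, hi = float(grid[a]), float(grid[b])
    if not lo < hi:
        hi = lo + 1e-9

    imax = int(np.argmax(r))
    span = float(grid[-1] - grid[0])
    pad = span / 50.0
    band = (r - 1.0) >= 0.5 * (r[imax] - 1.0)
    a = imax
    while a > 0 and band[a - 1]:
        a -= 1
    b = imax
    while b < len(grid) - 1 and band[b + 1]:
        b += 1
    m_lo = float(grid[a]) - (span / 8.0 if a == 0 else pad)
    m_hi = float(grid[b]) + (span / 8.0 if b == len(grid) - 1 else pad)
    return {"optimal": (lo, hi), "mis_set": (m_lo, m_hi)}


# ---------------------------------------------------------------------------
# the default study cohort


def default_cohort_spec(
    n_subjects: int = 8000,
    n_noise_features: int = 8,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> CohortSpec:
    """The standard test-bench cohort.

    Roughly two dozen features emulating a health-survey table: a dominant
    age effect, a protective body-size signal carried by four redundant
    anthropometric proxies, a U-shaped serum-urate-like lab, a saturating
    urine-albumin-like lab, monotone red-cell-distribution-width-like and
    lead-like labs, an age x lead and a sex x chloride interaction, two
    questionnaire signals and pure-noise labs.
    """
    features = (
        FeatureDef("age", "demographic", ("uniform", 18.0, 85.0)),
        FeatureDef("sex", "demographic", ("bernoulli", 0.5)),
        FeatureDef("uric_acid", "laboratory", ("normal", 5.5, 1.3)),
        FeatureDef("urine_albumin", "laboratory", ("lognormal", 3.4, 1.0)),
        FeatureDef("rdw", "laboratory", ("normal", 13.5, 1.2)),
        FeatureDef("blood_lead", "laboratory", ("lognormal", -2.1, 0.6)),
        FeatureDef("serum_chloride", "laboratory", ("normal", 102.0, 2.5)),
        FeatureDef("smoker", "questionnaire", ("bernoulli", 0.25)),
        FeatureDef("general_health", "questionnaire", ("uniform", 1.0, 5.0)),
    )
    body = RedundancyGroup(
        "body_size",
        (
            RedundancyMember("arm_circumference", "examination", 32.0, 4.0, 0.05),
            RedundancyMember("bmi", "examination", 27.0, 4.5, 0.08),
            RedundancyMember("waist_circumference", "examination", 98.0, 12.0, 0.05),
            RedundancyMember("weight_kg", "examination", 80.0, 14.0, 0.08),
        ),
    )
    effects = (
        PlantedEffect("age", Monotone(), 0.9),
        PlantedEffect("arm_circumference", Monotone(), -0.5),
        PlantedEffect("uric_acid", UShape(optimum=5.0, curvature=0.35), 0.6),
        PlantedEffect("urine_albumin", Threshold(knot=150.0, plateau=1.0), 0.6),
        PlantedEffect("rdw", Monotone(), 0.45),
        PlantedEffect("blood_lead", Monotone(), 0.4),
        PlantedEffect("blood_lead", Interaction(partner="age"), -0.35),
        PlantedEffect("serum_chloride", Monotone(), -0.3),
        PlantedEffect("serum_chloride", Interaction(partner="sex"), 0.3),
        PlantedEffect("smoker", Monotone(), 0.35),
        PlantedEffect("general_health", Monotone(), 0.3),
    )
    return CohortSpec(
        n_subjects=n_subjects,
        features=features,
        effects=effects,
        redundancy_groups=(body,),
        n_noise_features=n_noise_features,
        missing_rate=missing_rate,
        seed=seed,
    )


def spec_to_dict(spec: CohortSpec) -> dict:
    """JSON-serializable description of a spec (for sidecar metadata)."""
    d = asdict(spec)
    for i, e in enumerate(spec.effects):
        d["effects"][i]["shape_kind"] = type(e.shape).__name__
    return d
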
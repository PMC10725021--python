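"""Synthetic MDD cohort generator with known conditional-dependence truth.

The generator draws a latent multivariate normal vector whose precision
matrix encodes a chosen sparse graph of partial correlations (the ground
truth an estimator should recover), then pushes each coordinate through a
monotone discretization onto its questionnaire scale.  Because the map is
monotone, the latent conditional-independence structure is what a copula-
aware estimator sees, while the observed margins (integer Likert items and
subscale totals) are calibrated to published cohort descriptives.

Discretization model: an integer-valued column on [lo, hi] is generated as
``clip(round(a*z + b), lo, hi)`` from the standard-normal latent z, which
is equivalent to cutting z at thresholds ((v + 0.5) - b)/a.  The two free
parameters (a, b) are solved numerically per variable so the discrete
column's exact mean and SD match their targets (|mean error| < 0.05 by
construction of the solver tolerance).

Presets
-------
``paper_like``
    25 latent questionnaire variables (7 insomnia items, 3 personality
    subscales, 4 interpersonal-distress subscales, 5 childhood-trauma
    subscales, 3 social-support subscales, two depression-severity totals,
    age) plus gender and medication-group categorical covariates.  Margins
    are calibrated to a published MDD cohort of n = 791 (insomnia total
    10.99 +/- 6.49, neuroticism 18.16 +/- 4.66, depression-severity-17
    17.51 +/- 7.47, age 22.06 +/- 4.72, 75.9% female).  The planted graph
    echoes the qualitative findings such an analysis reports: strong
    within-insomnia edges (maintenance-awakening, worry-daytime), a
    neuroticism bridge into the insomnia community, weak distress/support
    edges to single symptoms, and no trauma-insomnia edges.  Medication
    group shifts the depression-severity latent (a linear-latent link).
``chain``
    Three continuous unit-normal variables with partial correlations 0.3 on
    the 1-2 and 2-3 pairs only; the canonical recovery benchmark.
``independent``
    Six continuous unit-normal variables with an empty graph.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import CATEGORICAL, CONTINUOUS, CohortDataset, VariableSpec
from .exceptions import SpecError

# Scale factor applied to the within-insomnia base partial correlations of
# the paper_like preset; fixed by one-off calibration of the insomnia-total
# SD (target 6.49) under the discretized margins.
_ISI_BASE = 0.11


@dataclass(frozen=True)
class Marginal:
    """Target margin for one generated column."""

    kind: str  # "likert" (discretized integer) | "normal" (identity latent)
    lo: float = 0.0
    hi: float = 0.0
    mean: float = 0.0
    sd: float = 1.0


@dataclass
class CovariateModel:
    """Categorical covariates drawn outside the copula.

    ``hamd_shift`` adds a per-medication-group offset to the depression-
    severity latents before discretization (treated groups lower), the
    linear-latent link between pharmacological treatment and severity.
    """

    gender_levels: tuple[int, ...] = (0, 1)  # 0 male, 1 female
    gender_probs: tuple[float, ...] = (191 / 791, 600 / 791)
    medication_levels: tuple[int, ...] = (0, 1, 2, 3)
    # untreated / antidepressants / antidepressants+hypnotics / not reported
    medication_probs: tuple[float, ...] = (457 / 791, 195 / 791, 27 / 791, 112 / 791)
    # probability-weighted to ~0 so the severity margin stays calibrated
    hamd_shift: tuple[float, ...] = (0.24, -0.46, -0.16, -0.11)


@dataclass
class GeneratorConfig:
    """Everything needed to draw one synthetic cohort."""

    n: int = 791
    seed: int = 0
    preset: str = "paper_like"
    # populated from the preset (or supplied directly):
    names: list[str] = field(default_factory=list)
    communities: list[str] = field(default_factory=list)
    roles: list[str] = field(default_factory=list)
    partials: dict[tuple[str, str], float] = field(default_factory=dict)
    marginals: dict[str, Marginal] = field(default_factory=dict)
    covariates: CovariateModel | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SpecError("cohort size must be >= 2")
        if not self.names:
            _apply_preset(self)
        _latent_correlation(self)  # validates positive definiteness eagerly


@dataclass
class GroundTruth:
    """The generating graph, for recovery checks."""

    nodes: list[str]
    communities: dict[str, str]
    adjacency: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.array_equal(w, w.T) or np.any(np.diag(w) != 0):
            raise SpecError("ground-truth weights must be symmetric with zero diagonal")
        self.weights = w
        self.adjacency = np.asarray(self.adjacency, dtype=bool)


# ---------------------------------------------------------------------------
# Presets

_ISI_ITEMS = [
    # (name, mean, sd) on the 0-4 item scale
    ("DIS", 1.74, 1.31),
    ("DMS", 1.40, 1.26),
    ("EMA", 1.32, 1.18),
    ("DS", 2.40, 1.13),
    ("IDF", 1.54, 1.07),
    ("NIQoL", 1.03, 1.01),
    ("Worry", 1.56, 1.15),
]

_PAPER_VARS: list[tuple[str, str, str, Marginal]] = (
    [(n, "ISI", "symptom", Marginal("likert", 0, 4, m, s)) for n, m, s in _ISI_ITEMS]
    + [
        ("EPQ_P", "EPQ", "factor", Marginal("likert", 0, 23, 5.39, 2.96)),
        ("EPQ_E", "EPQ", "factor", Marginal("likert", 0, 21, 6.90, 4.55)),
        ("EPQ_N", "EPQ", "factor", Marginal("likert", 0, 23, 18.16, 4.66)),
        ("IRCDS_Convo", "IRCDS", "factor", Marginal("likert", 0, 7, 4.01, 1.88)),
        ("IRCDS_MF", "IRCDS", "factor", Marginal("likert", 0, 7, 4.96, 1.89)),
        ("IRCDS_MDP", "IRCDS", "factor", Marginal("likert", 0, 7, 2.55, 1.66)),
        ("IRCDS_HI", "IRCDS", "factor", Marginal("likert", 0, 7, 2.73, 1.89)),
        ("CTQ_EA", "CTQ", "factor", Marginal("likert", 5, 25, 9.75, 4.53)),
        ("CTQ_PA", "CTQ", "factor", Marginal("likert", 5, 25, 7.13, 3.42)),
        ("CTQ_SA", "CTQ", "factor", Marginal("likert", 5, 25, 5.92, 2.10)),
        ("CTQ_EN", "CTQ", "factor", Marginal("likert", 5, 25, 13.27, 5.57)),
        ("CTQ_PN", "CTQ", "factor", Marginal("likert", 5, 25, 8.49, 3.60)),
        ("SSRS_OS", "SSRS", "factor", Marginal("likert", 1, 22, 8.53, 2.84)),
        ("SSRS_SS", "SSRS", "factor", Marginal("likert", 8, 32, 16.66, 3.90)),
        ("SSRS_UoS", "SSRS", "factor", Marginal("likert", 3, 12, 6.38, 1.79)),
        ("HAMD14", "COVARIATE", "covariate", Marginal("likert", 0, 42, 14.89, 6.42)),
        ("HAMD17", "COVARIATE", "covariate", Marginal("likert", 0, 52, 17.51, 7.47)),
        ("age", "COVARIATE", "covariate", Marginal("likert", 18, 55, 22.06, 4.72)),
    ]
)


class _EdgeDict(dict):
    """Partial-correlation edges keyed symmetrically."""

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def __setitem__(self, key, value):
        super().__setitem__(self._key(*key), value)

    def __getitem__(self, key):
        return super().__getitem__(self._key(*key))

    def __contains__(self, key):
        return super().__contains__(self._key(*key))

    def bump(self, a: str, b: str, delta: float) -> None:
        self[a, b] = self.get(self._key(a, b), 0.0) + delta


def _paper_partials() -> dict[tuple[str, str], float]:
    e = _EdgeDict()
    isi = [n for n, *_ in _ISI_ITEMS]
    for i in range(len(isi)):
        for j in range(i + 1, len(isi)):
            e[(isi[i], isi[j])] = _ISI_BASE
    # headline within-insomnia edges
    e.bump("DMS", "EMA", 0.16)
    e.bump("Worry", "IDF", 0.13)
    e.bump("Worry", "DS", 0.11)
    e.bump("DIS", "DMS", 0.07)
    e.bump("IDF", "NIQoL", 0.07)
    # personality
    e[("EPQ_N", "Worry")] = 0.20
    e[("EPQ_N", "EMA")] = 0.10
    e[("EPQ_P", "EPQ_N")] = 0.22
    e[("EPQ_N", "IRCDS_MF")] = 0.16
    e[("EPQ_N", "IRCDS_MDP")] = 0.12
    e[("EPQ_P", "IRCDS_MDP")] = 0.14
    e[("EPQ_P", "IRCDS_Convo")] = 0.10
    e[("EPQ_E", "IRCDS_Convo")] = -0.14
    e[("EPQ_E", "IRCDS_MF")] = -0.12
    e[("EPQ_E", "SSRS_UoS")] = 0.16
    e[("EPQ_E", "SSRS_SS")] = 0.10
    # interpersonal distress
    e[("IRCDS_Convo", "IRCDS_MF")] = 0.30
    e[("IRCDS_Convo", "IRCDS_MDP")] = 0.20
    e[("IRCDS_MF", "IRCDS_HI")] = 0.22
    e[("IRCDS_MDP", "IRCDS_HI")] = 0.16
    e[("IRCDS_Convo", "IRCDS_HI")] = 0.10
    e[("IRCDS_MF", "IRCDS_MDP")] = 0.12
    e[("IRCDS_Convo", "SSRS_UoS")] = -0.14
    e[("IRCDS_MDP", "IDF")] = 0.15  # weak distress-symptom edge
    # childhood trauma: interconnected, no insomnia edges
    e[("CTQ_EA", "CTQ_PA")] = 0.30
    e[("CTQ_EA", "CTQ_EN")] = 0.28
    e[("CTQ_EN", "CTQ_PN")] = 0.35
    e[("CTQ_PA", "CTQ_PN")] = 0.18
    e[("CTQ_EA", "CTQ_SA")] = 0.12
    e[("CTQ_PA", "CTQ_SA")] = 0.20
    e[("CTQ_EA", "EPQ_N")] = 0.14
    e[("CTQ_EN", "SSRS_SS")] = -0.16
    e[("CTQ_PN", "SSRS_OS")] = -0.12
    # social support
    e[("SSRS_OS", "SSRS_SS")] = 0.28
    e[("SSRS_SS", "SSRS_UoS")] = 0.20
    e[("SSRS_OS", "SSRS_UoS")] = 0.12
    e[("SSRS_OS", "DIS")] = -0.15  # weak support-symptom edge
    # depression severity
    e[("HAMD14", "Worry")] = 0.12
    e[("HAMD14", "IDF")] = 0.14
    e[("HAMD14", "DMS")] = 0.08
    e[("HAMD14", "EPQ_N")] = 0.18
    e[("HAMD14", "SSRS_OS")] = -0.10
    e[("HAMD14", "IRCDS_MF")] = 0.08
    e[("HAMD14", "HAMD17")] = 0.60
    return e


def _apply_preset(cfg: GeneratorConfig) -> None:
    if cfg.preset == "paper_like":
        cfg.names = [v[0] for v in _PAPER_VARS] + ["gender", "medication"]
        cfg.communities = [v[1] for v in _PAPER_VARS] + ["COVARIATE", "COVARIATE"]
        cfg.roles = [v[2] for v in _PAPER_VARS] + ["covariate", "covariate"]
        cfg.marginals = {v[0]: v[3] for v in _PAPER_VARS}
        cfg.partials = _paper_partials()
        cfg.covariates = cfg.covariates or CovariateModel()
    elif cfg.preset == "chain":
        cfg.names = ["V1", "V2", "V3"]
        cfg.communities = ["A", "B", "A"]
        cfg.roles = ["factor", "factor", "factor"]
        cfg.marginals = {v: Marginal("normal") for v in cfg.names}
        cfg.partials = {("V1", "V2"): 0.3, ("V2", "V3"): 0.3}
    elif cfg.preset == "independent":
        cfg.names = [f"V{i+1}" for i in range(6)]
        cfg.communities = ["A", "B"] * 3
        cfg.roles = ["factor"] * 6
        cfg.marginals = {v: Marginal("normal") for v in cfg.names}
        cfg.partials = {}
    else:
        raise SpecError(f"unknown preset {cfg.preset!r}")


# ---------------------------------------------------------------------------
# Latent covariance


def _latent_names(cfg: GeneratorConfig) -> list[str]:
    return [v for v in cfg.names if v in cfg.marginals]


def _precision(cfg: GeneratorConfig) -> np.ndarray:
    names = _latent_names(cfg)
    idx = {v: i for i, v in enumerate(names)}
    p = len(names)
    omega = np.eye(p)
    for (a, b), rho in cfg.partials.items():
        if a not in idx or b not in idx:
            raise SpecError(f"edge ({a}, {b}) references an unknown latent variable")
        omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = -rho
    return omega


def _latent_correlation(cfg: GeneratorConfig) -> np.ndarray:
    omega = _precision(cfg)
    eig = np.linalg.eigvalsh(omega)
    if eig.min() <= 1e-8:
        raise SpecError(
            f"implied latent precision is not positive definite (min eigenvalue {eig.min():.4g})"
        )
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


# ---------------------------------------------------------------------------
# Discretization


@functools.lru_cache(maxsize=256)
def solve_discretization(marg: Marginal) -> tuple[float, float]:
    """Solve (a, b) so clip(round(a*z + b), lo, hi) has the target mean/SD."""
    lo, hi = int(marg.lo), int(marg.hi)
    values = np.arange(lo, hi + 1, dtype=float)

    def moments(a: float, b: float) -> tuple[float, float]:
        cuts = (values[:-1] + 0.5 - b) / a
        cdf = np.concatenate(([0.0], stats.norm.cdf(cuts), [1.0]))
        probs = np.diff(cdf)
        mean = float(probs @ values)
        var = float(probs @ (values - mean) ** 2)
        return mean, np.sqrt(var)

    def resid(x):
        m, s = moments(x[0], x[1])
        # bounded scales cannot always hit (mean, SD) jointly; prioritize the
        # mean (the calibration target) and let the SD absorb the residual
        return [10.0 * (m - marg.mean), s - marg.sd]

    sol = optimize.least_squares(
        resid, x0=[marg.sd, marg.mean], bounds=([1e-3, lo - 20 * marg.sd], [np.inf, hi + 20 * marg.sd])
    )
    a, b = float(sol.x[0]), float(sol.x[1])
    m, s = moments(a, b)
    if abs(m - marg.mean) > 0.05:
        raise SpecError(
            f"discretization solver missed the target mean by {abs(m - marg.mean):.3f}"
        )
    return a, b


def _discretize(z: np.ndarray, marg: Marginal, a: float, b: float) -> np.ndarray:
    return np.clip(np.round(a * z + b), marg.lo, marg.hi)


# ---------------------------------------------------------------------------
# Generation


def generate_cohort(config: GeneratorConfig) -> tuple[CohortDataset, GroundTruth]:
    """Draw one cohort and its generating-graph ground truth.

    Identical (config, seed) pairs produce bit-identical datasets: the
    random stream is consumed in a fixed order (latent normal block first,
    then gender, then medication).
    """
    cfg = config
    R = _latent_correlation(cfg)
    latent_names = _latent_names(cfg)
    rng = np.random.default_rng(cfg.seed)
    L = np.linalg.cholesky(R)
    Z = rng.standard_normal((cfg.n, len(latent_names))) @ L.T

    columns: dict[str, np.ndarray] = {}
    cov = cfg.covariates
    if cov is not None:
        gender = rng.choice(np.array(cov.gender_levels), size=cfg.n, p=np.array(cov.gender_probs))
        medication = rng.choice(
            np.array(cov.medication_levels), size=cfg.n, p=np.array(cov.medication_probs)
        )
        shift = np.array(cov.hamd_shift)[np.searchsorted(cov.medication_levels, medication)]
        for name in ("HAMD14", "HAMD17"):
            if name in latent_names:
                Z[:, latent_names.index(name)] += shift
        columns["gender"] = gender.astype(float)
        columns["medication"] = medication.astype(float)

    for j, name in enumerate(latent_names):
        marg = cfg.marginals[name]
        if marg.kind == "normal":
            columns[name] = Z[:, j]
        else:
            a, b = solve_discretization(marg)
            columns[name] = _discretize(Z[:, j], marg, a, b)

    specs = []
    for name, comm, role in zip(cfg.names, cfg.communities, cfg.roles):
        if name == "gender" and cov is not None:
            specs.append(VariableSpec(name, CATEGORICAL, levels=cov.gender_levels,
                                      community=comm, role=role))
        elif name == "medication" and cov is not None:
            specs.append(VariableSpec(name, CATEGORICAL, levels=cov.medication_levels,
                                      community=comm, role=role))
        else:
            marg = cfg.marginals[name]
            if marg.kind == "normal":
                specs.append(VariableSpec(name, CONTINUOUS, community=comm, role=role))
            else:
                specs.append(VariableSpec(name, CONTINUOUS, min_value=marg.lo,
                                          max_value=marg.hi, community=comm, role=role))

    values = pd.DataFrame({name: columns[name] for name in cfg.names})
    data = CohortDataset(values, specs, provenance=f"generator:{cfg.preset}:seed={cfg.seed}:n={cfg.n}")

    truth = _ground_truth(cfg)
    return data, truth


def _ground_truth(cfg: GeneratorConfig) -> GroundTruth:
    names = list(cfg.names)
    idx = {v: i for i, v in enumerate(names)}
    p = len(names)
    weights = np.zeros((p, p))
    for (a, b), rho in cfg.partials.items():
        weights[idx[a], idx[b]] = weights[idx[b], idx[a]] = rho
    adjacency = weights != 0
    # the medication -> depression-severity link is a planted dependence even
    # though it lives outside the copula; record it in the adjacency
    if cfg.covariates is not None and "medication" in idx:
        for name in ("HAMD14", "HAMD17"):
            if name in idx and any(s != 0 for s in cfg.covariates.hamd_shift):
                adjacency[idx["medication"], idx[name]] = True
                adjacency[idx[name], idx["medication"]] = True
    return GroundTruth(
        nodes=names,
        communities={v: c for v, c in zip(cfg.names, cfg.communities)},
        adjacency=adjacency,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# Descriptives


@dataclass
class Descriptives:
    """Cohort summary: moments for numeric columns, level tables for categorical."""

    numeric: pd.DataFrame
    categorical: pd.DataFrame


def moment_summary(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd[n-1], moment-ratio skewness, non-excess kurtosis m4/m2^2)."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    d = x - m
    m2 = np.mean(d**2)
    sd = x.std(ddof=1)
    if m2 == 0:
        return float(m), float(sd), 0.0, 0.0
    skew = float(np.mean(d**3) / m2**1.5)
    kurt = float(np.mean(d**4) / m2**2)
    return float(m), float(sd), skew, kurt


def summarize_cohort(data: CohortDataset) -> Descriptives:
    """Per-variable descriptives in the conventions of cohort tables:
    SD with n-1 denominator, moment-ratio skewness, non-excess kurtosis
    (a normal distribution scores 3); categorical variables get level
    counts and percentages."""
    if data.n == 0:
        raise SpecError("cannot summarize an empty dataset")
    num_rows, cat_rows = [], []
    for s in data.specs:
        col = data.values[s.name].to_numpy(dtype=float)
        if s.is_categorical:
            for lv in s.levels:
                count = int((col == lv).sum())
                cat_rows.append(
                    {"variable": s.name, "level": lv, "count": count,
                     "percent": 100.0 * count / data.n}
                )
        else:
            mean, sd, skew, kurt = moment_summary(col)
            num_rows.append(
                {"variable": s.name, "mean": mean, "sd": sd,
                 "skewness": skew, "kurtosis": kurt}
            )
    numeric = pd.DataFrame(num_rows).set_index("variable") if num_rows else pd.DataFrame()
    categorical = pd.DataFrame(cat_rows).set_index(["variable", "level"]) if cat_rows else pd.DataFrame()
    return Descriptives(numeric=numeric, categorical=categorical)


def isi_total(data: CohortDataset) -> np.ndarray:
    """Sum of the seven insomnia items of a paper_like-style cohort."""
    items = [n for n, *_ in _ISI_ITEMS]
    missing = [c for c in items if c not in data.names]
    if missing:
        raise SpecError(f"dataset lacks insomnia items: {missing}")
    return data.values[items].to_numpy(dtype=float).sum(axis=1)


__all__ = [
    "Marginal",
    "CovariateModel",
    "GeneratorConfig",
    "GroundTruth",
    "Descriptives",
    "generate_cohort",
    "summarize_cohort",
    "moment_summary",
    "solve_discretization",
    "isi_total",
]
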
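"""Synthetic cohort generation with known Ising ground truth.

Respondent vectors are drawn from a pairwise binary Markov random field on
{0,1}^p:

    P(x) \\propto exp( tau' x  +  sum_{i<j} omega_ij x_i x_j )

so each omega entry is the conditional log-odds ratio of its item pair and
each tau entry a baseline log-odds threshold.  Demographic covariates shift
thresholds additively (tau + beta z), country strata add a further offset,
and a logistic selection mechanism distorts the sampled demographics so that
post-stratification raking downstream is non-trivial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .items import ITEM_LABELS, ResponseMatrix

EXACT_MAX_P = 20
GIBBS_BURNIN = 1000  # sweeps discarded per chain
GIBBS_THIN = 10      # sweeps between retained draws

#: Covariate columns, in the order `beta` and `selection_bias` index them.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "age_band",
    "partnered",
    "university",
    "high_income",
    "employed",
    "child_household",
    "works_with_children",
)


class SimulationError(ValueError):
    pass


@dataclass
class TrueIsingModel:
    """Ground-truth thresholds, pairwise interactions, and covariate effects."""

    tau: np.ndarray                      # (p,) baseline log-odds thresholds
    omega: np.ndarray                    # (p, p) symmetric, zero diagonal
    beta: np.ndarray | None = None       # (p, n_cov) threshold shifts per covariate
    labels: tuple[str, ...] = ITEM_LABELS
    covariates: tuple[str, ...] = COVARIATE_COLUMNS

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        p = self.tau.shape[0]
        if self.omega.shape != (p, p):
            raise SimulationError("omega must be p x p")
        if not np.allclose(self.omega, self.omega.T):
            raise SimulationError("omega must be symmetric")
        if np.abs(np.diag(self.omega)).max(initial=0.0) != 0.0:
            raise SimulationError("omega must have zero diagonal")
        if not (np.isfinite(self.tau).all() and np.isfinite(self.omega).all()):
            raise SimulationError("tau and omega must be finite")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (p, len(self.covariates)):
                raise SimulationError(
                    f"beta must be {p} x {len(self.covariates)} "
                    f"(items x covariates {self.covariates})"
                )
        self.labels = tuple(self.labels)[:p]

    @property
    def p(self) -> int:
        return self.tau.shape[0]

    @property
    def sparsity(self) -> float:
        """Fraction of item pairs with a nonzero interaction."""
        iu = np.triu_indices(self.p, k=1)
        return float(np.mean(self.omega[iu] != 0.0))

    def edge_set(self) -> set[tuple[int, int]]:
        iu = np.triu_indices(self.p, k=1)
        return {
            (int(i), int(j))
            for i, j in zip(*iu)
            if self.omega[i, j] != 0.0
        }


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort: strata, covariates, selection bias."""

    n: int
    country_labels: tuple[str, ...] = ("AU", "UK", "US")
    country_props: tuple[float, ...] = (0.40, 0.30, 0.30)
    country_tau_offsets: tuple[float, ...] = (0.0, 0.0, 0.4)
    covariate_generators: dict[str, np.ndarray] = field(default_factory=dict)
    selection_bias: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationError("n must be >= 1")
        props = np.asarray(self.country_props, dtype=float)
        if not np.isclose(props.sum(), 1.0):
            raise SimulationError("country mixing proportions must sum to 1")
        if len(self.country_labels) != len(self.country_props):
            raise SimulationError("country labels/proportions length mismatch")
        gens = dict(DEFAULT_COVARIATE_GENERATORS)
        gens.update(self.covariate_generators)
        unknown = set(gens) - set(COVARIATE_COLUMNS)
        if unknown:
            raise SimulationError(f"unknown covariates in generators: {sorted(unknown)}")
        self.covariate_generators = gens
        bad = set(self.selection_bias) - set(COVARIATE_COLUMNS)
        if bad:
            raise SimulationError(f"unknown covariates in selection_bias: {sorted(bad)}")


@dataclass
class SyntheticCohort:
    """Responses + demographics + the truth and population margins behind them."""

    responses: ResponseMatrix
    demographics: pd.DataFrame
    truth: TrueIsingModel
    population_margins: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if self.responses.n != len(self.demographics):
            raise SimulationError("responses and demographics row counts differ")

    @property
    def n(self) -> int:
        return self.responses.n


# Age bands are the six ordered brackets 18-24 ... 65+; covariate z-encoding
# maps band b to (b - 3.5) / 2.5 in [-1, 1], binaries stay 0/1.
DEFAULT_COVARIATE_GENERATORS: dict[str, np.ndarray] = {
    "age_band": np.array([0.12, 0.18, 0.18, 0.17, 0.16, 0.19]),
    "partnered": np.array([0.40, 0.60]),
    "university": np.array([0.68, 0.32]),
    "high_income": np.array([0.75, 0.25]),
    "employed": np.array([0.30, 0.70]),
    "child_household": np.array([0.65, 0.35]),
    "works_with_children": np.array([0.90, 0.10]),
}


def covariate_design(demographics: pd.DataFrame) -> np.ndarray:
    """Map a demographics table to the z-matrix multiplying `beta`."""
    cols = []
    for name in COVARIATE_COLUMNS:
        v = demographics[name].to_numpy(dtype=float)
        if name == "age_band":
            v = (v - 3.5) / 2.5
        cols.append(v)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------

def enumerate_states(p: int) -> np.ndarray:
    """All 2^p binary states, one row per state (lexicographic)."""
    if p > EXACT_MAX_P:
        raise SimulationError(
            f"p={p} too large for exact enumeration (max {EXACT_MAX_P}); use method='gibbs'"
        )
    return np.array(list(itertools.product((0, 1), repeat=p)), dtype=np.int8)


def state_log_weights(tau: np.ndarray, omega: np.ndarray, states: np.ndarray) -> np.ndarray:
    s = states.astype(float)
    return s @ tau + 0.5 * np.einsum("si,ij,sj->s", s, omega, s)


def exact_distribution(truth: TrueIsingModel) -> tuple[np.ndarray, np.ndarray]:
    """(states, probabilities) of the fully enumerated model."""
    states = enumerate_states(truth.p)
    logw = state_log_weights(truth.tau, truth.omega, states)
    logw -= logw.max()
    w = np.exp(logw)
    return states, w / w.sum()


def exact_marginals(truth: TrueIsingModel) -> np.ndarray:
    states, probs = exact_distribution(truth)
    return probs @ states


def _gibbs_sample(
    tau: np.ndarray,
    omega: np.ndarray,
    n: int,
    rng: np.random.Generator,
    burnin: int = GIBBS_BURNIN,
    thin: int = GIBBS_THIN,
    n_chains: int | None = None,
) -> np.ndarray:
    p = tau.shape[0]
    if n_chains is None:
        n_chains = min(n, 256)
    per_chain = -(-n // n_chains)  # ceil
    x = (rng.random((n_chains, p)) < 0.5).astype(np.int8)
    draws = np.empty((n_chains * per_chain, p), dtype=np.int8)
    n_sweeps = burnin + per_chain * thin
    kept = 0
    for sweep in range(n_sweeps):
        for i in range(p):
            eta = tau[i] + x @ omega[:, i]
            prob = 1.0 / (1.0 + np.exp(-eta))
            x[:, i] = rng.random(n_chains) < prob
        if sweep >= burnin and (sweep - burnin) % thin == thin - 1:
            draws[kept * n_chains : (kept + 1) * n_chains] = x
            kept += 1
    return draws[:n]


def simulate_ising(
    truth: TrueIsingModel,
    n: int,
    method: str = "exact",
    seed: int | np.random.Generator = 0,
    *,
    burnin: int = GIBBS_BURNIN,
    thin: int = GIBBS_THIN,
    n_chains: int | None = None,
) -> ResponseMatrix:
    """Draw n respondent vectors from the Ising truth.

    method='exact' enumerates all 2^p states (p <= 20) and samples from the
    normalised distribution; method='gibbs' runs parallel Gibbs chains with
    `burnin` discarded sweeps and `thin` sweeps between retained draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "exact":
        states, probs = exact_distribution(truth)
        idx = rng.choice(states.shape[0], size=n, p=probs)
        values = states[idx]
    elif method == "gibbs":
        values = _gibbs_sample(
            truth.tau, truth.omega, n, rng, burnin=burnin, thin=thin, n_chains=n_chains
        )
    else:
        raise SimulationError(f"unknown method {method!r}")
    return ResponseMatrix(values, truth.labels)


# ---------------------------------------------------------------------------
# Demographics and selection
# ---------------------------------------------------------------------------

def _draw_demographics(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n
    country = rng.choice(
        len(spec.country_labels), size=n, p=np.asarray(spec.country_props, dtype=float)
    )
    cols: dict[str, np.ndarray] = {
        "country": np.asarray(spec.country_labels)[country],
    }
    for name in COVARIATE_COLUMNS:
        probs = np.asarray(spec.covariate_generators[name], dtype=float)
        levels = rng.choice(len(probs), size=n, p=probs)
        if name == "age_band":
            cols[name] = levels + 1  # bands coded 1..6
        else:
            cols[name] = levels
    df = pd.DataFrame(cols)
    df.insert(0, "respondent_id", np.arange(1, n + 1))
    return df


def _margins_from_sample(demographics: pd.DataFrame) -> dict[str, dict[str, float]]:
    margins: dict[str, dict[str, float]] = {}
    for name in ("country", *COVARIATE_COLUMNS):
        counts = demographics[name].value_counts(normalize=True).sort_index()
        margins[name] = {str(k): float(v) for k, v in counts.items()}
    return margins


def attach_demographics(
    responses: ResponseMatrix,
    spec: CohortSpec,
    truth: TrueIsingModel,
    seed: int | np.random.Generator = 0,
) -> SyntheticCohort:
    """Draw demographics and re-simulate items with per-respondent thresholds.

    Each respondent's threshold vector is tau + beta z + country offset; rows
    sharing a covariate pattern share one exactly enumerated distribution, so
    the draw is exact for p <= 20.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.n != responses.n:
        spec = replace(spec, n=responses.n)
    demographics = _draw_demographics(spec, rng)
    margins = _margins_from_sample(demographics)

    p = truth.p
    z = covariate_design(demographics)
    shift = z @ truth.beta.T if truth.beta is not None else np.zeros((spec.n, p))
    offsets = dict(zip(spec.country_labels, spec.country_tau_offsets))
    shift += np.array([offsets[c] for c in demographics["country"]])[:, None]

    states = enumerate_states(p)
    pair_logw = 0.5 * np.einsum(
        "si,ij,sj->s", states.astype(float), truth.omega, states.astype(float)
    )
    values = np.empty((spec.n, p), dtype=np.int8)
    # group respondents by identical threshold shift; enumerate once per group
    uniq, inverse = np.unique(np.round(shift, 12), axis=0, return_inverse=True)
    u = rng.random(spec.n)
    for g in range(uniq.shape[0]):
        rows = np.flatnonzero(inverse == g)
        logw = states @ (truth.tau + uniq[g]) + pair_logw
        logw -= logw.max()
        w = np.exp(logw)
        cdf = np.cumsum(w / w.sum())
        idx = np.searchsorted(cdf, u[rows], side="right").clip(max=states.shape[0] - 1)
        values[rows] = states[idx]

    return SyntheticCohort(
        responses=ResponseMatrix(values, truth.labels),
        demographics=demographics,
        truth=truth,
        population_margins=margins,
    )


def biased_subsample(
    cohort: SyntheticCohort,
    selection_bias: dict[str, float],
    n_keep: int,
    seed: int | np.random.Generator = 0,
) -> SyntheticCohort:
    """Retain n_keep rows with probability proportional to logistic(bias . z).

    Population margins are left untouched: they describe the pre-selection
    cohort and are the raking targets downstream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_keep > cohort.n:
        raise SimulationError("n_keep exceeds cohort size")
    bad = set(selection_bias) - set(COVARIATE_COLUMNS)
    if bad:
        raise SimulationError(f"unknown covariates in selection_bias: {sorted(bad)}")
    z = covariate_design(cohort.demographics)
    eta = np.zeros(cohort.n)
    for name, coef in selection_bias.items():
        eta += coef * z[:, COVARIATE_COLUMNS.index(name)]
    probs = 1.0 / (1.0 + np.exp(-eta))
    if probs.sum() < 1e-12:
        raise SimulationError("selection probabilities are all ~0")
    keep = rng.choice(cohort.n, size=n_keep, replace=False, p=probs / probs.sum())
    keep.sort()
    return SyntheticCohort(
        responses=ResponseMatrix(cohort.responses.values[keep], cohort.responses.labels),
        demographics=cohort.demographics.iloc[keep].reset_index(drop=True),
        truth=cohort.truth,
        population_margins=cohort.population_margins,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Pooled target marginal prevalences used to calibrate the default preset.
DEFAULT_PREVALENCE_TARGETS = np.array(
    [0.035, 0.046, 0.047, 0.024, 0.027, 0.055, 0.057, 0.080, 0.057, 0.074]
)

#: Twelve sparse positive edges (0-based item pairs) with weights in [0.5, 1.5].
DEFAULT_EDGES: tuple[tuple[int, int, float], ...] = (
    (0, 1, 1.3),   # viewed_csam -- contact_child
    (0, 9, 1.2),   # viewed_csam -- likely_contact_u14
    (0, 8, 0.9),   # viewed_csam -- concerned
    (2, 3, 1.5),   # flirted_online -- webcam_child
    (3, 4, 1.4),   # webcam_child -- purchased_csam
    (4, 9, 1.1),   # purchased_csam -- likely_contact_u14
    (5, 6, 0.9),   # would_view_csam -- would_watch_webcam
    (5, 7, 0.8),   # would_view_csam -- feelings
    (6, 7, 1.0),   # would_watch_webcam -- feelings
    (7, 8, 0.6),   # feelings -- concerned
    (8, 9, 1.0),   # concerned -- likely_contact_u14
    (1, 9, 0.7),   # contact_child -- likely_contact_u14
)


def calibrate_tau(
    omega: np.ndarray,
    target_marginals: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Find tau so the enumerated marginals hit the targets (fixed point)."""
    target = np.asarray(target_marginals, dtype=float)
    p = omega.shape[0]
    states = enumerate_states(p)
    pair_logw = 0.5 * np.einsum(
        "si,ij,sj->s", states.astype(float), omega, states.astype(float)
    )
    logit = lambda q: np.log(q / (1.0 - q))
    tau = logit(target)
    for _ in range(max_iter):
        logw = states @ tau + pair_logw
        logw -= logw.max()
        w = np.exp(logw)
        marg = (w / w.sum()) @ states
        err = logit(target) - logit(marg)
        tau = tau + err
        if np.abs(err).max() < tol:
            break
    return tau


def default_truth(p: int = 10) -> TrueIsingModel:
    """Default sparse ground truth: 12 edges, marginal prevalences 2.4%-8%."""
    if p != 10:
        raise SimulationError("default_truth is defined for p=10")
    omega = np.zeros((p, p))
    for i, j, wgt in DEFAULT_EDGES:
        omega[i, j] = omega[j, i] = wgt
    tau = calibrate_tau(omega, DEFAULT_PREVALENCE_TARGETS)
    beta = np.zeros((p, len(COVARIATE_COLUMNS)))
    # mild "trust and access" effects on selected items
    beta[0, COVARIATE_COLUMNS.index("works_with_children")] = np.log(2.0)
    beta[3, COVARIATE_COLUMNS.index("child_household")] = np.log(2.0)
    beta[9, COVARIATE_COLUMNS.index("high_income")] = np.log(1.5)
    return TrueIsingModel(tau=tau, omega=omega, beta=beta)


def independence_truth(p: int = 10) -> TrueIsingModel:
    """Null ground truth: no pairwise dependence, same marginals."""
    tau = np.log(
        DEFAULT_PREVALENCE_TARGETS[:p] / (1.0 - DEFAULT_PREVALENCE_TARGETS[:p])
    )
    return TrueIsingModel(tau=tau, omega=np.zeros((p, p)))


def recovery_truth(p: int = 10, effect: float = np.log(4.0)) -> TrueIsingModel:
    """Default truth with a planted works-with-children effect for recovery tests."""
    truth = default_truth(p)
    beta = np.zeros_like(truth.beta)
    beta[0, COVARIATE_COLUMNS.index("works_with_children")] = effect
    return TrueIsingModel(tau=truth.tau, omega=truth.omega, beta=beta)


DEFAULT_SELECTION_BIAS: dict[str, float] = {
    "age_band": -0.6,      # oversample younger respondents
    "university": 0.5,     # oversample the university educated
    "employed": 0.3,
}

PRESETS = {
    "default": default_truth,
    "independence": independence_truth,
    "recovery": recovery_truth,
}


def generate_cohort(
    n: int,
    preset: str = "default",
    seed: int = 0,
    *,
    biased: bool = True,
    keep_fraction: float = 0.6,
    spec: CohortSpec | None = None,
) -> SyntheticCohort:
    """One-call cohort: truth preset -> demographics -> optional biased subsample."""
    if preset not in PRESETS:
        raise SimulationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    rng = np.random.default_rng(seed)
    truth = PRESETS[preset]()
    n_population = int(np.ceil(n / keep_fraction)) if biased else n
    if spec is None:
        spec = CohortSpec(n=n_population, seed=seed)
    else:
        spec = replace(spec, n=n_population)
    responses = simulate_ising(truth, n_population, method="exact", seed=rng)
    cohort = attach_demographics(responses, spec, truth, seed=rng)
    if biased:
        cohort = biased_subsample(cohort, DEFAULT_SELECTION_BIAS, n, seed=rng)
    return cohort
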
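"""Synthetic cohorts: the binary-panel benchmarking generator and a
longitudinal clinical fixture.

The benchmarking generator produces binary (low/high) feature panels whose
event probability is a sum of time-varying per-feature contributions::

    phi_i = sum_{t in [1,T]} sum_{k in [1,p]} theta_k(x_ik(t), t)

with the event drawn as U(0,1) < phi_i (phi is used literally as a
probability: phi <= 0 never fires, phi >= 1 always).  Scenario knobs are the
number of effector features (complex: 45 of 50; simple: 5 of 50), the
smoothness of each effector's time profile, and the missing-data rate.
Cohorts are oversampled and downsampled to an exact 15% event prevalence.

The clinical fixture emulates an irregularly sampled post-transplant cohort
(continuous labs at feature-specific frequencies, categorical peri
covariates, onset days from a feature-dependent hazard) with recorded ground
truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortDataset, DynamicPanel

STAY_PROB = 0.7        # low->low and high->high transition rate
THETA_BOUND = np.log(0.7 / 0.3)


@dataclass
class SimScenario:
    """Benchmark-generator knobs.

    complexity: 'complex' (45 effectors of p=50) or 'simple' (5 effectors).
    smoothness: 'smooth' (multiplicative Gaussian random walk, sd 0.05) or
    'rough' (iid uniform) time profiles, both rescaled to [0.3, 0.7].
    """

    complexity: str = "complex"
    smoothness: str = "smooth"
    missing_rate: float = 0.6
    n: int = 1000
    p: int = 50
    T: int = 14
    prevalence: float = 0.15
    reps: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.complexity not in ("complex", "simple"):
            raise ValueError("complexity must be 'complex' or 'simple'")
        if self.smoothness not in ("smooth", "rough"):
            raise ValueError("smoothness must be 'smooth' or 'rough'")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.p < self.n_effectors:
            raise ValueError("p must cover the effector features")

    @property
    def n_effectors(self) -> int:
        return 45 if self.complexity == "complex" else 5


@dataclass
class SimCohort:
    """One generated cohort plus its ground truth."""

    features: np.ndarray          # (n, p, T) binary 0=low / 1=high
    missing: np.ndarray           # (n, p, T) bool, True = missing
    event: np.ndarray             # (n,) bool
    theta: np.ndarray             # (p, T, 2) truth: [:, :, 0]=low, 1=high
    alpha: np.ndarray             # (p, T) alpha curves (0 rows for dummies)
    phi: np.ndarray               # (n,) relative risks of the kept individuals
    scenario: SimScenario = None


def simulate_feature_walk(T: int, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Binary Markov chains with stay probability 0.7; shape (size, T)."""
    x = np.empty((size, T), dtype=np.int8)
    x[:, 0] = rng.random(size) < 0.5  # stationary start
    for t in range(1, T):
        switch = rng.random(size) < (1 - STAY_PROB)
        x[:, t] = np.where(switch, 1 - x[:, t - 1], x[:, t - 1])
    return x


def _rescale(a: np.ndarray, lo: float = 0.3, hi: float = 0.7) -> np.ndarray:
    rng_ = a.max(axis=-1, keepdims=True) - a.min(axis=-1, keepdims=True)
    rng_ = np.where(rng_ == 0, 1.0, rng_)
    scaled = lo + (hi - lo) * (a - a.min(axis=-1, keepdims=True)) / rng_
    # a degenerate constant profile maps to the midpoint
    const = (a.max(axis=-1, keepdims=True) == a.min(axis=-1, keepdims=True))
    return np.where(const, (lo + hi) / 2, scaled)


def build_effector_table(scenario: SimScenario, rng: np.random.Generator):
    """Ground-truth theta_k(x, t) and the underlying alpha_k(t) curves.

    Effectors are features 1..n_effectors; the rest are dummies with
    theta == 0.  alpha curves are rescaled so min = 0.3 and max = 0.7
    exactly; theta(high, t) = log(alpha / (1 - alpha)), theta(low, t) =
    -theta(high, t).
    """
    p, T, ne = scenario.p, scenario.T, scenario.n_effectors
    alpha = np.zeros((p, T))
    if scenario.smoothness == "smooth":
        steps = rng.normal(1.0, 0.05, size=(ne, T))
        steps[:, 0] = 1.0
        a = np.cumprod(steps, axis=1)
    else:
        a = rng.uniform(0, 1, size=(ne, T))
    alpha[:ne] = _rescale(a)
    theta = np.zeros((p, T, 2))
    with np.errstate(divide="ignore"):
        th_high = np.where(alpha[:ne] > 0, np.log(alpha[:ne] / (1 - alpha[:ne])), 0.0)
    theta[:ne, :, 1] = th_high
    theta[:ne, :, 0] = -th_high
    return theta, alpha


def phi_from_theta(features: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Relative risk phi_i = sum_t sum_k theta_k(x_ik(t), t); vectorized."""
    th_low, th_high = theta[:, :, 0], theta[:, :, 1]
    x = features.astype(float)
    return (x * th_high[None] + (1 - x) * th_low[None]).sum(axis=(1, 2))


class GenerationError(RuntimeError):
    pass


def simulate_cohort(scenario: SimScenario, rng=None,
                    max_batches: int = 100) -> SimCohort:
    """Generate one cohort with exactly round(n * prevalence) events.

    Individuals are generated in batches of n and the first-come class
    quotas filled without replacement; missingness (if any) is applied after
    event assignment.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    theta, alpha = build_effector_table(scenario, rng)
    n_pos = int(round(scenario.n * scenario.prevalence))
    n_neg = scenario.n - n_pos
    pos_feat, neg_feat, pos_phi, neg_phi = [], [], [], []
    for _ in range(max_batches):
        x = simulate_feature_walk(
            scenario.T, rng, size=scenario.n * scenario.p
        ).reshape(scenario.n, scenario.p, scenario.T)
        phi = phi_from_theta(x, theta)
        u = rng.uniform(0, 1, scenario.n)
        ev = u < phi
        need_pos = n_pos - sum(len(b) for b in pos_feat)
        need_neg = n_neg - sum(len(b) for b in neg_feat)
        if need_pos > 0 and ev.any():
            take = np.nonzero(ev)[0][:need_pos]
            pos_feat.append(x[take])
            pos_phi.append(phi[take])
        if need_neg > 0 and (~ev).any():
            take = np.nonzero(~ev)[0][:need_neg]
            neg_feat.append(x[take])
            neg_phi.append(phi[take])
        if (sum(len(b) for b in pos_feat) >= n_pos
                and sum(len(b) for b in neg_feat) >= n_neg):
            break
    else:
        raise GenerationError(
            f"could not reach {n_pos} events in {max_batches} batches "
            f"(scenario={scenario})"
        )
    features = np.concatenate(pos_feat + neg_feat)
    phi = np.concatenate(pos_phi + neg_phi)
    event = np.zeros(scenario.n, dtype=bool)
    event[:n_pos] = True
    # shuffle so class blocks are not ordered
    perm = rng.permutation(scenario.n)
    features, phi, event = features[perm], phi[perm], event[perm]
    missing = np.zeros(features.shape, dtype=bool)
    if scenario.missing_rate > 0:
        missing = rng.random(features.shape) < scenario.missing_rate
    return SimCohort(features, missing, event, theta, alpha, phi, scenario)


def sim_to_cohort(sim: SimCohort) -> CohortDataset:
    """Adapt a simulated cohort to the clinical panel structure.

    Events get a nominal onset on day T+1 with everyone observed through
    T+1, so the moving-window label at every day 1..T equals the event flag.
    """
    n, p, T = sim.features.shape
    values = np.zeros((n, p, T + 1))
    mask = np.zeros((n, p, T + 1), dtype=bool)
    values[:, :, :T] = sim.features
    mask[:, :, :T] = ~sim.missing
    panel = DynamicPanel(values, mask, [f"i{j}" for j in range(n)],
                         [f"f{k}" for k in range(p)], T + 1)
    peri = pd.DataFrame(index=panel.patients)
    outcomes = pd.DataFrame(
        {
            "onset_day": pd.array(
                [T + 1 if e else pd.NA for e in sim.event], dtype="Int64"
            ),
            "last_observed_day": T + 1,
        },
        index=panel.patients,
    )
    return CohortDataset(panel, peri, outcomes)


def oracle_scores(sim: SimCohort, indices=None) -> np.ndarray:
    """Score with the true theta over observed cells (the ceiling model)."""
    feats = sim.features if indices is None else sim.features[indices]
    miss = sim.missing if indices is None else sim.missing[indices]
    th_low, th_high = sim.theta[:, :, 0], sim.theta[:, :, 1]
    x = feats.astype(float)
    contrib = x * th_high[None] + (1 - x) * th_low[None]
    return np.where(miss, 0.0, contrib).sum(axis=(1, 2))


def run_scenario_grid(scenarios, models=("dagoat", "xgboost"), reps: int = 30,
                      seed: int = 0, holdout: float = 0.2) -> pd.DataFrame:
    """Holdout AUROC / AUPRC per scenario x model x replication.

    Each replication generates a fresh cohort (seeded deterministically from
    ``seed``, the scenario index and the rep index), splits it 80:20 and
    scores the holdout fold.
    """
    from .evaluation import auprc, auroc
    from .model import DaGOAT

    rows = []
    for s_idx, scen in enumerate(scenarios):
        for rep in range(reps):
            ss = np.random.SeedSequence([int(seed), s_idx, rep])
            rng = np.random.default_rng(ss)
            sim = simulate_cohort(scen, rng)
            n = scen.n
            perm = rng.permutation(n)
            n_test = int(round(holdout * n))
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            cohort = sim_to_cohort(sim)
            train = cohort.subset_patients(train_idx)
            test = cohort.subset_patients(test_idx)
            y_test = sim.event[test_idx]
            for model_name in models:
                scores = _fit_score_sim(model_name, sim, train, test,
                                        train_idx, test_idx, scen, ss)
                rows.append({
                    "complexity": scen.complexity,
                    "smoothness": scen.smoothness,
                    "missing_rate": scen.missing_rate,
                    "model": model_name,
                    "rep": rep,
                    "auroc": auroc(scores, y_test),
                    "auprc": auprc(scores, y_test),
                })
    return pd.DataFrame(rows)


def _fit_score_sim(model_name, sim, train, test, train_idx, test_idx, scen, ss):
    from .model import DaGOAT

    if model_name == "dagoat":
        model = DaGOAT(delta=scen.T, horizon=scen.T + 1).fit(train)
        return model.predict_score(test, scen.T)
    if model_name == "oracle":
        return oracle_scores(sim, test_idx)
    if model_name == "xgboost":
        from xgboost import XGBClassifier

        Xtr = _flat(sim, train_idx)
        Xte = _flat(sim, test_idx)
        rs = int(ss.generate_state(1)[0] % (2**31))
        clf = XGBClassifier(random_state=rs, n_jobs=1, verbosity=0)
        clf.fit(Xtr, sim.event[train_idx].astype(int))
        return clf.predict_proba(Xte)[:, 1]
    raise ValueError(f"unknown model {model_name!r}")


def _flat(sim: SimCohort, idx) -> np.ndarray:
    x = sim.features[idx].astype(float)
    x[sim.missing[idx]] = np.nan
    return x.reshape(len(idx), -1)


def default_scenario_grid(n: int = 1000, reps: int = 150) -> list:
    """The 2 x 2 x 2 manipulated-parameter grid."""
    grid = []
    for complexity in ("complex", "simple"):
        for smoothness in ("smooth", "rough"):
            for missing in (0.0, 0.6):
                grid.append(SimScenario(complexity, smoothness, missing,
                                        n=n, reps=reps))
    return grid


# ---------------------------------------------------------------------------
# clinical fixture

@dataclass
class FixtureTruth:
    betas: np.ndarray
    latent: np.ndarray
    base_hazard: np.ndarray
    peri_effect: float


def generate_clinical_fixture(
    n_patients: int = 500,
    n_features: int = 8,
    horizon: int = 100,
    effector_betas=(2.0, 0.6, 0.3),
    peri_effect: float = 0.5,
    target_cumulative_incidence: float = 0.15,
    ar_coef: float = 0.9,
    sampling_periods=(1, 2, 3, 1, 7, 3, 2, 5),
    dropout: float = 0.1,
    censor_frac: float = 0.05,
    seed: int = 0,
):
    """Longitudinal synthetic post-transplant cohort with known effectors.

    Latent per-patient-feature AR(1) processes drive a proportional-hazards
    onset model: hazard_i(t) = h0(t) * exp(sum_k beta_k * s_ik(t) +
    peri_effect * 1{mismatched donor}).  The first len(effector_betas)
    features are effectors; the rest are dummies.  Observed values are the
    latent process plus measurement noise, sampled at feature-specific
    periods with additional random dropout.  h0 is a gamma-shaped curve
    peaking in the third to fourth post-transplant week, scaled so the
    expected cumulative incidence matches ``target_cumulative_incidence``.

    Returns (CohortDataset, FixtureTruth).
    """
    rng = np.random.default_rng(seed)
    betas = np.zeros(n_features)
    betas[: len(effector_betas)] = effector_betas

    # latent AR(1), stationary N(0,1)
    latent = np.empty((n_patients, n_features, horizon))
    latent[:, :, 0] = rng.normal(size=(n_patients, n_features))
    innov_sd = np.sqrt(1 - ar_coef**2)
    for d in range(1, horizon):
        latent[:, :, d] = (ar_coef * latent[:, :, d - 1]
                           + innov_sd * rng.normal(size=(n_patients, n_features)))

    peri_mismatch = rng.random(n_patients) < 0.5
    blood = rng.choice(["A", "B", "AB", "O"], n_patients)

    days = np.arange(1, horizon + 1)
    from scipy.stats import gamma as gamma_dist

    shape_curve = gamma_dist.pdf(days, a=6, scale=4.5)
    shape_curve /= shape_curve.sum()
    lin = np.einsum("ikd,k->id", latent, betas) + peri_effect * peri_mismatch[:, None]
    # scale h0 so mean cumulative hazard matches the target incidence
    mean_rr = np.exp(lin).mean()
    h0 = shape_curve * (-np.log(1 - target_cumulative_incidence)) / mean_rr

    hazard = np.clip(h0[None, :] * np.exp(lin), 0, 1)
    onset = np.full(n_patients, np.nan)
    for i in range(n_patients):
        u = rng.random(horizon)
        hit = np.nonzero(u < hazard[i])[0]
        if hit.size:
            onset[i] = hit[0] + 1

    last_observed = np.full(n_patients, horizon)
    censored = rng.random(n_patients) < censor_frac
    cens_day = rng.integers(30, horizon + 1, n_patients)
    for i in range(n_patients):
        if censored[i] and (np.isnan(onset[i]) or onset[i] > cens_day[i]):
            onset[i] = np.nan
            last_observed[i] = cens_day[i]

    # observed measurements: latent + noise at feature-specific periods
    periods = np.resize(np.asarray(sampling_periods, dtype=int), n_features)
    offsets = rng.integers(0, periods, (n_patients, n_features))
    mask = np.zeros((n_patients, n_features, horizon), dtype=bool)
    for k in range(n_features):
        sched = ((days[None, :] - 1 - offsets[:, [k]]) % periods[k]) == 0
        mask[:, k, :] = sched
    mask &= rng.random(mask.shape) >= dropout
    mask &= days[None, None, :] <= last_observed[:, None, None]
    noise = rng.normal(0, 0.2, latent.shape)
    feat_scale = rng.uniform(0.5, 30.0, n_features)
    feat_loc = rng.uniform(-5, 120, n_features)
    values = (latent + noise) * feat_scale[None, :, None] + feat_loc[None, :, None]
    values = np.where(mask, values, 0.0)

    patients = [f"p{i:04d}" for i in range(n_patients)]
    feats = [f"feat{k}" for k in range(n_features)]
    panel = DynamicPanel(values, mask, patients, feats, horizon)
    peri = pd.DataFrame(
        {
            "donor_match": np.where(peri_mismatch, "mismatched", "matched"),
            "blood_type": blood,
        },
        index=patients,
    )
    outcomes = pd.DataFrame(
        {
            "onset_day": pd.array(
                [int(o) if np.isfinite(o) else pd.NA for o in onset], dtype="Int64"
            ),
            "last_observed_day": last_observed.astype(int),
        },
        index=patients,
    )
    cohort = CohortDataset(panel, peri, outcomes)
    truth = FixtureTruth(betas, latent, h0, peri_effect)
    return cohort, truth
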
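"""Synthetic study populations: latent symptom factors, a 209-item
mixed-type questionnaire battery, demographics, adaptive IQ scores and
two-step task behavior generated by hybrid agents with configurable
planted effects.

The battery has an oblique three-factor structure.  Per-questionnaire
loading targets default to the anxious-depression / compulsivity /
social-withdrawal pattern (trait anxiety, apathy and depression dominate
factor 1; OCD, eating-disorder and alcohol items factor 2; social
anxiety factor 3), item responses arise from a graded-threshold model on
the loading-weighted factors, and each subject's model-based weight
declines linearly with their compulsivity factor score (default -17% per
SD) with additional age, IQ and gender effects on learning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import cat as cat_mod
from .rl import HybridParams
from .task import TaskConfig, simulate_session

# instrument tags -> (n_items, n_levels); schizotypy is binary (2 levels).
# The per-instrument split follows the published lengths of the named
# scales and sums to 209 analysis items; it is an explicit assumption of
# the generator, recorded here and in the manifest.
QUESTIONNAIRES = {
    "OCD": (18, 5),
    "depression": (20, 4),
    "trait_anxiety": (20, 4),
    "alcohol": (10, 5),
    "apathy": (18, 4),
    "eating": (26, 6),
    "impulsivity": (30, 4),
    "schizotypy": (43, 2),
    "social_anxiety": (24, 4),
}

# (mean, sd) of target pattern loadings per questionnaire on each factor
DEFAULT_LOADING_TARGETS = {
    "alcohol":        ((0.15, 0.05), (0.31, 0.07), (-0.23, 0.06)),
    "apathy":         ((0.44, 0.16), (-0.05, 0.13), (0.04, 0.13)),
    "depression":     ((0.38, 0.23), (0.14, 0.14), (0.04, 0.06)),
    "eating":         ((-0.05, 0.10), (0.36, 0.15), (0.06, 0.06)),
    "impulsivity":    ((0.24, 0.22), (0.15, 0.15), (-0.11, 0.11)),
    "OCD":            ((-0.05, 0.14), (0.50, 0.06), (0.09, 0.07)),
    "schizotypy":     ((0.16, 0.11), (0.18, 0.13), (0.08, 0.14)),
    "social_anxiety": ((0.04, 0.05), (0.08, 0.09), (0.57, 0.14)),
    "trait_anxiety":  ((0.52, 0.17), (0.15, 0.16), (0.13, 0.08)),
}

DEFAULT_PHI = np.array(
    [[1.00, 0.35, 0.30],
     [0.35, 1.00, 0.25],
     [0.30, 0.25, 1.00]]
)

# group prior over transformed hybrid parameters
# (alpha_logit, beta_stage2, beta_mb, beta_mf0, beta_mf1, beta_stick)
DEFAULT_PRIOR_MEAN = np.array([0.0, 1.2, 0.7, 0.3, 0.5, 0.15])
DEFAULT_PRIOR_SD = np.array([0.5, 0.3, 0.3, 0.2, 0.25, 0.2])

CATCH_EXPECTED = 1  # coded response to "please select 'A little'"


@dataclass
class PopulationConfig:
    """Study conditions for the synthetic population."""

    n_subjects: int = 1413
    phi: np.ndarray = field(default_factory=lambda: DEFAULT_PHI.copy())
    loading_targets: dict = field(default_factory=lambda: dict(DEFAULT_LOADING_TARGETS))
    effect_factor2_pct: float = -17.0   # % change in beta_MB per SD of factor 2
    age_mb_pct: float = -5.0            # % change in beta_MB per SD of age
    iq_mb_pct: float = 5.0              # % change in beta_MB per SD of IQ
    male_mb_pct: float = 4.0            # % change in beta_MB for males (+1)
    age_mf_pct: float = 4.0             # % change in beta_MF1 per SD of age
    mb_resid_sd: float = 0.15           # residual SD of beta_MB around its linear model
    prior_mean: np.ndarray = field(default_factory=lambda: DEFAULT_PRIOR_MEAN.copy())
    prior_sd: np.ndarray = field(default_factory=lambda: DEFAULT_PRIOR_SD.copy())
    age_mean: float = 33.0
    age_sd: float = 11.0
    age_range: tuple = (18, 76)
    p_male: float = 0.42
    # planted noncompliance rates (all zero by default: clean population)
    rate_missers: float = 0.0
    rate_mashers: float = 0.0
    rate_fast_rt: float = 0.0
    rate_catch_fail: float = 0.0
    rate_iq_zero: float = 0.0
    item_scale: float = 1.0             # shrink the battery proportionally (tests)
    seed: int = 0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, float)
        if self.phi.shape != (3, 3):
            raise ValueError("exactly 3 factors are supported")
        for q, rows in self.loading_targets.items():
            for m, s in rows:
                if not -1 <= m <= 1:
                    raise ValueError(f"loading target out of [-1, 1] for {q}")


@dataclass
class ItemBattery:
    """Battery manifest: item metadata plus the drawn true loadings."""

    items: pd.DataFrame  # item_id, questionnaire, n_levels, binary, reverse,
                         # lam1..lam3, is_catch

    @property
    def analysis_items(self) -> pd.DataFrame:
        return self.items[~self.items["is_catch"]]

    @property
    def n_items(self) -> int:
        return int((~self.items["is_catch"]).sum())

    def questionnaire_tags(self) -> pd.Series:
        d = self.analysis_items
        return pd.Series(d["questionnaire"].to_numpy(), index=d["item_id"])

    def binary_map(self) -> dict:
        d = self.analysis_items
        return dict(zip(d["item_id"], d["binary"]))

    def to_json(self) -> str:
        return self.items.to_json(orient="records")

    @classmethod
    def from_json(cls, s: str) -> "ItemBattery":
        import io

        df = pd.read_json(io.StringIO(s), orient="records")
        return cls(items=df[list(cls_columns())])


def cls_columns():
    return ["item_id", "questionnaire", "n_levels", "binary", "reverse",
            "lam1", "lam2", "lam3", "is_catch"]


@dataclass
class SubjectProfiles:
    subjects: pd.DataFrame        # indexed by subject_id
    responses: pd.DataFrame       # subjects x analysis items
    battery: ItemBattery
    catch_responses: pd.DataFrame # subject_id, response, expected

    def hybrid_params(self, subject_id) -> HybridParams:
        row = self.subjects.loc[subject_id]
        return HybridParams(
            alpha=row["alpha"], beta_stage2=row["beta_stage2"],
            beta_mb=row["beta_mb"], beta_mf0=row["beta_mf0"],
            beta_mf1=row["beta_mf1"], beta_stick=row["beta_stick"],
        )


def generate_battery_manifest(config: PopulationConfig | None = None) -> ItemBattery:
    """Build the item manifest and draw true pattern loadings.

    Items are partitioned over the nine instruments (schizotypy binary,
    everything else ordinal); one catch item is appended and excluded
    from analysis.  Loadings are drawn per item around the questionnaire's
    target mean/SD and rows are rescaled if the implied communality under
    the oblique factor model exceeds 0.9.
    """
    config = config or PopulationConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for q, (n_items, n_levels) in QUESTIONNAIRES.items():
        n = max(2, int(round(n_items * config.item_scale)))
        targets = config.loading_targets[q]
        for i in range(n):
            lam = np.array([rng.normal(m, s) for m, s in targets])
            h2 = float(lam @ config.phi @ lam)
            if h2 > 0.9:
                lam *= np.sqrt(0.9 / h2)
            rows.append(
                {
                    "item_id": f"{q}_{i+1:02d}",
                    "questionnaire": q,
                    "n_levels": n_levels,
                    "binary": n_levels == 2,
                    "reverse": False,
                    "lam1": lam[0], "lam2": lam[1], "lam3": lam[2],
                    "is_catch": False,
                }
            )
    rows.append(
        {"item_id": "catch_01", "questionnaire": "catch", "n_levels": 4,
         "binary": False, "reverse": False,
         "lam1": 0.0, "lam2": 0.0, "lam3": 0.0, "is_catch": True}
    )
    return ItemBattery(items=pd.DataFrame(rows)[cls_columns()])


def _thresholds(n_levels: int) -> np.ndarray:
    """Graded thresholds equally spaced on the latent scale in [-1.2, 1.2]."""
    if n_levels == 2:
        return np.array([0.0])
    return np.linspace(-1.2, 1.2, n_levels - 1)


def generate_population(config: PopulationConfig | None = None, seed=None) -> SubjectProfiles:
    """Sample a complete subject population.

    Oblique factor scores -> graded item responses; demographics in the
    reported ranges (ages 18-76, ~58% female); IQ measured by a 5-item
    adaptive test on a synthetic 26-item bank; each subject's hybrid-agent
    parameters drawn from the group prior with the model-based weight tied
    linearly to the compulsivity factor and to age, IQ and gender.
    """
    config = config or PopulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    battery = generate_battery_manifest(config)
    n = config.n_subjects
    ids = [f"sub{i:04d}" for i in range(n)]

    # latent factors
    Lchol = np.linalg.cholesky(config.phi)
    F = rng.standard_normal((n, 3)) @ Lchol.T

    # item responses
    d = battery.analysis_items
    lam = d[["lam1", "lam2", "lam3"]].to_numpy()
    h2 = np.einsum("ij,jk,ik->i", lam, config.phi, lam)
    ystar = F @ lam.T + rng.standard_normal((n, len(d))) * np.sqrt(np.clip(1 - h2, 0.05, 1))
    resp = np.zeros_like(ystar, dtype=int)
    for j, (_, item) in enumerate(d.iterrows()):
        resp[:, j] = np.searchsorted(_thresholds(int(item["n_levels"])), ystar[:, j])
    responses = pd.DataFrame(resp, index=ids, columns=d["item_id"].to_numpy())

    # demographics
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    gender = np.where(rng.random(n) < config.p_male, 1, -1)
    theta_iq = rng.standard_normal(n)

    # noncompliance assignment (mutually exclusive, in order)
    u = rng.random(n)
    kinds = np.full(n, "none", dtype=object)
    edges = np.cumsum([config.rate_missers, config.rate_mashers,
                       config.rate_fast_rt, config.rate_catch_fail,
                       config.rate_iq_zero])
    labels = ["misser", "masher", "fast_rt", "catch_fail", "iq_zero"]
    prev = 0.0
    for lab, edge in zip(labels, edges):
        kinds[(u >= prev) & (u < edge)] = lab
        prev = edge

    # adaptive IQ measurement
    bank = cat_mod.make_bank(seed=rng.integers(2**31))
    theta_hat = np.empty(n)
    n_correct = np.empty(n, dtype=int)
    for i in range(n):
        if kinds[i] == "iq_zero":
            sess = cat_mod.administer_cat(bank, responder=lambda row: 0,
                                          seed=rng.integers(2**31))
        else:
            sess = cat_mod.administer_cat(bank, true_theta=theta_iq[i],
                                          seed=rng.integers(2**31))
        theta_hat[i] = sess.theta
        n_correct[i] = sess.n_correct

    # hybrid parameters with planted effects
    z_age = (age - age.mean()) / age.std(ddof=0)
    z_iq = (theta_iq - theta_iq.mean()) / theta_iq.std(ddof=0)
    draws = config.prior_mean + rng.standard_normal((n, 6)) * config.prior_sd
    alpha = expit(draws[:, 0])
    mb_mean = config.prior_mean[2]
    mult = (
        1.0
        + config.effect_factor2_pct / 100.0 * F[:, 1]
        + config.age_mb_pct / 100.0 * z_age
        + config.iq_mb_pct / 100.0 * z_iq
        + config.male_mb_pct / 100.0 * gender
    )
    beta_mb = np.clip(mb_mean * mult + rng.normal(0, config.mb_resid_sd, n), 0.01, None)
    beta_mf1 = draws[:, 4] * (1.0 + config.age_mf_pct / 100.0 * z_age)

    subjects = pd.DataFrame(
        {
            "age": age, "iq": theta_iq, "iq_hat": theta_hat,
            "iq_n_correct": n_correct, "gender": gender,
            "f1": F[:, 0], "f2": F[:, 1], "f3": F[:, 2],
            "alpha": alpha, "beta_stage2": draws[:, 1], "beta_mb": beta_mb,
            "beta_mf0": draws[:, 3], "beta_mf1": beta_mf1,
            "beta_stick": draws[:, 5], "noncompliance": kinds,
        },
        index=pd.Index(ids, name="subject_id"),
    )

    catch = pd.DataFrame(
        {
            "subject_id": ids,
            "response": np.where(
                kinds == "catch_fail",
                (CATCH_EXPECTED + 1 + rng.integers(0, 3, n)) % 4,
                CATCH_EXPECTED,
            ),
            "expected": CATCH_EXPECTED,
        }
    )
    return SubjectProfiles(subjects=subjects, responses=responses,
                           battery=battery, catch_responses=catch)


def generate_behavior(
    profiles: SubjectProfiles,
    task_config: TaskConfig | None = None,
    seed=None,
):
    """One task session per subject, with planted noncompliant behavior.

    Missers skip ~15% of trials; mashers hold one key (both stages) with
    implausibly fast responses; fast_rt subjects respond normally but
    far faster than the sample.
    """
    task_config = task_config or TaskConfig()
    rng = np.random.default_rng(seed)
    sessions = []
    for sid, row in profiles.subjects.iterrows():
        kind = row["noncompliance"]
        params = profiles.hybrid_params(sid)
        miss = 0.15 if kind == "misser" else 0.0
        rt_mean = 0.12 if kind in ("masher", "fast_rt") else 0.7
        sess = simulate_session(
            params, task_config, seed=rng, subject_id=sid,
            miss_prob=miss, rt_mean=rt_mean,
        )
        if kind == "masher":
            key = int(rng.integers(0, 2))
            tr = sess.trials
            n_tr = len(tr)
            # hold one key on > 95% of responses at both stages
            hold = rng.random(n_tr) < 0.98
            tr.loc[hold, "c1"] = key
            tr.loc[hold, "c2"] = key
            tr["state"] = np.where(
                rng.random(n_tr) < task_config.p_common, tr["c1"], 1 - tr["c1"]
            )
            tr["transition"] = np.where(tr["state"] == tr["c1"], "common", "rare")
        sessions.append(sess)
    return sessions


def config_to_json(config: PopulationConfig) -> str:
    d = asdict(config)
    d["phi"] = np.asarray(config.phi).tolist()
    d["prior_mean"] = np.asarray(config.prior_mean).tolist()
    d["prior_sd"] = np.asarray(config.prior_sd).tolist()
    return json.dumps(d, indent=2)


def config_from_json(s: str) -> PopulationConfig:
    d = json.loads(s)
    d["phi"] = np.array(d["phi"])
    d["prior_mean"] = np.array(d["prior_mean"])
    d["prior_sd"] = np.array(d["prior_sd"])
    d["loading_targets"] = {
        q: tuple(tuple(x) for x in rows) for q, rows in d["loading_targets"].items()
    }
    d["age_range"] = tuple(d["age_range"])
    return PopulationConfig(**d)
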
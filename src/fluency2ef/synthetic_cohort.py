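"""Synthetic fluency cohort generator.

Emulates a cohort of healthy adults (default n = 230, ages 20-55) performing
the three timed fluency tasks, together with demographics and a 68-variable
executive-function score table, so that every pipeline stage can be exercised
without access to clinical data.

The generative model has three layers:

1. **Latent abilities.**  Five correlated standard-normal abilities per
   participant — flexibility, working memory, inhibition, attention, speed.
   In the ``paper_like`` scenario age lowers abilities (older participants
   produce fewer words), education raises them, and sex adds a small offset,
   creating the confounding structure the prediction engine must remove.

2. **Word production.**  A cluster-structured retrieval walk over the bundled
   toy taxonomy: the speaker stays in the current semantic cluster with a
   continuation probability (higher working memory -> longer clusters) and
   otherwise jumps to a fresh cluster, paying a switch latency penalty
   (lower flexibility -> larger penalty).  Inter-word pauses are lognormal,
   inflate linearly with time on task, and shrink with the speed ability.
   Words are sampled without replacement within a cluster, so repetitions
   only occur as deliberately injected repetition errors (hazard falls with
   inhibition and working memory).  The switching task alternates its two
   categories; occasional category errors emit an out-of-task word.

3. **EF scores.**  Each of the 68 battery variables loads on its test's
   domain ability plus a speed component, with Gaussian noise, and is then
   shifted/scaled and sign-flipped per the schema polarity (reaction-time
   variables: smaller is better).

Scenarios: ``null`` severs every coupling (abilities drive neither speech nor
scores, so features and targets are independent); ``paper_like`` is the
default full model; ``planted`` additionally rewrites designated targets as
noisy functions of realized fluency features — one target driven by a
semantic + latency combination *residualized against the four sum scores*
(signal invisible to the classical feature set by construction) and one
driven by a single feature (for importance-recovery checks).
`describe_truth` reports the exact planted couplings.

The toy vocabulary is far smaller than a real speaker's lexicon, so word
counts are scaled down (about 10-16 per task, not 25-35); every structural
relationship the analysis relies on is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_extraction
from .session_data import (
    Demographics,
    EFBattery,
    FluencySession,
    Token,
    default_battery_schema,
)
from .toy_resource import (
    CATEGORY_CLUSTERS,
    build_toy_embeddings,
    build_toy_taxonomy,
)

ABILITIES = ("flexibility", "working_memory", "inhibition", "attention", "speed")

_DOMAIN_ABILITY = {
    "cognitive flexibility": "flexibility",
    "working memory": "working_memory",
    "inhibition": "inhibition",
    "attention": "attention",
    "vigilance": "attention",
}

_TASK_CATEGORY = {"t1": "animals", "t2": "jobs"}


@dataclass
class PlantedCoupling:
    """One engineered target: which features carry its signal."""

    target: str
    features: list[str]
    weights: list[float]
    r_squared: float
    residualize_against_sums: bool


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort."""

    n_participants: int = 230
    seed: int = 0
    scenario: str = "paper_like"  # "null" | "paper_like" | "planted"
    duration: float = 120.0

    # latent abilities
    ability_corr: float = 0.3  # common off-diagonal correlation
    age_range: tuple[float, float] = (20.0, 55.0)
    age_slope: float = -0.35  # per SD of age, applied to every ability
    education_slope: float = 0.15
    sex_offset: float = 0.1
    education_probs: tuple[float, ...] = (8 / 230, 63 / 230, 69 / 230, 90 / 230)
    male_fraction: float = 92 / 230

    # word production
    base_pause_mu: float = math.log(4.0)  # lognormal median pause, seconds
    pause_sigma: float = 0.45
    switch_penalty: float = 0.35  # added to mu on a cluster switch
    flexibility_penalty_relief: float = 0.15
    speed_pause_coef: float = 0.15  # faster participants pause less
    session_state_sd: float = 0.22  # per-session latency intercept (day form)
    slowing: float = 0.6  # mu inflation from task start to end
    continuation_base: float = 0.68
    continuation_wm_coef: float = 0.08
    word_duration: tuple[float, float] = (0.45, 0.85)
    repetition_hazard: float = 0.035
    repetition_ability_coef: float = 0.015  # relief from inhibition + wm
    category_hazard: float = 0.03
    category_flex_coef: float = 0.012
    switch_compliance: float = 0.8  # prob. of alternating categories in t3
    compliance_flex_coef: float = 0.05

    # EF scores: loadings vs noise chosen so that only a moderate subset of
    # variables is predictable from speech behaviour, strongest for the
    # speed-dominated reaction-time variables
    domain_loading: float = 0.55
    speed_loading: float = 0.45
    rt_speed_loading: float = 0.75
    noise_sd: float = 1.25

    # planted scenario
    planted_target: str = "spm_correct"
    planted_features: tuple[str, ...] = (
        "sem_seq_tax_t1", "sem_cum_tax_t2", "sem_cum_emb_t3",
        "lat_mean_t1", "lat_q1_t3",
    )
    planted_r2: float = 0.45
    planted_solo_target: str = "stroop_signature"
    planted_solo_feature: str = "sem_cum_tax_t1"
    planted_solo_r2: float = 0.5

    def __post_init__(self) -> None:
        if self.scenario not in ("null", "paper_like", "planted"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.continuation_base < 1:
            raise ValueError("continuation_base must be in (0, 1)")


@dataclass
class Cohort:
    """Everything one simulated study yields."""

    sessions: list[FluencySession]
    demographics: pd.DataFrame
    battery: EFBattery
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Latent layer
# ---------------------------------------------------------------------------

def _draw_abilities(
    config: GeneratorConfig, demo: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    k = len(ABILITIES)
    corr = np.full((k, k), config.ability_corr)
    np.fill_diagonal(corr, 1.0)
    theta = rng.multivariate_normal(np.zeros(k), corr, size=len(demo),
                                    method="cholesky")
    if config.scenario != "null":
        age_z = (demo["age"] - demo["age"].mean()) / demo["age"].std(ddof=0)
        edu_z = (demo["education"] - demo["education"].mean()) / \
            demo["education"].std(ddof=0)
        shift = (
            config.age_slope * age_z.to_numpy()[:, None]
            + config.education_slope * edu_z.to_numpy()[:, None]
            + config.sex_offset * demo["sex"].to_numpy()[:, None]
        )
        theta = theta + shift
    return pd.DataFrame(theta, index=demo.index, columns=ABILITIES)


def _draw_demographics(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_participants
    pids = [f"p{i:04d}" for i in range(1, n + 1)]
    lo, hi = config.age_range
    demo = pd.DataFrame(
        {
            "sex": (rng.random(n) < config.male_fraction).astype(int),
            "age": np.round(rng.uniform(lo, hi, size=n), 1),
            "education": rng.choice(
                [1, 2, 3, 4], size=n, p=np.asarray(config.education_probs)
            ),
        },
        index=pd.Index(pids, name="participant_id"),
    )
    for pid, row in demo.iterrows():  # invariant check via the domain type
        Demographics(pid, int(row["sex"]), float(row["age"]), int(row["education"]))
    return demo


# ---------------------------------------------------------------------------
# Word production
# ---------------------------------------------------------------------------

def _simulate_task(
    config: GeneratorConfig,
    task_id: str,
    theta: pd.Series,
    rng: np.random.Generator,
) -> list[Token]:
    """Cluster-structured retrieval walk for one task."""
    null = config.scenario == "null"
    flex = 0.0 if null else float(theta["flexibility"])
    wm = 0.0 if null else float(theta["working_memory"])
    inhib = 0.0 if null else float(theta["inhibition"])
    speed = 0.0 if null else float(theta["speed"])

    if task_id == "t3":
        categories = ["sports", "fruits"]
    else:
        categories = [_TASK_CATEGORY[task_id]]

    # Remaining words per (category, cluster); sampled without replacement.
    remaining = {
        cat: {cl: list(words) for cl, words in CATEGORY_CLUSTERS[cat].items()}
        for cat in categories
    }
    produced: list[str] = []
    tokens: list[Token] = []
    cat_idx = 0
    current_cluster: dict[str, str | None] = {cat: None for cat in categories}

    p_cont = float(np.clip(config.continuation_base + config.continuation_wm_coef * wm,
                           0.05, 0.95))
    rep_hazard = float(np.clip(
        config.repetition_hazard - config.repetition_ability_coef * (inhib + wm),
        0.0, 0.5,
    ))
    cat_hazard = float(np.clip(
        config.category_hazard - config.category_flex_coef * flex, 0.0, 0.5,
    )) if task_id == "t3" else 0.0

    off_task_words = [
        w
        for cat, clusters in CATEGORY_CLUSTERS.items()
        if cat not in categories
        for words in clusters.values()
        for w in words
    ]

    # Session-level state (daily form, microphone distance, warm-up): a
    # random pause intercept shared by all words of this session.  Keeps
    # latency features an imperfect, realistic measure of the speed ability.
    session_mu = float(rng.normal(scale=config.session_state_sd))

    t = float(rng.uniform(0.8, 2.5))  # initial retrieval latency
    first = True
    while True:
        category = categories[cat_idx % len(categories)]
        pools = remaining[category]
        nonempty = [cl for cl, words in pools.items() if words]

        is_switch = False
        word: str | None = None
        code = "correct"

        if task_id == "t3":
            # Alternate categories with flexibility-dependent compliance;
            # non-compliance keeps the current category for one more word.
            compliance = float(np.clip(
                config.switch_compliance + config.compliance_flex_coef * flex,
                0.05, 1.0,
            ))
            if rng.random() < compliance:
                cat_idx += 1
        if rng.random() < rep_hazard and produced:
            word = produced[int(rng.integers(len(produced)))]
            code = "repetition_error"
        elif cat_hazard and rng.random() < cat_hazard:
            word = off_task_words[int(rng.integers(len(off_task_words)))]
            code = "category_error"
        else:
            if not nonempty:
                break  # category exhausted
            cluster = current_cluster[category]
            stay = (
                cluster is not None
                and pools.get(cluster)
                and rng.random() < p_cont
            )
            if not stay:
                choices = [cl for cl in nonempty if cl != cluster] or nonempty
                cluster = choices[int(rng.integers(len(choices)))]
                is_switch = True
            current_cluster[category] = cluster
            pool = pools[cluster]
            word = pool.pop(int(rng.integers(len(pool))))
            produced.append(word)

        if not first:
            mu = (
                config.base_pause_mu
                + session_mu
                + config.slowing * (t / config.duration)
                - config.speed_pause_coef * speed
            )
            if is_switch:
                mu += max(
                    0.0,
                    config.switch_penalty - config.flexibility_penalty_relief * flex,
                )
            t += float(rng.lognormal(mu, config.pause_sigma))
        first = False

        dur = float(rng.uniform(*config.word_duration))
        if t + dur > config.duration:
            break
        tokens.append(
            Token(
                word=word,
                onset=round(t, 3),
                offset=round(t + dur, 3),
                code=code,
                category=category if task_id == "t3" else None,
            )
        )
        t += dur
    return tokens


# ---------------------------------------------------------------------------
# EF scores
# ---------------------------------------------------------------------------

def _loading_matrix(config: GeneratorConfig, schema: pd.DataFrame) -> np.ndarray:
    """(68 x 5) ability loadings; zero everywhere in the null scenario."""
    L = np.zeros((len(schema), len(ABILITIES)))
    if config.scenario == "null":
        return L
    for i, row in enumerate(schema.itertuples()):
        ability = _DOMAIN_ABILITY[row.domain]
        speed_dominated = row.variable.endswith(("rt_mean", "rt_sd"))
        if speed_dominated:
            L[i, ABILITIES.index("speed")] = config.rt_speed_loading
            L[i, ABILITIES.index(ability)] = 0.2
        else:
            L[i, ABILITIES.index(ability)] = config.domain_loading
            L[i, ABILITIES.index("speed")] = config.speed_loading * 0.4
    return L


def _score_battery(
    config: GeneratorConfig,
    schema: pd.DataFrame,
    abilities: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    L = _loading_matrix(config, schema)
    if L.shape != (len(schema), len(ABILITIES)):
        raise ValueError(f"loading matrix shape {L.shape}, expected "
                         f"({len(schema)}, {len(ABILITIES)})")
    latent = abilities.to_numpy() @ L.T
    noise = rng.normal(scale=config.noise_sd, size=latent.shape)
    y = latent + noise
    sign = np.where(schema["larger_is_better"].to_numpy(), 1.0, -1.0)
    scores = 50.0 + 10.0 * sign * y  # clinical-looking scale, polarity applied
    return pd.DataFrame(np.round(scores, 3), index=abilities.index,
                        columns=list(schema["variable"]))


# ---------------------------------------------------------------------------
# Planted targets
# ---------------------------------------------------------------------------

def _zscore_imputed(col: pd.Series) -> np.ndarray:
    x = col.to_numpy(dtype=float)
    med = np.nanmedian(x)
    x = np.where(np.isnan(x), 0.0 if math.isnan(med) else med, x)
    sd = x.std()
    return (x - x.mean()) / (sd if sd else 1.0)


def _plant_targets(
    config: GeneratorConfig,
    cohort: Cohort,
    rng: np.random.Generator,
) -> list[PlantedCoupling]:
    """Rewrite designated EF targets as noisy functions of realized features."""
    taxonomy = build_toy_taxonomy()
    embeddings = build_toy_embeddings()
    feats = feature_extraction.build_feature_table(
        cohort.sessions, taxonomy, embeddings
    ).loc[cohort.battery.scores.index]

    for name in (config.planted_target, config.planted_solo_target):
        if name not in cohort.battery.scores.columns:
            raise ValueError(f"planted target {name!r} is not a battery variable")

    couplings: list[PlantedCoupling] = []

    # Target 1: combined semantic + latency signal, orthogonalized to the sum
    # scores so the classical feature set carries none of it.
    Z = np.column_stack([_zscore_imputed(feats[f]) for f in config.planted_features])
    S = np.column_stack(
        [np.ones(len(feats))]
        + [_zscore_imputed(feats[f]) for f in feature_extraction.CLASSICAL_FEATURES]
    )
    beta, *_ = np.linalg.lstsq(S, Z, rcond=None)
    resid = Z - S @ beta
    weights = np.ones(resid.shape[1])
    signal = resid @ weights
    signal = (signal - signal.mean()) / signal.std()
    noise = rng.standard_normal(len(signal))
    y = math.sqrt(config.planted_r2) * signal + math.sqrt(1 - config.planted_r2) * noise
    cohort.battery.scores[config.planted_target] = np.round(50.0 + 10.0 * y, 3)
    couplings.append(
        PlantedCoupling(
            target=config.planted_target,
            features=list(config.planted_features),
            weights=list(weights),
            r_squared=config.planted_r2,
            residualize_against_sums=True,
        )
    )

    # Target 2: one feature carries the whole signal (importance recovery).
    solo = _zscore_imputed(feats[config.planted_solo_feature])
    noise = rng.standard_normal(len(solo))
    y = math.sqrt(config.planted_solo_r2) * solo \
        + math.sqrt(1 - config.planted_solo_r2) * noise
    cohort.battery.scores[config.planted_solo_target] = np.round(50.0 + 10.0 * y, 3)
    couplings.append(
        PlantedCoupling(
            target=config.planted_solo_target,
            features=[config.planted_solo_feature],
            weights=[1.0],
            r_squared=config.planted_solo_r2,
            residualize_against_sums=False,
        )
    )
    return couplings


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate sessions, demographics and EF scores; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    demo = _draw_demographics(config, rng)
    abilities = _draw_abilities(config, demo, rng)
    schema = default_battery_schema()

    sessions: list[FluencySession] = []
    for pid in demo.index:
        for task_id in ("t1", "t2", "t3"):
            tokens = _simulate_task(config, task_id, abilities.loc[pid], rng)
            sessions.append(
                FluencySession(
                    participant_id=pid, task_id=task_id,
                    tokens=tokens, duration=config.duration,
                )
            )

    scores = _score_battery(config, schema, abilities, rng)
    cohort = Cohort(
        sessions=sessions,
        demographics=demo,
        battery=EFBattery(scores=scores, schema=schema),
        truth=describe_truth(config),
    )
    if config.scenario == "planted":
        couplings = _plant_targets(config, cohort, rng)
        cohort.truth["couplings"] = [vars(c) for c in couplings]
    return cohort


def describe_truth(config: GeneratorConfig) -> dict:
    """Ground-truth record of every planted coupling in the configuration."""
    truth: dict = {"scenario": config.scenario, "couplings": []}
    if config.scenario == "null":
        return truth
    truth["age_slope"] = config.age_slope
    truth["education_slope"] = config.education_slope
    truth["sex_offset"] = config.sex_offset
    if config.scenario == "planted":
        truth["couplings"] = [
            {
                "target": config.planted_target,
                "features": list(config.planted_features),
                "r_squared": config.planted_r2,
                "residualize_against_sums": True,
            },
            {
                "target": config.planted_solo_target,
                "features": [config.planted_solo_feature],
                "r_squared": config.planted_solo_r2,
                "residualize_against_sums": False,
            },
        ]
    return truth


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write transcripts, demographics, EF scores and truth.json to a directory."""
    import json

    from .session_data import write_demographics, write_ef_scores, write_sessions

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": directory / "sessions.tsv",
        "demographics": directory / "demographics.tsv",
        "ef_scores": directory / "ef_scores.tsv",
        "truth": directory / "truth.json",
    }
    write_sessions(cohort.sessions, paths["sessions"])
    write_demographics(cohort.demographics, paths["demographics"])
    write_ef_scores(cohort.battery, paths["ef_scores"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    return paths
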
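"""Per-participant fluency feature extraction.

From each participant's three coded sessions the full 43-feature set is
computed: sum scores and the switch coefficient, error counts, speech-latency
profiles over four 30-second task intervals, and semantic relatedness means
under two backends (taxonomy path similarity and embedding cosine).  The
classical clinical evaluation keeps only the four sum-score features.

Conventions (all exposed as switches where noted):

* Sum scores count only tokens coded ``correct``.
* Pauses are offset-to-onset gaps between neighbouring tokens, over *all*
  tokens regardless of code (errors occupy speaking time); a pause belongs to
  the 30-s interval containing its start.  The latency before the first word
  is not a pause.
* Semantic means use correct-coded tokens only.  Sequential = mean similarity
  over consecutive pairs in production order; cumulative = mean over all
  unordered pairs.  A pair whose similarity is undefined (word missing from
  the backend) is deleted; its neighbours are *not* spliced together.
* A feature whose definition cannot be evaluated (missing task, no valid
  pair, zero denominator) is missing (NaN), never imputed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .semantic_resource import EmbeddingTable, Taxonomy
from .session_data import TASK_CATEGORIES, TASK_IDS, FluencySession

_TASKS = ("t1", "t2", "t3")

#: Canonical order of the 43 fluency features.
FEATURE_NAMES: list[str] = (
    ["sum_t1", "sum_t2", "sum_t3", "sum_total", "switch_coef",
     "err_rep_t1", "err_rep_t2", "err_rep_t3", "err_cat_t3"]
    + [f"lat_mean_{t}" for t in _TASKS]
    + [f"lat_q{q}_{t}" for t in _TASKS for q in (1, 2, 3, 4)]
    + [f"lat_diff_{t}" for t in _TASKS]
    + [f"sem_seq_tax_{t}" for t in _TASKS]
    + [f"sem_cum_tax_{t}" for t in _TASKS]
    + ["sem_seq_tax_cat1_t3", "sem_seq_tax_cat2_t3"]
    + [f"sem_seq_emb_{t}" for t in _TASKS]
    + [f"sem_cum_emb_{t}" for t in _TASKS]
    + ["sem_seq_emb_cat1_t3", "sem_seq_emb_cat2_t3"]
)
assert len(FEATURE_NAMES) == 43

#: The classical clinical evaluation: sum scores only.
CLASSICAL_FEATURES: list[str] = ["sum_t1", "sum_t2", "sum_t3", "sum_total"]

#: Human-readable description of every feature (sidecar schema).
FEATURE_DESCRIPTIONS: dict[str, str] = {
    **{f"sum_{t}": f"Correct words produced in task {t}" for t in _TASKS},
    "sum_total": "Correct words summed over the three tasks",
    "switch_coef": "sum_t3 / ((sum_t1 + sum_t2) / 2): switching vs simple output",
    **{f"err_rep_{t}": f"Repetition errors in task {t}" for t in _TASKS},
    "err_cat_t3": "Category errors in the switching task",
    **{f"lat_mean_{t}": f"Mean inter-word pause (s) in task {t}" for t in _TASKS},
    **{
        f"lat_q{q}_{t}": f"Mean pause (s) in task {t}, interval {(q - 1) * 30}-{q * 30} s"
        for t in _TASKS for q in (1, 2, 3, 4)
    },
    **{f"lat_diff_{t}": f"Pause progression i4 - i1 (s) in task {t}" for t in _TASKS},
    **{f"sem_seq_tax_{t}": f"Mean taxonomy similarity, consecutive pairs, task {t}" for t in _TASKS},
    **{f"sem_cum_tax_{t}": f"Mean taxonomy similarity, all pairs, task {t}" for t in _TASKS},
    "sem_seq_tax_cat1_t3": "Taxonomy sequential mean within category 1 (sports), t3",
    "sem_seq_tax_cat2_t3": "Taxonomy sequential mean within category 2 (fruits), t3",
    **{f"sem_seq_emb_{t}": f"Mean embedding cosine, consecutive pairs, task {t}" for t in _TASKS},
    **{f"sem_cum_emb_{t}": f"Mean embedding cosine, all pairs, task {t}" for t in _TASKS},
    "sem_seq_emb_cat1_t3": "Embedding sequential mean within category 1 (sports), t3",
    "sem_seq_emb_cat2_t3": "Embedding sequential mean within category 2 (fruits), t3",
}
assert set(FEATURE_DESCRIPTIONS) == set(FEATURE_NAMES)


# ---------------------------------------------------------------------------
# Sum scores and errors
# ---------------------------------------------------------------------------

def extract_sum_scores(sessions: dict[str, FluencySession]) -> dict[str, float]:
    """Sum of correct tokens per task, total, and the switch coefficient.

    The switch coefficient relates switching-task output to simple-task
    output: ``sum_t3 / ((sum_t1 + sum_t2) / 2)``; undefined when a task is
    missing or ``sum_t1 + sum_t2 = 0``.
    """
    out: dict[str, float] = {}
    for t in _TASKS:
        s = sessions.get(t)
        out[f"sum_{t}"] = (
            float(sum(1 for tok in s.tokens if tok.code == "correct"))
            if s is not None else math.nan
        )
    sums = [out[f"sum_{t}"] for t in _TASKS]
    out["sum_total"] = float(np.sum(sums)) if not any(map(math.isnan, sums)) else math.nan
    s1, s2, s3 = sums
    if any(map(math.isnan, sums)) or (s1 + s2) == 0:
        out["switch_coef"] = math.nan
    else:
        out["switch_coef"] = s3 / ((s1 + s2) / 2.0)
    return out


def extract_error_counts(sessions: dict[str, FluencySession]) -> dict[str, float]:
    """Repetition-error counts per task and category errors in t3."""
    out: dict[str, float] = {}
    for t in _TASKS:
        s = sessions.get(t)
        out[f"err_rep_{t}"] = (
            float(sum(1 for tok in s.tokens if tok.code == "repetition_error"))
            if s is not None else math.nan
        )
    s3 = sessions.get("t3")
    out["err_cat_t3"] = (
        float(sum(1 for tok in s3.tokens if tok.code == "category_error"))
        if s3 is not None else math.nan
    )
    return out


# ---------------------------------------------------------------------------
# Latencies
# ---------------------------------------------------------------------------

@dataclass
class LatencyProfile:
    """Inter-word pauses of one session and their interval summary.

    ``intervals[q]`` (q = 0..3) is the mean pause starting in task seconds
    [30q, 30(q+1)); NaN when no pause starts there.  ``difference`` is the
    late-minus-early progression i4 - i1.
    """

    pauses: list[float] = field(default_factory=list)
    starts: list[float] = field(default_factory=list)
    intervals: list[float] = field(default_factory=lambda: [math.nan] * 4)
    mean: float = math.nan
    difference: float = math.nan


def extract_latencies(
    session: FluencySession, tokens: str = "all"
) -> LatencyProfile:
    """Pause profile of one session.

    Parameters
    ----------
    tokens
        ``"all"`` (default) computes gaps over every token regardless of
        code — errors occupy speaking time; ``"correct"`` restricts to
        correct-coded tokens.
    """
    toks = session.tokens if tokens == "all" else [
        t for t in session.tokens if t.code == "correct"
    ]
    profile = LatencyProfile()
    per_interval: list[list[float]] = [[], [], [], []]
    for prev, nxt in zip(toks, toks[1:]):
        gap = nxt.onset - prev.offset
        start = prev.offset
        profile.pauses.append(gap)
        profile.starts.append(start)
        q = min(3, int(start // 30.0))
        per_interval[q].append(gap)
    if profile.pauses:
        profile.mean = float(np.mean(profile.pauses))
    profile.intervals = [
        float(np.mean(g)) if g else math.nan for g in per_interval
    ]
    i1, i4 = profile.intervals[0], profile.intervals[3]
    if not (math.isnan(i1) or math.isnan(i4)):
        profile.difference = i4 - i1
    return profile


# ---------------------------------------------------------------------------
# Semantic relatedness means
# ---------------------------------------------------------------------------

def _mean_defined(values: list[float | None]) -> float:
    kept = [v for v in values if v is not None]
    return float(np.mean(kept)) if kept else math.nan


def extract_semantic_means(
    session: FluencySession,
    backend: Taxonomy | EmbeddingTable,
    tokens: str = "correct",
) -> dict[str, float]:
    """Sequential and cumulative relatedness means for one session.

    Returns keys ``sequential``, ``cumulative`` and, for the switching task,
    ``sequential_cat1`` / ``sequential_cat2`` (consecutive pairs whose two
    tokens share the category label; category 1/2 follow the task's declared
    order, e.g. sports then fruits).
    """
    toks = [t for t in session.tokens if t.code == "correct"] if tokens == "correct" \
        else list(session.tokens)
    words = [t.word for t in toks]

    seq = [backend.word_similarity(a, b) for a, b in zip(words, words[1:])]
    cum = [
        backend.word_similarity(words[i], words[j])
        for i in range(len(words)) for j in range(i + 1, len(words))
    ]
    out = {"sequential": _mean_defined(seq), "cumulative": _mean_defined(cum)}

    if session.task_id == "t3":
        cats = TASK_CATEGORIES["t3"]
        for k, cat in enumerate(cats, start=1):
            within = [
                backend.word_similarity(a.word, b.word)
                for a, b in zip(toks, toks[1:])
                if a.category == cat and b.category == cat
            ]
            out[f"sequential_cat{k}"] = _mean_defined(within)
    return out


# ---------------------------------------------------------------------------
# Full table
# ---------------------------------------------------------------------------

def extract_participant_features(
    sessions: dict[str, FluencySession],
    taxonomy: Taxonomy | None = None,
    embeddings: EmbeddingTable | None = None,
    pause_tokens: str = "all",
    semantic_tokens: str = "correct",
) -> dict[str, float]:
    """All 43 features for one participant's session dict (task_id -> session)."""
    feats: dict[str, float] = dict.fromkeys(FEATURE_NAMES, math.nan)
    feats.update(extract_sum_scores(sessions))
    feats.update(extract_error_counts(sessions))
    for t in _TASKS:
        s = sessions.get(t)
        if s is None:
            continue
        prof = extract_latencies(s, tokens=pause_tokens)
        feats[f"lat_mean_{t}"] = prof.mean
        for q in range(4):
            feats[f"lat_q{q + 1}_{t}"] = prof.intervals[q]
        feats[f"lat_diff_{t}"] = prof.difference
        for tag, backend in (("tax", taxonomy), ("emb", embeddings)):
            if backend is None:
                continue
            sem = extract_semantic_means(s, backend, tokens=semantic_tokens)
            feats[f"sem_seq_{tag}_{t}"] = sem["sequential"]
            feats[f"sem_cum_{tag}_{t}"] = sem["cumulative"]
            if t == "t3":
                feats[f"sem_seq_{tag}_cat1_t3"] = sem["sequential_cat1"]
                feats[f"sem_seq_{tag}_cat2_t3"] = sem["sequential_cat2"]
    return feats


def build_feature_table(
    sessions: list[FluencySession],
    taxonomy: Taxonomy | None = None,
    embeddings: EmbeddingTable | None = None,
    pause_tokens: str = "all",
    semantic_tokens: str = "correct",
) -> pd.DataFrame:
    """Participants x 43 feature table (index: participant_id; NaN = missing)."""
    by_participant: dict[str, dict[str, FluencySession]] = {}
    for s in sessions:
        slot = by_participant.setdefault(s.participant_id, {})
        if s.task_id in slot:
            raise ValueError(
                f"duplicate session for participant {s.participant_id}, task {s.task_id}"
            )
        slot[s.task_id] = s
    rows = {
        pid: extract_participant_features(
            task_sessions, taxonomy, embeddings,
            pause_tokens=pause_tokens, semantic_tokens=semantic_tokens,
        )
        for pid, task_sessions in sorted(by_participant.items())
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_NAMES)
    table.index.name = "participant_id"
    return table


def classical_subset(table: pd.DataFrame) -> pd.DataFrame:
    """The four sum-score columns (the standard clinical evaluation)."""
    return table[CLASSICAL_FEATURES]


def feature_schema() -> dict[str, str]:
    """Sidecar schema: canonical feature name -> description."""
    return dict(FEATURE_DESCRIPTIONS)
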
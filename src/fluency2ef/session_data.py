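"""Data model and I/O for coded semantic-verbal-fluency sessions.

A fluency session is one participant performing one timed (default 120 s)
word-production task: two simple tasks (t1 = animals, t2 = jobs) and one
switching task (t3 = alternating sports/fruits).  Tokens arrive already
transcribed and manually coded as ``correct``, ``repetition_error`` or
``category_error``; category errors only exist in the switching task.

The transcript dialect is a UTF-8 TSV with columns
``participant_id  task  word  onset_s  offset_s  code  category``.
A minimal Praat TextGrid reader (interval tiers, long or short format) is
provided for importing time-aligned transcriptions; coding happens downstream.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

TASK_IDS = ("t1", "t2", "t3")
TASK_CATEGORIES: dict[str, tuple[str, ...]] = {
    "t1": ("animals",),
    "t2": ("jobs",),
    "t3": ("sports", "fruits"),
}
CODES = ("correct", "repetition_error", "category_error")

TRANSCRIPT_COLUMNS = [
    "participant_id", "task", "word", "onset_s", "offset_s", "code", "category",
]


class ValidationError(ValueError):
    """A transcript or score table violates the session data contract."""


def normalize_word(word: str) -> str:
    """Trim, lower-case and NFC-normalize a word; compounds are kept verbatim."""
    return unicodedata.normalize("NFC", word.strip().lower())


@dataclass(frozen=True)
class Token:
    """One produced word with its time interval and manual code."""

    word: str
    onset: float
    offset: float
    code: str = "correct"
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.word:
            raise ValidationError("token word must be non-empty")
        if not (0.0 <= self.onset <= self.offset):
            raise ValidationError(
                f"token {self.word!r}: require 0 <= onset <= offset, "
                f"got onset={self.onset}, offset={self.offset}"
            )
        if self.code not in CODES:
            raise ValidationError(f"unknown code {self.code!r} for token {self.word!r}")


@dataclass
class FluencySession:
    """One participant x one task: ordered coded tokens with timings."""

    participant_id: str
    task_id: str
    tokens: list[Token] = field(default_factory=list)
    duration: float = 120.0

    def __post_init__(self) -> None:
        if self.task_id not in TASK_IDS:
            raise ValidationError(f"unknown task_id {self.task_id!r}")
        self.tokens = sorted(self.tokens, key=lambda t: t.onset)
        self._validate()

    @property
    def categories(self) -> tuple[str, ...]:
        return TASK_CATEGORIES[self.task_id]

    def _validate(self) -> None:
        prev: Token | None = None
        for tok in self.tokens:
            if tok.offset > self.duration:
                raise ValidationError(
                    f"{self.participant_id}/{self.task_id}: token {tok.word!r} "
                    f"ends at {tok.offset}s, past the {self.duration}s task"
                )
            if prev is not None and tok.onset < prev.offset:
                raise ValidationError(
                    f"{self.participant_id}/{self.task_id}: tokens {prev.word!r} "
                    f"and {tok.word!r} overlap in time"
                )
            if tok.code == "category_error" and self.task_id != "t3":
                raise ValidationError(
                    f"{self.participant_id}/{self.task_id}: category_error code "
                    "is only defined for the switching task t3"
                )
            if self.task_id == "t3" and tok.category is None:
                raise ValidationError(
                    f"{self.participant_id}/t3: token {tok.word!r} has no "
                    "category label (required in the switching task)"
                )
            prev = tok


@dataclass(frozen=True)
class Demographics:
    """Participant-level confound record: sex, age, ordinal education (1-4)."""

    participant_id: str
    sex: int
    age: float
    education: int

    def __post_init__(self) -> None:
        if self.education not in (1, 2, 3, 4):
            raise ValidationError(
                f"{self.participant_id}: education must be 1-4, got {self.education}"
            )


# ---------------------------------------------------------------------------
# EF battery schema
# ---------------------------------------------------------------------------

DOMAINS = (
    "cognitive flexibility", "working memory", "inhibition", "attention", "vigilance",
)

# 14 tests -> (domain, number of extracted variables).  The real battery's full
# variable list lives in an unavailable supplement, so the default registry
# distributes the 68 variables over the named tests with documented invented
# variable names; counts are configurable via a registry TSV.
DEFAULT_TEST_REGISTRY: dict[str, tuple[str, int]] = {
    "TMT": ("cognitive flexibility", 5),
    "SPM": ("cognitive flexibility", 4),
    "WCST": ("cognitive flexibility", 6),
    "TOL": ("cognitive flexibility", 4),
    "SWITCH": ("cognitive flexibility", 5),
    "NBN": ("working memory", 5),
    "NVLT": ("working memory", 4),
    "CORSI": ("working memory", 4),
    "STOP": ("inhibition", 5),
    "SIMON": ("inhibition", 4),
    "STROOP": ("inhibition", 5),
    "WAF_G": ("attention", 6),
    "WAF_R": ("attention", 6),
    "CLOCK": ("vigilance", 5),
}

# Variable-name stems, cycled per test; reaction-time and error variables have
# polarity smaller-is-better, correct/signature variables larger-is-better.
_VARIABLE_STEMS = [
    ("rt_mean", False),
    ("rt_sd", False),
    ("errors", False),
    ("correct", True),
    ("signature", True),
    ("omissions", False),
]


def default_battery_schema() -> pd.DataFrame:
    """Return the default 68-variable schema: variable -> test, domain, polarity.

    ``polarity`` is True when larger values mean better performance.
    """
    rows = []
    for test, (domain, count) in DEFAULT_TEST_REGISTRY.items():
        for i in range(count):
            stem, larger_better = _VARIABLE_STEMS[i % len(_VARIABLE_STEMS)]
            rows.append(
                {
                    "variable": f"{test.lower()}_{stem}",
                    "test": test,
                    "domain": domain,
                    "larger_is_better": larger_better,
                }
            )
    schema = pd.DataFrame(rows)
    assert len(schema) == 68, "default registry must yield 68 variables"
    assert schema["variable"].is_unique
    return schema


def load_battery_schema(path: str | Path) -> pd.DataFrame:
    """Load a battery schema TSV (columns: variable, test, domain, larger_is_better)."""
    schema = pd.read_csv(path, sep="\t")
    required = {"variable", "test", "domain", "larger_is_better"}
    missing = required - set(schema.columns)
    if missing:
        raise ValidationError(f"battery schema missing columns: {sorted(missing)}")
    if not schema["variable"].is_unique:
        raise ValidationError("battery schema has duplicate variable names")
    bad = set(schema["domain"]) - set(DOMAINS)
    if bad:
        raise ValidationError(f"unknown EF domains in schema: {sorted(bad)}")
    schema["larger_is_better"] = schema["larger_is_better"].astype(bool)
    return schema


@dataclass
class EFBattery:
    """Wide table of executive-function test scores plus its variable schema."""

    scores: pd.DataFrame  # index: participant_id, columns: variables
    schema: pd.DataFrame  # variable -> test, domain, larger_is_better

    def __post_init__(self) -> None:
        schema_vars = list(self.schema["variable"])
        missing = [v for v in schema_vars if v not in self.scores.columns]
        if missing:
            raise ValidationError(f"EF table missing schema variables: {missing}")
        unknown = [c for c in self.scores.columns if c not in schema_vars]
        if unknown:
            raise ValidationError(f"EF table has unregistered columns: {unknown}")
        self.scores = self.scores[schema_vars]

    @property
    def variables(self) -> list[str]:
        return list(self.schema["variable"])

    def domain_of(self, variable: str) -> str:
        row = self.schema.loc[self.schema["variable"] == variable]
        return str(row["domain"].iloc[0])

    def test_of(self, variable: str) -> str:
        row = self.schema.loc[self.schema["variable"] == variable]
        return str(row["test"].iloc[0])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_sessions(path: str | Path, duration: float = 120.0) -> list[FluencySession]:
    """Read coded sessions from the transcript TSV dialect.

    Returns one :class:`FluencySession` per (participant, task) pair present,
    tokens sorted by onset.  Validation failures raise :class:`ValidationError`
    naming the offending row (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str}, keep_default_na=False)
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: transcript missing columns {missing}")

    sessions: list[FluencySession] = []
    for (pid, task), group in df.groupby(["participant_id", "task"], sort=True):
        tokens = []
        unsorted_onsets = False
        last_onset = -1.0
        for idx, row in group.iterrows():
            rowno = int(idx) + 2  # header + 1-based
            category = str(row["category"]) or None
            try:
                tok = Token(
                    word=normalize_word(str(row["word"])),
                    onset=float(row["onset_s"]),
                    offset=float(row["offset_s"]),
                    code=str(row["code"]),
                    category=category,
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path} row {rowno}: {exc}") from exc
            if tok.onset < last_onset:
                unsorted_onsets = True
            last_onset = tok.onset
            tokens.append(tok)
        if unsorted_onsets:
            logger.warning(
                "%s: tokens for %s/%s listed out of onset order; sorting", path, pid, task
            )
        try:
            sessions.append(
                FluencySession(participant_id=str(pid), task_id=str(task),
                               tokens=tokens, duration=duration)
            )
        except ValidationError as exc:
            first_row = int(group.index[0]) + 2
            raise ValidationError(
                f"{path} rows {first_row}..{int(group.index[-1]) + 2}: {exc}"
            ) from exc
    return sessions


def write_sessions(sessions: list[FluencySession], path: str | Path) -> None:
    """Write sessions in the transcript TSV dialect (round-trips read_sessions)."""
    rows = []
    for s in sorted(sessions, key=lambda s: (s.participant_id, s.task_id)):
        for tok in s.tokens:
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "task": s.task_id,
                    "word": tok.word,
                    "onset_s": f"{tok.onset:.3f}",
                    "offset_s": f"{tok.offset:.3f}",
                    "code": tok.code,
                    "category": tok.category or "",
                }
            )
    pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read the demographics TSV (participant_id, sex, age, education)."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    required = {"participant_id", "sex", "age", "education"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: demographics missing columns {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValidationError(f"{path}: duplicate participants {dupes}")
    bad = ~df["education"].isin([1, 2, 3, 4])
    if bad.any():
        raise ValidationError(
            f"{path}: education outside 1-4 for {df.loc[bad, 'participant_id'].tolist()}"
        )
    return df.set_index("participant_id")


def write_demographics(demographics: pd.DataFrame, path: str | Path) -> None:
    demographics.reset_index().to_csv(path, sep="\t", index=False)


def read_ef_scores(
    path: str | Path,
    schema: pd.DataFrame | None = None,
    on_unknown: str = "error",
) -> EFBattery:
    """Read a wide EF score table and attach the battery schema.

    Parameters
    ----------
    schema
        Variable registry; defaults to :func:`default_battery_schema`.
    on_unknown
        ``"error"`` rejects unregistered columns, ``"warn"`` drops them with a
        log warning.
    """
    if schema is None:
        schema = default_battery_schema()
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ValidationError(f"{path}: EF table needs a participant_id column")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValidationError(f"{path}: duplicate participant rows {dupes}")
    df = df.set_index("participant_id")

    known = set(schema["variable"])
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        if on_unknown == "warn":
            logger.warning("%s: dropping unregistered EF columns %s", path, unknown)
            df = df.drop(columns=unknown)
        else:
            raise ValidationError(f"{path}: unregistered EF columns {unknown}")
    missing = [v for v in schema["variable"] if v not in df.columns]
    if missing:
        raise ValidationError(f"{path}: EF table missing schema variables {missing}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric EF cells ({exc})") from exc
    return EFBattery(scores=df, schema=schema)


def write_ef_scores(battery: EFBattery, path: str | Path) -> None:
    battery.scores.reset_index().rename(
        columns={"index": "participant_id"}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Praat TextGrid (interval tiers; long or short text format)
# ---------------------------------------------------------------------------

_QUOTED = re.compile(r'"((?:[^"]|"")*)"')
_NUMBER = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")


def _textgrid_tiers(text: str) -> dict[str, list[tuple[float, float, str]]]:
    """Parse interval tiers out of a TextGrid file (long or short format).

    Both formats serialize each tier as its class string ("IntervalTier"),
    its name, the tier bounds, the interval count, then per interval
    xmin, xmax, text.  Point tiers are skipped.
    """
    tiers: dict[str, list[tuple[float, float, str]]] = {}

    # Tokenize the whole file into an ordered stream of strings and numbers.
    tokens: list[tuple[str, str | float]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == '"':
            m = _QUOTED.match(text, i)
            if not m:
                raise ValidationError("unterminated string in TextGrid")
            tokens.append(("str", m.group(1).replace('""', '"')))
            i = m.end()
        elif ch.isdigit() or (ch == "-" and i + 1 < len(text) and text[i + 1].isdigit()):
            m = _NUMBER.match(text, i)
            tokens.append(("num", float(m.group(0))))
            i = m.end()
        else:
            i += 1

    k = 0
    n = len(tokens)
    while k < n:
        kind, val = tokens[k]
        if kind == "str" and val in ("IntervalTier", "TextTier"):
            is_interval = val == "IntervalTier"
            if k + 1 >= n or tokens[k + 1][0] != "str":
                raise ValidationError("TextGrid tier missing name")
            name = str(tokens[k + 1][1])
            k += 2
            nums = []
            while k < n and tokens[k][0] == "num" and len(nums) < 3:
                nums.append(float(tokens[k][1]))  # xmin, xmax, size
                k += 1
            if len(nums) < 3:
                raise ValidationError(f"TextGrid tier {name!r}: truncated header")
            size = int(nums[2])
            intervals = []
            for _ in range(size):
                # Long format interleaves index numbers ("intervals [1]:");
                # the last two numbers before the label are xmin / xmax
                # (for point tiers: the last one is the point time).
                pending: list[float] = []
                while k < n and tokens[k][0] == "num":
                    pending.append(float(tokens[k][1]))
                    k += 1
                if k >= n or (is_interval and len(pending) < 2):
                    raise ValidationError(f"TextGrid tier {name!r}: truncated")
                label = str(tokens[k][1])
                k += 1
                if is_interval:
                    intervals.append((pending[-2], pending[-1], label))
            if is_interval:
                tiers[name] = intervals
        else:
            k += 1
    return tiers


def read_textgrid(
    path: str | Path,
    tier_name: str,
    participant_id: str,
    task_id: str,
    duration: float = 120.0,
    category: str | None = None,
) -> FluencySession:
    """Build a session from a Praat TextGrid interval tier.

    Non-empty intervals become tokens coded ``correct`` (error coding is an
    editing step downstream); empty intervals are treated as silence.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    if "ooTextFile" not in text:
        raise ValidationError(f"{path}: not a Praat TextGrid")
    tiers = _textgrid_tiers(text)
    if tier_name not in tiers:
        raise ValidationError(
            f"{path}: no interval tier {tier_name!r}; available: {sorted(tiers)}"
        )
    if task_id == "t3" and category is None:
        category = TASK_CATEGORIES["t3"][0]
    tokens = [
        Token(word=normalize_word(label), onset=xmin, offset=xmax,
              code="correct", category=category)
        for xmin, xmax, label in tiers[tier_name]
        if label.strip()
    ]
    return FluencySession(
        participant_id=participant_id, task_id=task_id,
        tokens=tokens, duration=duration,
    )
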
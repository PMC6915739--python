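"""Trial-by-trial behavioral dataset: schema, validation, CSV round trip.

One row per trial: condition cell, the three token values, visited states,
chosen actions, available action sets and the delivered reward.  The CSV
carries a versioned header comment so readers can reject incompatible files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .config import ACTION_INDEX, ACTIONS, COMPLEXITY_LEVELS, UNCERTAINTY_LEVELS
from .task_env import OUTCOME_STATES, STAGE2_STATES, START_STATE, StateSpaceModel

SCHEMA_VERSION = "arbrl-behavior-v1"

COLUMNS = [
    "subject", "session", "trial", "uncertainty", "complexity", "p1",
    "token_red", "token_blue", "token_silver",
    "s1", "a1", "s2", "a2", "s_out", "reward",
    "avail1", "avail2", "timeout",
]


@dataclass(frozen=True)
class TrialRecord:
    """A single trial; ``avail1``/``avail2`` are ordered action-name tuples."""

    subject: str
    session: int
    trial: int
    uncertainty: str
    complexity: str
    p1: float
    token_values: tuple[float, float, float]  # (red, blue, silver)
    s1: int
    a1: str
    s2: int
    a2: str
    s_out: int
    reward: float
    avail1: tuple[str, ...]
    avail2: tuple[str, ...]
    timeout: bool = False

    def as_row(self) -> dict:
        r, b, s = self.token_values
        return {
            "subject": self.subject, "session": self.session, "trial": self.trial,
            "uncertainty": self.uncertainty, "complexity": self.complexity,
            "p1": self.p1, "token_red": r, "token_blue": b, "token_silver": s,
            "s1": self.s1, "a1": self.a1, "s2": self.s2, "a2": self.a2,
            "s_out": self.s_out, "reward": self.reward,
            "avail1": "|".join(self.avail1), "avail2": "|".join(self.avail2),
            "timeout": int(self.timeout),
        }


class DatasetError(ValueError):
    """Raised when a dataset violates the schema or task invariants."""


class BehavioralDataset:
    """A validated table of :class:`TrialRecord` rows (one or more subjects)."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[TrialRecord]) -> "BehavioralDataset":
        return cls(pd.DataFrame([r.as_row() for r in records], columns=COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.df["subject"]))

    def for_subject(self, subject: str) -> "BehavioralDataset":
        return BehavioralDataset(self.df[self.df["subject"] == subject])

    def iter_sessions(self) -> Iterator[pd.DataFrame]:
        for (_, _), grp in self.df.groupby(["subject", "session"], sort=True):
            yield grp

    # -- validation --------------------------------------------------------
    def validate(self, model: StateSpaceModel | None = None) -> None:
        df = self.df
        if not df["uncertainty"].isin(UNCERTAINTY_LEVELS).all():
            raise DatasetError("uncertainty must be 'low' or 'high'")
        if not df["complexity"].isin(COMPLEXITY_LEVELS).all():
            raise DatasetError("complexity must be 'low' or 'high'")
        tok = df[["token_red", "token_blue", "token_silver"]].to_numpy(float)
        if tok.min() < 1.0 or tok.max() > 10.0:
            raise DatasetError("token values must lie in [1, 10]")
        if (df["s1"] != START_STATE).any():
            raise DatasetError("stage-1 state must be the start state")
        if not df["s2"].isin(STAGE2_STATES).all():
            raise DatasetError("invalid stage-2 state id")
        if not df["s_out"].isin(OUTCOME_STATES).all():
            raise DatasetError("invalid outcome state id")
        for stage, (acol, avcol) in enumerate((("a1", "avail1"), ("a2", "avail2")), 1):
            avail_sets = df[avcol].str.split("|")
            ok = [a in av for a, av in zip(df[acol], avail_sets)]
            if not all(ok):
                bad = int(np.argmin(ok))
                raise DatasetError(f"row {bad}: stage-{stage} choice not in available set")
        if model is not None:
            for _, row in df.iterrows():
                s2a, s2b = model.successors(START_STATE, row["a1"])
                if row["s2"] not in (s2a, s2b):
                    raise DatasetError("recorded s2 is not a successor of (s1, a1)")
                oa, ob = model.successors(int(row["s2"]), row["a2"])
                if row["s_out"] not in (oa, ob):
                    raise DatasetError("recorded outcome is not a successor of (s2, a2)")
            tokmap = model.token_idx
            tokv = tok[np.arange(len(df)), np.clip(tokmap[df["s_out"].to_numpy(int)], 0, 2)]
            rewarded = df["reward"].to_numpy(float) > 0
            if not np.allclose(df.loc[rewarded, "reward"],
                               tokv[rewarded.astype(bool)], atol=1e-9):
                raise DatasetError("delivered reward must equal the outcome token value")

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# {SCHEMA_VERSION}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, model: StateSpaceModel | None = None,
                 validate: bool = True) -> "BehavioralDataset":
        text = Path(path).read_text()
        first, _, rest = text.partition("\n")
        if SCHEMA_VERSION not in first:
            raise DatasetError(
                f"unrecognized schema header {first!r}; expected {SCHEMA_VERSION}"
            )
        ds = cls(pd.read_csv(io.StringIO(rest)))
        if validate:
            ds.validate(model)
        return ds

    # -- array form for the likelihood kernel -------------------------------
    def session_arrays(self) -> dict[str, np.ndarray]:
        """Dataset as flat arrays with a session-start marker, sorted by
        (subject, session, trial); action columns as integer indices."""
        df = self.df.sort_values(["subject", "session", "trial"], kind="stable")
        key = df["subject"].astype(str) + "\x00" + df["session"].astype(str)
        new_session = np.ones(len(df), dtype=np.bool_)
        new_session[1:] = key.to_numpy()[1:] != key.to_numpy()[:-1]
        return {
            "new_session": new_session,
            "uncertainty": (df["uncertainty"] == "high").to_numpy(np.int64),
            "complexity": (df["complexity"] == "high").to_numpy(np.int64),
            "tokens": df[["token_red", "token_blue", "token_silver"]].to_numpy(np.float64),
            "a1": df["a1"].map(ACTION_INDEX).to_numpy(np.int64),
            "s2": df["s2"].to_numpy(np.int64),
            "a2": df["a2"].map(ACTION_INDEX).to_numpy(np.int64),
            "s_out": df["s_out"].to_numpy(np.int64),
            "reward": df["reward"].to_numpy(np.float64),
        }
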
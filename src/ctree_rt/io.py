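"""Readers and writers for session tables, tree files and run configs.

Session files are plain CSV with header ``trial,kick,prediction,rt_seconds``
and 1-based contiguous trial numbers.  Trees are JSON objects with the
contexts written as digit strings, oldest symbol first (``"21"`` means
``X[n-1] = 2, X[n] = 1``); probabilistic trees additionally carry one
transition row per context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .trees import (
    Alphabet,
    ContextTree,
    ProbabilisticContextTree,
    SessionData,
    context_from_string,
    context_to_string,
)

PathLike = Union[str, Path]

SESSION_COLUMNS = ["trial", "kick", "prediction", "rt_seconds"]


class SessionParseError(ValueError):
    """Raised for malformed session files; messages carry row numbers."""


def read_session(path: PathLike, alphabet: Optional[Alphabet] = None) -> SessionData:
    """Read and validate one participant session from CSV."""
    path = Path(path)
    alphabet = alphabet or Alphabet()
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SessionParseError(f"{path}: missing column(s) {missing}")
    n = len(df)
    trials = df["trial"].to_numpy()
    if not np.array_equal(trials, np.arange(1, n + 1)):
        bad = int(np.argmax(trials != np.arange(1, n + 1))) + 1
        raise SessionParseError(f"{path}: trial numbers must be 1..{n} contiguous (first problem at data row {bad})")
    for col in ("kick", "prediction"):
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, list(alphabet.symbols))
        if bad.any():
            row = int(np.argmax(bad)) + 1
            raise SessionParseError(f"{path}: {col}={vals[np.argmax(bad)]} outside alphabet at data row {row}")
    rts = df["rt_seconds"].to_numpy(dtype=float)
    nonpos = ~(rts > 0)
    if nonpos.any():
        row = int(np.argmax(nonpos)) + 1
        raise SessionParseError(f"{path}: non-positive rt_seconds at data row {row}")
    return SessionData(
        df["kick"].to_numpy(np.int64),
        df["prediction"].to_numpy(np.int64),
        rts,
        participant_id=path.stem,
        alphabet=alphabet,
    )


def write_session(session: SessionData, path: PathLike) -> Path:
    """Write a session to CSV with 1-based trial numbers and >= 6 significant
    digits on the response times."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "trial": np.arange(1, len(session) + 1),
            "kick": session.kicks,
            "prediction": session.predictions,
            "rt_seconds": session.response_times,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def tree_to_dict(tree: Union[ContextTree, ProbabilisticContextTree]) -> dict:
    if isinstance(tree, ProbabilisticContextTree):
        return {
            "alphabet": list(tree.alphabet.symbols),
            "contexts": tree.tree.as_strings(),
            "transition": {
                context_to_string(w): [float(x) for x in tree.transition[w]]
                for w in tree.tree
            },
        }
    return {"alphabet": list(tree.alphabet.symbols), "contexts": tree.as_strings()}


def tree_from_dict(d: dict) -> Union[ContextTree, ProbabilisticContextTree]:
    alphabet = Alphabet(tuple(d["alphabet"]))
    tree = ContextTree(frozenset(context_from_string(s) for s in d["contexts"]), alphabet)
    if "transition" in d:
        transition = {
            context_from_string(s): np.asarray(row, dtype=float)
            for s, row in d["transition"].items()
        }
        return ProbabilisticContextTree(tree, transition)
    return tree


def write_tree(tree, path: PathLike, extra: Optional[dict] = None) -> Path:
    path = Path(path)
    payload = tree_to_dict(tree)
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_tree(path: PathLike):
    return tree_from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunConfig:
    """Top-level pipeline configuration (simulation + estimation + analysis)."""

    n_participants: int = 22
    n_trials: int = 1000
    epoch_boundaries: tuple[int, ...] = (334, 668)
    seed: int = 0
    K: int = 3
    alpha: float = 0.05
    min_count: int = 5
    mode_threshold: float = 0.5
    trim: float = 0.2
    q: float = 0.05
    contexts: tuple[str, ...] = ("0", "2", "01", "11", "21")
    cohort_dir: Optional[str] = None  # ingest mode: read sessions instead of simulating
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epoch_boundaries"] = list(self.epoch_boundaries)
        d["contexts"] = list(self.contexts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        out = cls(**d)
        out = cls(
            **{
                **d,
                "epoch_boundaries": tuple(d.get("epoch_boundaries", (334, 668))),
                "contexts": tuple(d.get("contexts", ("0", "2", "01", "11", "21"))),
            }
        )
        return out


def read_config(path: PathLike) -> RunConfig:
    """Load a run config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: PathLike) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path
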
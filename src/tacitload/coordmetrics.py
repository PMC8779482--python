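"""Behavioural coordination statistics.

Two measures quantify tacit coordination over a population of N players and
G games of L labels each:

* **Coordination index (CI)**, per game: the probability that two distinct
  players drawn at random without replacement chose the same label,

  ``CI = sum_l n_l (n_l - 1) / (N (N - 1))``

  where ``n_l`` is the number of players who chose label ``l``.  CI is 1 iff
  everyone converged on one label and 0 iff no two players agree; it measures
  how easy a game is to coordinate (low CI = no prominent focal point).

* **Individual coordination ability (iCA)**, per player: the player's
  pairwise agreement with the rest of the population, summed over games and
  normalised to [0, 1],

  ``iCA_i = sum_g m_i(g) / (G (N - 1))``

  with ``m_i(g)`` the number of *other* players who chose player i's label
  in game g.  The population mean of the per-game agreement
  ``m_i(g) / (N - 1)`` equals that game's CI exactly, which ties the two
  measures together and is asserted as a property test.

Both are invariant under relabelling of the options.  Printed tables round
CI to three decimals (round-half-even); internal comparisons always use full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ChoiceTable, InputError, ParameterError


@dataclass
class CoordinationScores:
    """Per-game CI, per-subject iCA and the underlying label counts."""

    ci: pd.Series  # index: game number (1-based)
    ica: pd.Series  # index: subject id
    label_counts: pd.DataFrame  # games x labels
    hardest_games: tuple[int, ...]  # argmin CI; more than one entry on ties


def coordination_index(counts: Sequence[int], n: int | None = None) -> float:
    """CI for one game from its per-label choice counts (full precision)."""
    counts = np.asarray(counts)
    if counts.ndim != 1 or np.any(counts < 0) or not np.all(counts == counts.astype(int)):
        raise InputError("counts must be non-negative integers")
    counts = counts.astype(int)
    total = int(counts.sum())
    if n is None:
        n = total
    if total != n:
        raise InputError(f"counts sum to {total}, expected n = {n}")
    if n < 2:
        raise ParameterError("CI needs at least 2 subjects")
    return float(np.sum(counts * (counts - 1)) / (n * (n - 1)))


def individual_coordination_ability(choices: ChoiceTable, subject: int) -> float:
    """iCA of one subject against the entire population."""
    n, g = choices.n_subjects, choices.n_games
    if n < 2 or g < 1:
        raise ParameterError("iCA needs >= 2 subjects and >= 1 game")
    if not 0 <= subject < n:
        raise InputError(f"unknown subject {subject} (have {n})")
    mine = choices.choices[subject]  # (games,)
    matches = (choices.choices == mine[None, :]).sum(axis=0) - 1  # exclude self
    return float(matches.sum() / (g * (n - 1)))


def label_count_matrix(choices: ChoiceTable) -> np.ndarray:
    """Per-game label counts, shape (n_games, n_labels)."""
    counts = np.zeros((choices.n_games, choices.n_labels), dtype=int)
    for g in range(choices.n_games):
        counts[g] = np.bincount(choices.choices[:, g], minlength=choices.n_labels)
    return counts


def ci_table(choices: ChoiceTable) -> CoordinationScores:
    """CI per game and iCA per subject for a complete choice table.

    The minimum-CI game(s) are reported as the hardest; exact ties yield the
    full tie set.
    """
    if choices.n_subjects < 2:
        raise ParameterError("need at least 2 subjects")
    counts = label_count_matrix(choices)
    n = choices.n_subjects
    ci_vals = (counts * (counts - 1)).sum(axis=1) / (n * (n - 1))
    games = np.arange(1, choices.n_games + 1)
    ci = pd.Series(ci_vals, index=pd.Index(games, name="game"), name="ci")
    ica = pd.Series(
        [individual_coordination_ability(choices, s) for s in range(n)],
        index=pd.Index(np.arange(n), name="subject"),
        name="ica",
    )
    hardest = tuple(int(g) for g in games[ci_vals == ci_vals.min()])
    label_counts = pd.DataFrame(
        counts,
        index=pd.Index(games, name="game"),
        columns=[f"label_{k}" for k in range(choices.n_labels)],
    )
    return CoordinationScores(ci=ci, ica=ica, label_counts=label_counts,
                              hardest_games=hardest)


def round_ci(value: float, decimals: int = 3) -> float:
    """Table-style rounding (round-half-even) of a CI value."""
    return float(np.round(value, decimals))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_choices(path: str | Path) -> ChoiceTable:
    """Read a choice table CSV (subject, game, label, rt_s, condition)."""
    df = pd.read_csv(path)
    required = {"subject", "game", "label", "rt_s", "condition"}
    if not required.issubset(df.columns):
        raise InputError(f"choice CSV must have columns {sorted(required)}")
    conditions = df["condition"].unique()
    if len(conditions) != 1:
        raise InputError("choice CSV must contain a single condition")
    subjects = np.sort(df["subject"].unique())
    games = np.sort(df["game"].unique())
    n_s, n_g = len(subjects), len(games)
    if len(df) != n_s * n_g:
        missing = {
            (s, g)
            for s in subjects
            for g in games
        } - set(zip(df["subject"], df["game"]))
        raise InputError(f"incomplete choice table; missing cells: {sorted(missing)}")
    piv_label = df.pivot(index="subject", columns="game", values="label")
    piv_rt = df.pivot(index="subject", columns="game", values="rt_s")
    return ChoiceTable(
        choices=piv_label.loc[subjects, games].to_numpy(),
        response_time=piv_rt.loc[subjects, games].to_numpy(),
        condition=str(conditions[0]),
        # labels are opaque indices; CI/iCA depend only on observed counts
        n_labels=max(int(df["label"].max()) + 1, 2),
    )


def save_scores(scores: CoordinationScores, directory: str | Path) -> tuple[Path, Path]:
    """Write per-game CI (with counts) and per-subject iCA CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ci_path = directory / "ci.csv"
    out = scores.label_counts.copy()
    out["ci"] = scores.ci
    out["ci_rounded"] = scores.ci.map(round_ci)
    out.to_csv(ci_path, float_format="%.10g")
    ica_path = directory / "ica.csv"
    scores.ica.to_frame().to_csv(ica_path, float_format="%.10g")
    return ci_path, ica_path
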
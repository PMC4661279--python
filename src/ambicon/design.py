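"""Matched-gamble task design: card-deck lotteries and the 4-run session schedule.

Each trial offers a choice between a sure gain ($3) and betting $10 on the type
of a card drawn from a 100-card deck.  The deck holds a known number of Type-1
cards; the remaining ``level`` cards (6-94, even) are split between Type 2 and
Type 3.  What participants know about that split defines the condition:

* ``risk`` -- the split is known and equal (level/2, level/2);
* ``ambiguity`` -- only the total ``level`` is known;
* ``conflict`` -- two equally credible sources assert precise but opposite
  splits (message_b is message_a swapped);
* ``ignorance`` -- structurally an ambiguity gamble (its behavioural findings
  are analysed elsewhere; it exists here so the imaging model has all four
  conditions).

Conditions are matched on expected value: the information-neutral winning
probability of a Type-2 (or Type-3) bet is level/200 in every condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONDITIONS = ("risk", "ambiguity", "conflict", "ignorance")
UNCERTAIN_CONDITIONS = ("ambiguity", "conflict", "ignorance")
TRIAL_TYPES = CONDITIONS + ("fixation",)
OPTIONS = ("sure", "type1", "type2", "type3")

DECK_SIZE = 100
SURE_GAIN = 3.0
WIN_PAYOFF = 10.0

GAMBLE_DURATION_S = 6.5
FIXATION_AFTER_S = 1.0
TRIAL_SLOT_S = GAMBLE_DURATION_S + FIXATION_AFTER_S  # 7.5 s, also fixation-trial length
TRIALS_PER_TYPE_PER_RUN = 8

#: Default levels: 20 even values <= 66 and 10 even values > 66, spanning 6..94.
#: Exactly the ten levels above 200/3 make betting the risk-neutral choice, so a
#: risk-neutral agent bets ten times in the 32-trial risk condition (repeats are
#: drawn from the <=66 subset).
DEFAULT_LEVELS = (
    6, 8, 12, 16, 20, 24, 28, 32, 36, 40,
    44, 46, 50, 52, 56, 58, 60, 62, 64, 66,
    68, 72, 76, 78, 82, 84, 88, 90, 92, 94,
)


class DesignError(ValueError):
    """Raised for invalid task-design configurations."""


@dataclass(frozen=True)
class Gamble:
    """One lottery: a 100-card deck with a condition-specific information state."""

    condition: str
    level: int
    message_a: tuple[int, int] | None = None
    message_b: tuple[int, int] | None = None
    sure_gain: float = SURE_GAIN
    win_payoff: float = WIN_PAYOFF
    gamble_id: str = ""

    @property
    def type1_count(self) -> int:
        return DECK_SIZE - self.level

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DesignError(f"unknown condition {self.condition!r}")
        if self.level % 2 or not (6 <= self.level <= 94):
            raise DesignError(f"level must be even and in [6, 94], got {self.level}")
        if self.condition == "conflict":
            a, b = self.message_a, self.message_b
            if a is None or b is None:
                raise DesignError("conflict gambles need two messages")
            if b != (a[1], a[0]) or sum(a) != self.level:
                raise DesignError("conflict messages must be swapped pairs summing to level")
            if a == (self.level // 2, self.level // 2):
                raise DesignError("conflict messages must disagree with the even split")


def conflict_messages(level: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """The two asserted (Type-2, Type-3) splits for a conflict gamble.

    Source A asserts (round(level/3), level - round(level/3)); source B asserts
    the swap.  At level 6 this gives (2, 4) vs (4, 2), and the message mean is
    level/2, keeping the information-neutral probability at level/200.
    """
    m = int(round(level / 3))
    return (m, level - m), (level - m, m)


def make_gamble(condition: str, level: int, gamble_id: str = "") -> Gamble:
    if condition == "conflict":
        a, b = conflict_messages(level)
        return Gamble(condition, level, a, b, gamble_id=gamble_id)
    return Gamble(condition, level, gamble_id=gamble_id)


@dataclass(frozen=True)
class GambleSet:
    """30 unique gambles per condition plus 2 seeded repeats (32 trials each)."""

    unique: dict[str, tuple[Gamble, ...]]
    repeats: dict[str, tuple[Gamble, ...]]
    levels: tuple[int, ...]
    seed: int

    def trial_gambles(self, condition: str) -> list[Gamble]:
        """All 32 trial gambles for one condition (uniques then repeats)."""
        return list(self.unique[condition]) + list(self.repeats[condition])


def _validate_levels(levels) -> tuple[int, ...]:
    levels = tuple(int(v) for v in levels)
    if len(levels) != len(set(levels)):
        raise DesignError("levels must be distinct")
    for v in levels:
        if v % 2 or not (6 <= v <= 94):
            raise DesignError(f"level {v} is odd or outside [6, 94]")
    return levels


def generate_gamble_set(
    levels=DEFAULT_LEVELS, seed: int = 0, conditions=CONDITIONS
) -> GambleSet:
    """Build the per-condition gamble sets, level-matched across conditions.

    ``levels`` must contain 30 distinct even integers in [6, 94] including the
    endpoints.  Two repeat levels are drawn (seeded) from the sub-levels not
    exceeding 66, so the risk-neutral bet count of the 32 risk trials stays at
    ten; the same repeat levels are used in every condition to preserve the
    expected-value match trial-for-trial.
    """
    levels = _validate_levels(levels)
    if len(levels) != 30 or 6 not in levels or 94 not in levels:
        raise DesignError("need 30 distinct even levels in [6, 94] incl. 6 and 94")
    rng = np.random.default_rng(seed)
    low = [v for v in levels if v <= 66]
    repeat_levels = tuple(sorted(rng.choice(low, size=2, replace=False).tolist()))

    unique: dict[str, tuple[Gamble, ...]] = {}
    repeats: dict[str, tuple[Gamble, ...]] = {}
    for cond in conditions:
        unique[cond] = tuple(
            make_gamble(cond, lvl, f"{cond[0].upper()}{i:02d}_L{lvl}")
            for i, lvl in enumerate(sorted(levels))
        )
        by_level = {g.level: g for g in unique[cond]}
        repeats[cond] = tuple(by_level[lvl] for lvl in repeat_levels)
    return GambleSet(unique, repeats, levels, seed)


def winning_probability(gamble: Gamble, option: str) -> float:
    """Information-neutral probability of winning the payoff of ``option``.

    Type-2/Type-3 bets win with probability level/200 in every condition: the
    known composition under risk, the interval midpoint under ambiguity, and
    the mean of the two messages under conflict.
    """
    if option == "sure":
        return 1.0
    if option == "type1":
        return (DECK_SIZE - gamble.level) / DECK_SIZE
    if option in ("type2", "type3"):
        return gamble.level / (2 * DECK_SIZE)
    raise DesignError(f"unknown option {option!r}")


@dataclass(frozen=True)
class SessionTrial:
    run: int                  # 0-based run index
    index_in_run: int
    trial_type: str           # condition name or "fixation"
    onset: float              # seconds from run start
    duration: float
    gamble: Gamble | None = None


@dataclass(frozen=True)
class Session:
    """The full scanning schedule: trials with onsets, runs, and volume counts."""

    trials: tuple[SessionTrial, ...]
    n_runs: int
    tr: float
    volumes_per_run: int

    @property
    def run_duration(self) -> float:
        return self.n_runs and self.volumes_per_run * self.tr

    def run_trials(self, run: int) -> list[SessionTrial]:
        return [t for t in self.trials if t.run == run]

    def gamble_trials(self, condition: str | None = None) -> list[SessionTrial]:
        out = [t for t in self.trials if t.trial_type != "fixation"]
        if condition is not None:
            out = [t for t in out if t.trial_type == condition]
        return out

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (one row per trial, all runs)."""
        rows = [
            {
                "run": t.run + 1,
                "onset": t.onset,
                "duration": t.duration,
                "trial_type": t.trial_type,
                "level": t.gamble.level if t.gamble else np.nan,
                "gamble_id": t.gamble.gamble_id if t.gamble else "n/a",
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def build_session(
    gambles: GambleSet,
    seed: int = 0,
    n_runs: int = 4,
    tr: float = 2.5,
    volumes_per_run: int = 200,
) -> Session:
    """Pseudorandomly schedule the session: 8 trials of each of the 5 trial
    types per run, 6.5 s gambles each followed by >= 1 s fixation, padded with
    seeded inter-trial baseline gaps to fill ``volumes_per_run * tr``.
    """
    per_cond = n_runs * TRIALS_PER_TYPE_PER_RUN
    pool = {c: gambles.trial_gambles(c) for c in CONDITIONS}
    for c, lst in pool.items():
        if len(lst) < per_cond:
            raise DesignError(
                f"{c}: {len(lst)} gambles cannot fill {n_runs} runs x "
                f"{TRIALS_PER_TYPE_PER_RUN} trials"
            )
    run_len = volumes_per_run * tr
    n_trials_run = TRIALS_PER_TYPE_PER_RUN * len(TRIAL_TYPES)
    slack = run_len - n_trials_run * TRIAL_SLOT_S
    if slack < 0:
        raise DesignError("run too short for 8 trials of each of the 5 types")

    rng = np.random.default_rng(seed)
    assign: dict[str, list[list[Gamble]]] = {}
    for c in CONDITIONS:
        order = rng.permutation(len(pool[c]))[:per_cond]
        picked = [pool[c][i] for i in order]
        assign[c] = [
            picked[r * TRIALS_PER_TYPE_PER_RUN : (r + 1) * TRIALS_PER_TYPE_PER_RUN]
            for r in range(n_runs)
        ]

    trials: list[SessionTrial] = []
    for run in range(n_runs):
        types = list(
            itertools.chain.from_iterable(
                [tt] * TRIALS_PER_TYPE_PER_RUN for tt in TRIAL_TYPES
            )
        )
        rng.shuffle(types)
        # distribute the slack as 0.5 s baseline units over the gaps after trials
        n_units = int(round(slack / 0.5))
        gap_units = rng.multinomial(n_units, np.ones(n_trials_run) / n_trials_run)
        t = 0.0
        counters = {c: 0 for c in CONDITIONS}
        for i, tt in enumerate(types):
            if tt == "fixation":
                trials.append(SessionTrial(run, i, tt, t, TRIAL_SLOT_S))
            else:
                g = assign[tt][run][counters[tt]]
                counters[tt] += 1
                trials.append(SessionTrial(run, i, tt, t, GAMBLE_DURATION_S, g))
            t += TRIAL_SLOT_S + gap_units[i] * 0.5
        assert t <= run_len + 1e-9
    return Session(tuple(trials), n_runs, tr, volumes_per_run)


def risk_neutral_bet_count(session: Session) -> int:
    """Number of risk trials on which a risk-neutral agent bets on Type 2/3.

    Betting is optimal when ``win_payoff * level/200`` strictly exceeds both the
    sure gain and the expected value of the Type-1 bet, i.e. level > 200/3 at
    the default payoffs; the default design yields exactly ten such trials.
    """
    risk = session.gamble_trials("risk")
    if not risk:
        raise DesignError("session has no risk trials")
    n = 0
    for t in risk:
        g = t.gamble
        ev_bet = g.win_payoff * winning_probability(g, "type2")
        ev_t1 = g.win_payoff * winning_probability(g, "type1")
        if ev_bet > g.sure_gain and ev_bet > ev_t1:
            n += 1
    return n


def gambles_to_table(gambles: GambleSet) -> pd.DataFrame:
    """Flat TSV-ready table of every unique gamble."""
    rows = []
    for cond in gambles.unique:
        for g in gambles.unique[cond]:
            a = g.message_a or (np.nan, np.nan)
            b = g.message_b or (np.nan, np.nan)
            rows.append(
                {
                    "gamble_id": g.gamble_id,
                    "condition": g.condition,
                    "level": g.level,
                    "type1_count": g.type1_count,
                    "msg_a_type2": a[0],
                    "msg_a_type3": a[1],
                    "msg_b_type2": b[0],
                    "msg_b_type3": b[1],
                    "sure_gain": g.sure_gain,
                    "win_payoff": g.win_payoff,
                }
            )
    return pd.DataFrame(rows)
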
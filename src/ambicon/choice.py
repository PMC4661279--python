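"""Subjective-expected-utility multinomial-logit choice model.

A subject assigns each option j a weight

    W_j = x_j ** theta * pi_j ** gamma_j

where x_j is the payoff, pi_j the winning probability, theta the monetary
utility exponent, and gamma_j a condition-specific probability-weighting
parameter applied only to options whose probability is uncertain (the Type-2
and Type-3 bets in ambiguity/conflict/ignorance trials).  The sure gain and
the Type-1 bet have precisely known probabilities and always use gamma = 1,
as does every option in risk trials (the identifiability anchor).  Choice
probabilities are a softmax over the weights: p_j = exp(W_j) / sum_k exp(W_k).
gamma > 1 is aversion (uncertain options down-weighted), gamma < 1 seeking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import OPTIONS, Gamble, winning_probability


class ChoiceModelError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectParameters:
    """Per-subject utility curvature and condition-specific probability weights."""

    theta: float = 1.0
    gamma_a: float = 1.0
    gamma_c: float = 1.0
    gamma_i: float = 1.0
    subject_id: str = ""
    age: float = float("nan")
    sex: str = ""

    def __post_init__(self) -> None:
        for name in ("theta", "gamma_a", "gamma_c", "gamma_i"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ChoiceModelError(f"{name} must be strictly positive and finite, got {v}")

    def gamma_for(self, condition: str) -> float:
        """The probability-weighting parameter for a trial's condition."""
        return {
            "risk": 1.0,
            "ambiguity": self.gamma_a,
            "conflict": self.gamma_c,
            "ignorance": self.gamma_i,
        }[condition]


@dataclass(frozen=True)
class ChoiceRecord:
    """One trial's outcome: the gamble, the chosen option, and the response time."""

    gamble: Gamble
    choice: str | None          # one of OPTIONS, or None for a missed response
    rt_s: float | None = None
    run: int = 0
    trial: int = 0
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.choice is not None and self.choice not in OPTIONS:
            raise ChoiceModelError(f"unknown option {self.choice!r}")


def option_weight(x: float, pi: float, gamma: float, theta: float) -> float:
    """W = x**theta * pi**gamma; returns 0 at pi = 0 by continuity."""
    if x <= 0 or gamma <= 0 or theta <= 0 or not (0.0 <= pi <= 1.0):
        raise ChoiceModelError(
            f"need x > 0, 0 <= pi <= 1, gamma > 0, theta > 0; got "
            f"x={x}, pi={pi}, gamma={gamma}, theta={theta}"
        )
    if pi == 0.0:
        return 0.0
    return float(x**theta * pi**gamma)


def _gamma_per_option(gamble: Gamble, params: SubjectParameters) -> np.ndarray:
    g = params.gamma_for(gamble.condition)
    return np.array([1.0, 1.0, g, g])


def option_weights(gamble: Gamble, params: SubjectParameters) -> np.ndarray:
    """Weights for (sure, type1, type2, type3) on one trial."""
    gammas = _gamma_per_option(gamble, params)
    return np.array(
        [
            option_weight(
                gamble.sure_gain if opt == "sure" else gamble.win_payoff,
                winning_probability(gamble, opt),
                gammas[i],
                params.theta,
            )
            for i, opt in enumerate(OPTIONS)
        ]
    )


def choice_probabilities(gamble: Gamble, params: SubjectParameters) -> np.ndarray:
    """Softmax choice probabilities over (sure, type1, type2, type3).

    Computed with a max-shift so the result is finite whenever the weights are.
    """
    w = option_weights(gamble, params)
    e = np.exp(w - w.max())
    return e / e.sum()


def subjective_value(gamble: Gamble, choice: str, params: SubjectParameters) -> float:
    """Weight W of the chosen option (the subjective-value confound regressor)."""
    idx = OPTIONS.index(choice)
    return float(option_weights(gamble, params)[idx])


def model_free_attitudes(choices) -> tuple[int, int, int]:
    """Model-free (RA, AA, CA) from bet counts, a "bet" being type2 or type3.

    RA = 10 - bets under risk (ten is the risk-neutral benchmark);
    AA = bets under risk - bets under ambiguity;
    CA = bets under risk - bets under conflict.
    Positive values are aversion, negative seeking.
    """
    bets = {c: 0 for c in ("risk", "ambiguity", "conflict")}
    seen = set()
    for rec in choices:
        cond = rec.gamble.condition
        if cond in bets:
            seen.add(cond)
            if rec.choice in ("type2", "type3"):
                bets[cond] += 1
    missing = set(bets) - seen
    if missing:
        raise ChoiceModelError(f"missing conditions: {sorted(missing)}")
    ra = 10 - bets["risk"]
    aa = bets["risk"] - bets["ambiguity"]
    ca = bets["risk"] - bets["conflict"]
    return ra, aa, ca


def choices_to_table(choices, subject_id: str = ""):
    """Flat CSV-ready table of a choice sequence (rt in milliseconds)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "run": rec.run + 1,
            "trial": rec.trial,
            "condition": rec.gamble.condition,
            "level": rec.gamble.level,
            "choice": rec.choice,
            "rt_ms": None if rec.rt_s is None else 1000.0 * rec.rt_s,
        }
        for rec in choices
    )


def parameters_to_dict(params: SubjectParameters, ra=None, aa=None, ca=None) -> dict:
    """JSON-ready record of fitted parameters plus optional model-free scores."""
    return {
        "subject_id": params.subject_id,
        "theta": params.theta,
        "gamma_a": params.gamma_a,
        "gamma_c": params.gamma_c,
        "gamma_i": params.gamma_i,
        "ra": ra, "aa": aa, "ca": ca,
    }


def second_order_variance(gamble: Gamble) -> float:
    """Variance of the Type-2 winning probability implied by the information.

    risk: the composition is known, variance 0.  ambiguity: the Type-2 count is
    uniform on {0, ..., level}, so Var(k/100) = level(level+2)/120000.
    conflict: a two-point distribution over the two messages' Type-2
    probabilities.  At every level the ambiguity variance exceeds the conflict
    variance, the design's variance ordering.
    """
    if gamble.condition == "risk":
        return 0.0
    if gamble.condition == "ambiguity":
        n = gamble.level
        return (n * (n + 2) / 12.0) / 1.0e4
    if gamble.condition == "conflict":
        a2 = gamble.message_a[0]
        b2 = gamble.message_b[0]
        return ((a2 - b2) / 200.0) ** 2
    raise ChoiceModelError(f"no second-order variance for {gamble.condition!r}")
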
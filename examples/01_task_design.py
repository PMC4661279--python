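"""Build the matched card-deck gamble sets and the 4-run session schedule.

Prints the design constants that the task guarantees by construction: 30
unique uncertainty levels from 6 to 94 cards, Type-2 winning probabilities
from 0.03 to 0.47 in every condition, 32 trials per condition, and exactly
ten risk trials on which a risk-neutral agent should bet.
"""

import ambicon as ac

gambles = ac.generate_gamble_set(seed=0)
session = ac.build_session(gambles, seed=0, n_runs=4, volumes_per_run=120)

probs = [ac.winning_probability(g, "type2") for g in gambles.unique["risk"]]
print(f"unique gambles per condition : {len(gambles.unique['risk'])}")
print(f"type-2 win probability range : {min(probs):.2f} .. {max(probs):.2f}")
print(f"trials per condition         : {len(gambles.trial_gambles('risk'))}")
print(f"risk-neutral bet count       : {ac.risk_neutral_bet_count(session)}")

g6 = next(g for g in gambles.unique["conflict"] if g.level == 6)
print(f"level-6 conflict messages    : {g6.message_a} vs {g6.message_b}")
print("\nfirst five scheduled trials of run 1:")
print(session.to_events().head().to_string(index=False))
# The events table is BIDS-style: onset/duration in seconds, one row per
# trial, fixation trials included as their own trial type.
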
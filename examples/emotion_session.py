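"""Simulate a background monitoring session.

A hidden emotional trajectory is sampled from a sticky five-state HMM;
every few steps a face is rendered for the current state, classified,
and the observation updates the filtered state posterior.  The TEA score
(valence-weighted posterior) picks an intervention strategy, and the
scalar affect E(t) relaxes toward the ideal level between captures.
"""

import emolearn as el

arts = el.run_training()  # default surrogate corpus, m=20, T=30
log = el.simulate_session(
    arts.features,
    arts.strong,
    T=30,
    mode="background",
    interval=5,
    noise_sd=0.3,
    seed=3,
)

cols = ["t", "hidden", "obs", "tea", "E", "strategy"]
print(log.captures()[cols].to_string(index=False))
print()
print(f"{int(log.frame['captured'].sum())} captures over {len(log.frame)} steps")
# Negative TEA (frustrated/angry posterior mass) triggers "soothe";
# near-neutral TEA triggers gentle encouragement; E(t) tracks the
# running affect and decays toward 0 between captures.
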
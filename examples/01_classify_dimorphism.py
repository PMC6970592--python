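"""Classify sexual size dimorphism of a wing muscle from specimen volumes.

Builds a two-species synthetic volume table (one species with a strongly
male-enlarged hg1, one monomorphic), normalizes each hemithorax by its
seven-muscle total, and prints per species the Cohen's d and the resulting
dimorphism call.  |d| >= 1.5 calls the muscle dimorphic; the sign says
which sex is enlarged.
"""

import numpy as np

from dimorphasr import SimConfig, effect_sizes, normalize, simulate_volumes

states = {"hg1": {"spA": "male_enlarged", "spB": "monomorphic"}}
table = simulate_volumes(states, SimConfig(seed=0, n_per_sex=12),
                         np.random.default_rng(0))
effects = effect_sizes(normalize(table), muscles=("hg1",))
for e in effects:
    print(f"{e.species} hg1: n={e.n_male}/{e.n_female} "
          f"d={e.d:+.2f} t={e.t_stat:+.2f} p={e.p_value:.2g} -> {e.state}")
print("\nA positive d means the male mean normalized volume exceeds the "
      "female's; spA crosses the 1.5 threshold, spB does not.")
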
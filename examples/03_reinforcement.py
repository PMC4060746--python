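"""Reinforcement learning enhances category activations.

Objects are divided into value groups and paired with their group's
reinforcer over repeated trials.  Conditioned-reinforcer weights (object
category -> value category) and incentive-motivational weights (value ->
object-value category) grow, closing a resonant loop that amplifies the
activations of valued categories relative to a control in which the
reinforcement pathways are clamped to zero.
"""

import numpy as np

from artscan import Model, ModelConfig, object_library
from artscan.engine import run_reinforcement_schedule

cfg = ModelConfig()
library = object_library(8, seed=1)
groups = {o: i % 2 for i, o in enumerate(sorted(library))}


def curves(ablate):
    m = Model(cfg, library, groups=groups)
    m.object_node = {o: i for i, o in enumerate(sorted(library))}
    m.ablate_reinforcement = ablate
    return run_reinforcement_schedule(m, trials=30, record=True)


with_r = curves(False)
without = curves(True)
print("trial-averaged activations, with vs without reinforcement:")
print(f"{'trial':>5} {'value+':>7} {'value-':>7} {'objval+':>8} "
      f"{'objval-':>8}")
for i in (0, 4, 9, 19, 29):
    print(f"{i + 1:>5} {with_r[i]['value']:>7.3f} {without[i]['value']:>7.3f}"
          f" {with_r[i]['orb']:>8.3f} {without[i]['orb']:>8.3f}")
print("The '+' columns (with reinforcement) exceed the '-' controls on "
      "every trial: pairing with a reinforcer converts the object category "
      "into a conditioned reinforcer and motivationally amplifies its "
      "object-value representation.")
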
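"""Where's-Waldo search through all six routes.

A model trained on 12 objects (3 value groups of 4) searches scenes in
which one trained object is the target at a random non-foveal position and
eight distractors come from the other value groups.  Search can start
bottom-up (an internal drive state only), from a cognitive name prime, or
from a motivational drive prime, and reach the eye-movement map either
directly (learned category-to-position association) or indirectly (boundary
priming -> surface enhancement -> shroud -> surface contours).

Expected pattern: every route finds its target; direct routes take
~180-200 ms of model time, indirect routes ~330-360 ms, and the bottom-up
origin is slowest within each path because its selection must wait for the
scene to be recognized.
"""

from artscan import Model, ModelConfig, object_library
from artscan.engine import (make_search_scenes, run_battery,
                            run_reinforcement_schedule, train_positional)

cfg = ModelConfig()
library = object_library(12, seed=2)
groups = {o: i % 3 for i, o in enumerate(sorted(library))}
model = Model(cfg, library, groups=groups)
print("training 12 objects at 9 positions (a few minutes)...")
train_positional(model)
run_reinforcement_schedule(model, trials=40)

scenes = make_search_scenes(model, seed=11)
df = run_battery(model, scenes)
summary = df.groupby(["origin", "path"]).agg(
    accuracy=("found", "mean"), mean_rt_ms=("rt_ms", "mean"))
print(summary.round(1).to_string())
print(f"overall first-saccade accuracy: {100 * df['found'].mean():.1f}% "
      f"over {len(df)} trials")
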
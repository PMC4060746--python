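import numpy as np
import pytest

from artscan import Model, ModelConfig, SceneSpec, object_library
from artscan.engine import (integrate, run_reinforcement_schedule,
                            train_positional)


@pytest.fixture(scope="session")
def cfg():
    return ModelConfig()


@pytest.fixture(scope="session")
def library6():
    return object_library(6, seed=1)


@pytest.fixture(scope="session")
def library12():
    return object_library(12, seed=2)


@pytest.fixture(scope="session")
def trained12(cfg, library12):
    """Model trained on 12 objects x all nine central positions, with
    reinforcement (3 value groups of 4)."""
    groups = {o: i % 3 for i, o in enumerate(sorted(library12))}
    m = Model(cfg, library12, groups=groups, seed=0)
    train_positional(m)
    run_reinforcement_schedule(m, trials=40)
    return m


@pytest.fixture(scope="session")
def freeview_log(cfg, library6):
    """Free-viewing learning trial on the canonical three-object scene."""
    m = Model(cfg, library6,
              groups={o: i % 3 for i, o in enumerate(sorted(library6))})
    spec = SceneSpec(cfg.scene_side,
                     [(13, "obj00"), (7, "obj01"), (14, "obj03")])
    log = integrate(m, spec, 4.5, learn=True)
    return m, log
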
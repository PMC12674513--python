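import numpy as np
import pandas as pd
import pytest

from ethobuzz import synth
from ethobuzz.events import default_phase_scheme
from ethobuzz.phase_metrics import summarize


@pytest.fixture(scope="session")
def part1():
    return default_phase_scheme("part1")


@pytest.fixture(scope="session")
def part2():
    return default_phase_scheme("part2")


@pytest.fixture(scope="session")
def demo_data(part1):
    """One seeded realisation of the demo behaviour generator."""
    spec = synth.default_behaviour_spec()
    events, roster, truth = synth.gen_behaviour_events(spec, seed=12345)
    return spec, events, roster, truth


@pytest.fixture(scope="session")
def demo_summaries(part1, demo_data):
    spec, events, roster, _ = demo_data
    return summarize(events, part1, roster)


def make_events(rows):
    """Event table from (trial, colony, bee, caste, behaviour, start, stop, loc)."""
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "colony_id", "bee_id", "caste", "behaviour",
            "start_s", "stop_s", "location",
        ],
    )


def make_roster(bees, trial_id="T1", colony_id="C1"):
    """Roster from (bee_id, caste) pairs."""
    return pd.DataFrame(
        [dict(trial_id=trial_id, colony_id=colony_id, bee_id=b, caste=c, excluded=False)
         for b, c in bees]
    )


def onset_annotations(onsets, sound_type="pulse_buzzing", recording_id="r1",
                      element_s=0.05):
    df = pd.DataFrame(
        dict(recording_id=recording_id, onset_s=np.asarray(onsets, float),
             sound_type=sound_type)
    )
    df["offset_s"] = df["onset_s"] + element_s
    return df[["recording_id", "onset_s", "offset_s", "sound_type"]]
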
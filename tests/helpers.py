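"""Shared builders for forced-model observation fixtures."""

import numpy as np

from ctldyn.model import InputSignals, initial_state, simulate
from ctldyn.observations import ObservationSet, make_row
from ctldyn.params import TumorImmuneParams

import pandas as pd


def study_inputs() -> InputSignals:
    """CTL and IFNG input knots shaped like the imaging/expression data."""
    return InputSignals.from_means(
        [1, 3, 5, 7, 10, 14], [20, 30, 25, 15, 5, 1],
        [1, 3, 5, 7], [0.5, 1.64, 0.3, 0.05])


def forced_observations(ke, ki, inputs, kgs=1.64, ksg=0.66,
                        v0=100.0) -> ObservationSet:
    """Noiseless growth/ratio observations from the input-forced model."""
    days = np.array([-1.0, 1.0, 3.0, 5.0, 7.0, 10.0, 14.0])
    p = TumorImmuneParams(kgs=kgs, ksg=ksg, ke=ke, ki=ki)
    traj = simulate(p, initial_state(p, v0=v0, t0=-1.0), days, inputs=inputs)
    v = traj["V"].to_numpy()
    rows = []
    for i in range(len(days) - 1):
        rate = np.log(v[i + 1] / v[i]) / (days[i + 1] - days[i])
        rows.append(make_row("growth_rate", 0.5 * (days[i] + days[i + 1]),
                             mean=rate, sd=0.1, n=5,
                             day_start=days[i], day_end=days[i + 1]))
    for i, day in enumerate(days[1:], start=1):
        rows.append(make_row("ratio_sgm_g1", day,
                             mean=traj["ratio_SG"].iloc[i], sd=0.05, n=4))
    return ObservationSet(pd.DataFrame(rows))
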
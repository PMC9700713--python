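import numpy as np
import pytest

from pwpe_eeg.containers import make_cap32
from pwpe_eeg.hgf import filter_sequence
from pwpe_eeg.simulate import (EffectSpec, NoiseSpec, ParadigmSpec,
                               gen_subject_eeg, gen_tone_sequence)


@pytest.fixture(scope="session")
def cap32():
    return make_cap32()


@pytest.fixture(scope="session")
def small_paradigm():
    return ParadigmSpec(n_trials=200)


@pytest.fixture(scope="session")
def small_subject(small_paradigm):
    """One simulated subject with the default planted epsilon2 effect."""
    seq = gen_tone_sequence(small_paradigm, seed=11)
    traj = filter_sequence(seq)
    epochs = gen_subject_eeg(seq, traj, [EffectSpec()], NoiseSpec(),
                             subject_scale=1.0, seed=12,
                             paradigm=small_paradigm)
    return seq, traj, epochs


def square_montage(n_side=5, spacing=20.0, with_eog=False):
    """A regular square electrode lattice for geometric oracles."""
    from pwpe_eeg.containers import ChannelInfo

    xs = spacing * (np.arange(n_side) - (n_side - 1) / 2)
    names, pos, role = [], [], []
    for i, x in enumerate(xs):
        for j, y in enumerate(xs):
            names.append(f"ch{i}{j}")
            pos.append((x, y))
            role.append("scalp")
    if with_eog:
        names.append("VEOG")
        pos.append((0.0, spacing * n_side))
        role.append("eog")
    return ChannelInfo(names, np.asarray(pos, float),
                       np.asarray(role, object), np.zeros(len(names), bool))
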
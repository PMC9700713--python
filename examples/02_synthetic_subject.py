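"""Simulate one subject's oddball EEG and clean it.

Plants a 5 uV/z sensory-pwPE effect on frontocentral channels at
100-228 ms, adds spatially correlated AR(1) noise and blinks, then runs
the preprocessing rules (EOG blink rejection, 100 uV amplitude rule,
>20% bad-channel rule) and reports the rejection bookkeeping.
"""
from pwpe_eeg import (EffectSpec, NoiseSpec, ParadigmSpec, filter_sequence,
                      gen_subject_eeg, gen_tone_sequence)
from pwpe_eeg.preprocess import preprocess_epochs

paradigm = ParadigmSpec(n_trials=600)
seq = gen_tone_sequence(paradigm, seed=3)
traj = filter_sequence(seq)
epochs = gen_subject_eeg(seq, traj, [EffectSpec()], NoiseSpec(),
                         subject_scale=1.0, seed=4, paradigm=paradigm)
print(f"epochs: {epochs.data.shape} (trials x channels x samples), "
      f"{epochs.meta['n_blinks']} blinks planted")

clean = preprocess_epochs(epochs)
counts = clean.rejection_counts()
print(f"kept {counts['none']} trials; rejected {counts['blink']} (blink), "
      f"{counts['amplitude']} (amplitude)")
print("bad channels:", [n for n, b in zip(clean.channels.names,
                                          clean.channels.bad) if b] or "none")
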
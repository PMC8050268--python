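"""From raw 2 kHz EMG recordings to the analysis tensor.

Renders raw surface-EMG surrogates (envelope-modulated band-limited
carriers), runs the fixed preprocessing chain — offset removal,
full-wave rectification, zero-phase 10 Hz low-pass, resampling to
200 Hz, 750 ms window ending at ball release — then assembles,
normalizes and QC-screens the tensor.
"""

import numpy as np

import pitchsynergy as ps

gt = ps.generate_ground_truth(ps.ScenarioConfig(noise_sd=0.0), seed=7)
recordings = ps.render_raw_emg(gt, seed=7)
print(f"{len(recordings)} trials of "
      f"{recordings[0].samples.shape[0]} samples x "
      f"{recordings[0].n_channels} channels at "
      f"{recordings[0].sampling_rate:.0f} Hz")

envelopes = [ps.preprocess_recording(r) for r in recordings]
tensor = ps.assemble_tensor(
    envelopes, [r.effort for r in recordings],
    ball_speeds=[r.ball_speed for r in recordings],
    muscle_labels=gt.muscle_labels)
print(f"assembled tensor: {tensor.X.shape}")

normalized = ps.minmax_normalize(tensor)
print(f"after min-max normalization each muscle spans "
      f"[{normalized.X.min(axis=(1, 2)).max():.0f}, "
      f"{normalized.X.max(axis=(1, 2)).min():.0f}]")

qc = ps.qc_subject(tensor)
print(f"QC: keep={qc.keep}, flagged muscles={qc.flagged_muscles}")

ref = ps.render_tensor(gt, seed=7)
rs = [np.corrcoef(tensor.X[i].ravel(), ref.X[i].ravel())[0, 1]
      for i in range(gt.n_muscles)]
print(f"round trip vs planted envelopes: per-channel r "
      f"min {min(rs):.3f}, mean {np.mean(rs):.3f}")
# r ~ 1 confirms the chain recovers the planted module activity from the
# raw carriers.
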
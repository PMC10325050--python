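"""Temporal Grad-CAM on a toy convolutional classifier.

A single conv filter is matched to a 10 Hz burst planted at 60-70 s of a
3-minute trace; the attribution peak should land inside that window,
demonstrating how the tool flags the EEG epochs driving a prediction.
"""

import numpy as np

from eegtriage.interpret import grad_cam_temporal
from eegtriage.nn import Model, NetworkSpec
from eegtriage.nn.layers import Conv1D, Dense, GlobalAvgPool, ReLU, Softmax

fs, T = 100.0, 18000
spec = NetworkSpec(input_shape=(1, T))
spec.add("conv", Conv1D(1, 25))
spec.add("relu", ReLU())
spec.add("gap", GlobalAvgPool())
spec.add("fc", Dense(3))
spec.add("softmax", Softmax())
model = Model(spec, seed=0)
model.params["conv"]["W"][0, 0, :] = np.sin(2 * np.pi * 10 * np.arange(25) / fs)
model.params["fc"]["W"][:] = 0.0
model.params["fc"]["W"][0, 1] = 1.0  # class 1 reads the burst detector

rng = np.random.default_rng(1)
t = np.arange(T) / fs
x = 0.05 * rng.standard_normal((1, T))
burst = (t >= 60) & (t < 70)
x[0, burst] += 3.0 * np.sin(2 * np.pi * 10 * t[burst])

trace = grad_cam_temporal(model, x, target_class=1, fs=fs, smooth_s=1.0)
peak = np.argmax(trace.importance) / fs
inside = trace.importance[burst].mean()
outside = trace.importance[~burst].mean()
print(f"trace length {trace.importance.size} samples "
      f"(one per input sample at {fs:.0f} Hz)")
print(f"attribution peak at {peak:.1f} s; mean importance inside the burst "
      f"is {inside / outside:.0f}x the outside mean")
print("A peak inside 60-70 s shows the attribution localizes the segment "
      "that made the classifier fire.")
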
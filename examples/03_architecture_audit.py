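"""Audit the five classifier architectures: shapes and trainable parameters.

Every architecture is a declarative layer graph; parameter totals are pure
functions of the spec (no instantiation needed) and the key intermediate
shapes of the STFT Network are printed for inspection.
"""

from eegtriage.nn import (
    build_feature_network,
    build_lstm_network,
    build_sfn,
    build_stft_network,
    build_tmn,
)

specs = {
    "Feature Network (100 inputs)": build_feature_network(100),
    "Topographic Map Network": build_tmn(),
    "STFT Network": build_stft_network(),
    "LSTM Network": build_lstm_network(),
    "Sensor Fusion Network": build_sfn(),
}

for name, spec in specs.items():
    total = spec.count_parameters()
    print(f"{name:30s} {spec.n_layers():4d} layers "
          f"{total:>10,d} trainable parameters ({total / 1e6:.2f} M)")

shapes = specs["STFT Network"].audit_shapes()
print("\nSTFT Network intermediates:")
for node in ("stft", "cat_ab", "flat_ab", "conv1d_c", "cat_all", "gap"):
    print(f"  {node:10s} -> {shapes[node]}")
print("\nThe 38-channel transform (129 bins x 559 frames) and the 8320-wide "
      "concatenation are the published checkpoints of this architecture.")
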
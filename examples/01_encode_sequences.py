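"""Encode RNA segments with the seven sequence-derived feature encoders.

Builds a small synthetic benchmark (positives enriched for the RRACH
consensus around the central adenosine), encodes it with every encoder,
and prints the width and range of each feature block.
"""

from m6age import (PseKNCParams, SynthConfig, encode_bpb, encode_ctd,
                   encode_eiip, encode_ncp_nd, encode_nps, encode_pseknc,
                   fit_bpb, fit_npps, encode_npps, fuse_features,
                   generate_dataset)

data = generate_dataset(SynthConfig(n_pos=100, n_neg=100, L=41, seed=1))
print(f"{len(data)} segments of length {data.seq_length}, "
      f"{int(data.labels.sum())} positives\n")

blocks = [
    encode_ctd(data),
    encode_pseknc(data, PseKNCParams(k=3, lam=2, w=0.1)),
    encode_nps(data),
    encode_npps(data, fit_npps(data, k=1)),
    encode_ncp_nd(data),
    encode_eiip(data),
    encode_bpb(data, fit_bpb(data)),
]
for b in blocks:
    print(f"{b.name:10s} {b.n_features:4d} features   "
          f"range [{b.matrix.min():+.3f}, {b.matrix.max():+.3f}]")

fused = fuse_features(blocks)
print(f"\nfused matrix: {fused.n_samples} x {fused.n_features}")
print("first columns:", ", ".join(fused.columns[:4]))
# Each column name is prefixed by its encoder, so any importance score can
# be traced back to the encoder and position that produced it.
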
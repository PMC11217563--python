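# Scaled-down study configuration: 64x64 single-channel phantoms.
image_size: 64
patch_size: 8
channels: 1
embed_dim: 64
depth: 4
heads: 4
mlp_size: 256
epochs: 10
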
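# Channel widths of the 3D Inception / Inception-ResNet networks.
#
# This file records the package's reading of the published architecture
# diagrams, which annotate per-layer output sizes separately for the binary
# and the ternary network.  The widths below reproduce the published
# multi-view Inception1 parameter totals (0.47e5 binary, 1.49e5 ternary)
# at two significant figures:
#
#   stem conv 3x3x3 -> max-pool 2x3x3 -> Inception module
#   -> 1x1x1 conv head -> avg-pool 2x3x3 -> softmax
#
# branch_widths are (w1, w3, w5) for the 1x1x1 / 3x3x3 / 5x5x5 branches.
binary:
  stem_channels: 12
  branch_widths: [10, 20, 24]
  head_channels: 32
ternary:
  stem_channels: 16
  branch_widths: [8, 20, 64]
  head_channels: 64
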
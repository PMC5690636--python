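"""Parameter accounting across the network family.

Prints total parameter counts, the conv:softmax weight ratio R_p and the
filters-per-hidden-channel ratio R_f for the chain nets and the DAG nets,
for the multi-view-one-network strategy and the one-view-one-network
ensembles.  The multi-view Inception1 totals land on 0.47e5 (binary) and
1.49e5 (ternary); note how much smaller the DAG nets are than the chain
nets, whose hidden fully connected layer dominates their counts.
"""

from mvcnn3d import (
    ArchitectureSpec,
    build_network,
    build_one_view_ensemble,
    count_parameters,
)

print(f"{'network':<28}{'task':<9}{'params':>12}{'R_p':>10}{'R_f':>6}")
for family, depth, label in [
    ("softmax", 0, "Softmax"),
    ("chain", 1, "CNN1"),
    ("chain", 2, "CNN2"),
    ("chain", 3, "CNN3"),
    ("inception1", 0, "Inception1"),
    ("inception2", 0, "Inception2"),
    ("inception_resnet", 0, "Inception-ResNet"),
]:
    for n_classes, task in [(2, "binary"), (3, "ternary")]:
        spec = ArchitectureSpec(family=family, depth_m=depth, n_classes=n_classes)
        rep = count_parameters(build_network(spec))
        print(f"{label:<28}{task:<9}{rep.total_params:>12,}"
              f"{rep.r_p:>9.1f}:1{rep.r_f:>5}:1")

print("\none-view-one-network ensembles (Inception1, binary):")
spec = ArchitectureSpec(family="inception1", n_classes=2)
for reduced, label in [(False, "variant 1 (same widths)"),
                       (True, "variant 2 (reduced widths)")]:
    rep = count_parameters(build_one_view_ensemble(spec, reduced_channels=reduced))
    print(f"  {label:<28}{rep.total_params:>12,}   R_f {rep.r_f}:1")
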
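"""Trace the LdcNet architecture layer by layer before building it.

The network is declared as a spec (blocks, filters, kernels, padding) and
the exact output shape of every layer is computed symbolically, so an
impossible configuration fails loudly before any weights are allocated.
"""

from ldcnet import NetworkSpec, default_spec, parameter_count, shape_trace

spec = default_spec()  # 64 px input, 3 blocks: the reference 15-layer net
print("reference LdcNet at 64 px input:")
print(f"{'#':>3} {'type':<8} output")
for index, kind, dims in shape_trace(spec):
    print(f"{index:>3} {kind:<8} {' x '.join(str(d) for d in dims)}")
print(f"\ntrainable parameters: {parameter_count(spec):,}")

# the same arithmetic adapts to other input scales and depths
for side in (58, 32):
    trace = shape_trace(default_spec(input_side=side))
    pools = [dims for _, kind, dims in trace if kind == "pool"]
    print(f"\ninput {side} px -> pooled feature maps {pools}")

print("\nA 4-block variant appends a padded 512-filter block:")
trace4 = shape_trace(default_spec(n_blocks=4))
print(f"  final feature map {trace4[-4][2]}, "
      f"parameters {parameter_count(default_spec(n_blocks=4)):,}")
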
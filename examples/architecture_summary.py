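"""Build the reference network and print its parameter accounting.

The reference architecture factorizes every 3D convolution into three
asymmetric stages (N×1×1, 1×N×1, 1×1×N), which is what keeps the whole
8-block network at ~231k parameters.  The printed per-block arithmetic
shows where every parameter lives; the two bottom-line counts are the
numbers to compare against any independent build of the same design.
"""

from braincam.model import build_model, count_parameters, reference_config

config = reference_config(input_shape=(91, 109, 91), use_covariates=True)
net = build_model(config, seed=0)

print("block  extent  channels      conv weights  biases  BN(train)  BN(stats)")
total_blocks = 0
for i, b in enumerate(config.blocks, start=1):
    n, cin, cout = b.kernel_extent, b.in_channels, b.out_channels
    w = n * cin * cout + 2 * n * cout * cout
    biases = 3 * cout
    bn_t, bn_s = 2 * cout, 2 * cout
    total_blocks += w + biases + bn_t
    pool = " + pool" if b.followed_by_pool else ""
    print(f"{i:>5}  {n:>6}  {cin:>4} → {cout:<4}  {w:>12}  {biases:>6}  {bn_t:>9}  {bn_s:>9}{pool}")

hidden = (128 + config.n_covariates) * config.hidden_units + config.hidden_units
output = config.hidden_units + 1
print(f"\nconvolutional blocks (trainable): {total_blocks}")
print(f"hidden stage ({128 + config.n_covariates}→{config.hidden_units}): {hidden}")
print(f"output stage ({config.hidden_units}→1): {output}")

total, trainable = count_parameters(net)
print(f"\ntotal parameters:     {total}")
print(f"trainable parameters: {trainable}")
print(f"running statistics:   {total - trainable}  (2 × {sum(b.out_channels for b in config.blocks)} channels)")
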
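"""Build a local-entropy map of a synthetic liver CT and print its scale.

The map assigns each voxel the Shannon entropy (nats) of the integer-HU
values in its 5x5x5 neighborhood: ~ln(125) = 4.83 nats is the ceiling,
reached only when all 125 neighbors differ.
"""

import numpy as np

from lemap import KernelConfig, PhantomSpec, generate_phantom, local_entropy_map, smooth_map

phantom = generate_phantom(PhantomSpec(pattern="homogeneous", seed=1))
raw = local_entropy_map(phantom.ct, KernelConfig(k=5))
smoothed = smooth_map(raw, sigma=1.0)

liver_mean = smoothed.data[phantom.liver.data].mean()
tumor_mean = smoothed.data[phantom.tumor.data].mean()
print(f"kernel bound ln(125)      : {raw.kernel.max_entropy:.4f} nats")
print(f"liver parenchyma entropy  : {liver_mean:.4f} nats")
print(f"tumor entropy             : {tumor_mean:.4f} nats")
print(f"tumor/liver ratio         : {tumor_mean / liver_mean:.4f}")
# The heterogeneous lesion (texture SD 35 HU vs liver 10 HU) spreads its
# kernels over more distinct HU symbols, so its local entropy is higher —
# the contrast the map is designed to display.
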
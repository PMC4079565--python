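"""Find and certify the conserved pools of a three-reaction enzyme toy network.

The network E + S <-> ES -> E + P conserves two moieties: the enzyme mass
(E + ES) and the substrate backbone (S + ES + P).  The pipeline finds both,
and the kernel-dimension bound certifies that no further independent pool
exists.
"""

from moietypools import PipelineConfig, find_all_mcls, format_pool, left_kernel
from moietypools.fixtures import toy_enzyme_network

model = toy_enzyme_network()
kern = left_kernel(model)
print(f"left-kernel dimension (max independent pools): {kern.dim}")

basis, certificate = find_all_mcls(model, PipelineConfig(seed=0))
for i, pool in enumerate(basis, 1):
    print(f"pool {i} (size {pool.size}): {format_pool(pool.coeffs_dict)}")
print(f"certificate: {certificate.status}")
# 'saturated_bound' means the basis size equals the kernel dimension, so the
# two pools generate every conservation law of this network.
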
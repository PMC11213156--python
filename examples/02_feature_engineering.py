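"""From IC time courses to an sFNC vector, and genotype calls to dosages.

The fMRI channel of the framework is the Pearson correlation matrix
between independent-component time courses, upper triangle vectorized;
with the study's 53 components this yields 1378 features. SNP genotypes
become minor-allele dosages in {0, 1, 2}.
"""

import numpy as np

from neurofuse.features import (
    compute_sfnc,
    devectorize,
    encode_dosage,
    vectorize_upper_triangle,
)

rng = np.random.default_rng(0)
timecourses = rng.normal(size=(53, 200))  # 53 components, 200 timepoints
sfnc = compute_sfnc(timecourses)
vec = vectorize_upper_triangle(sfnc)
print(f"sFNC matrix {sfnc.shape} -> vector of {vec.values.size} features")
print(f"  round-trip exact: {np.allclose(devectorize(vec), sfnc)}")
print(f"  off-diagonal range [{vec.values.min():.3f}, {vec.values.max():.3f}] (null data)")

calls = ["A/A", "A/G", "G/G", "G/A"]
dosage = encode_dosage(calls, wild="A", mutant="G", snp_ids=[f"rs{i}" for i in range(4)])
print(f"genotype calls {calls} -> dosages {dosage.values.tolist()}")
print("  -> 0 = wild homozygous, 1 = heterozygous (order-insensitive), 2 = mutant homozygous")
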
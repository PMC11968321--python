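"""Privacy-preserving visualization payloads.

k-NN centroid replacement shares each plotted point among its neighbourhood;
Gaussian noise addition perturbs values by a custodian-bounded variance
fraction.  Both refuse parameters laxer than the custodian minimums.
"""

import numpy as np

from fedshield.errors import FedShieldError
from fedshield.obfuscation import gaussian_noise_obfuscate, knn_centroid_obfuscate
from fedshield.settings import default_settings

s = default_settings()
rng = np.random.default_rng(4)
age = rng.normal(50, 10, 200)
bmi = 20 + 0.1 * age + rng.normal(0, 3, 200)
points = np.column_stack([age, bmi])

obf = knn_centroid_obfuscate(points, k=5, s=s)
print(f"knn k=5: first original point {points[0].round(2)} -> centroid {obf.coords[0].round(2)}")
shared = len(np.unique(obf.coords.round(9), axis=0))
print(f"  200 points map onto {shared} distinct centroids (information is pooled locally)")

try:
    knn_centroid_obfuscate(points, k=2, s=s)
except FedShieldError as err:
    print(f"k=2 refused: {err.code} ({err})")

noised = gaussian_noise_obfuscate(bmi, noise_fraction=0.25, seed=123, s=s)
ratio = np.var(noised.coords[:, 0] - bmi, ddof=1) / np.var(bmi, ddof=1)
print(f"\nnoise fraction 0.25: realized added-noise variance = {ratio:.3f} x var(bmi)")

try:
    gaussian_noise_obfuscate(bmi, noise_fraction=0.1, seed=123, s=s)
except FedShieldError as err:
    print(f"fraction 0.1 refused: {err.code} ({err})")
# The noise floor exists because weak noise can be averaged away over
# repeated requests; the custodian minimum keeps every released view blurred.
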
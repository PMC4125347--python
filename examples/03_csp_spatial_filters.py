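"""Two-class CSP on a pair of covariance matrices, spelled out.

CSP simultaneously diagonalizes two class covariances S_a and S_b with
W S_a W' = D_a, W S_b W' = D_b and D_a + D_b = I.  Components with
D_a eigenvalue near 1 carry variance almost exclusively under class A;
near 0, under class B.  The columns of W^{-1} (the spatial patterns) say
which channels each component lives on.
"""

import numpy as np

from emgpick import csp, pick_channels_from_pattern

# Commuting diagonal toy problem with a closed form: lam_i = a_i / (a_i + b_i)
sigma_a = np.diag([4.0, 1.0, 1.0])
sigma_b = np.diag([1.0, 1.0, 4.0])
fs = csp(sigma_a, sigma_b)
print("eigenvalues D_a:", np.round(fs.eig_target, 4))  # 0.8, 0.5, 0.2
print("eigenvalues sum to one:", np.allclose(fs.eig_target + fs.eig_other, 1.0))

WA = fs.filters @ sigma_a @ fs.filters.T
print("W S_a W' diagonal:", np.round(np.diag(WA), 4))

first, last = pick_channels_from_pattern(fs)
print(f"first pattern -> channel {first} (max variance for class A)")
print(f"last pattern  -> channel {last} (max variance for class B)")
# The picked channels are the axes of the largest/smallest eigenvalues:
# channel 0 discriminates for class A, channel 2 for class B.
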
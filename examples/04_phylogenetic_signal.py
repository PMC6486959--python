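"""Phylogenetic signal: Blomberg's K and Pagel's lambda.

K = 1 is the Brownian-motion expectation; K < 1 means relatives resemble
each other less than BM predicts. lambda scales the off-diagonal
phylogenetic covariance (0 = no signal, 1 = BM); it is tested against
lambda = 0 with a likelihood-ratio test.
"""

import floralevo as fe

tree = fe.sim_tree(32, seed=3)
df, _ = fe.sim_bm_traits(tree, {"tube_length": 1.0}, {"tube_length": 4.0}, seed=4)
x = df.set_index("species")["tube_length"]

k = fe.blomberg_k(tree, x, n_permutations=1000, seed=5)
lam = fe.pagel_lambda(tree, x)
print("trait evolved under Brownian motion on the tree:")
print(f"  Blomberg's K = {k.kappa:.3f} (randomization p = {k.k_pvalue:.4f})")
print(f"  Pagel's lambda = {lam.lambda_hat:.3f} (LRT vs 0: p = {lam.lambda_pvalue:.2e})")

import numpy as np
rng = np.random.default_rng(6)
shuffled = dict(zip(x.index, rng.permutation(x.to_numpy())))
k2 = fe.blomberg_k(tree, shuffled, n_permutations=1000, seed=7)
lam2 = fe.pagel_lambda(tree, shuffled)
print("\nsame values shuffled across the tips (signal destroyed):")
print(f"  Blomberg's K = {k2.kappa:.3f} (randomization p = {k2.k_pvalue:.4f})")
print(f"  Pagel's lambda = {lam2.lambda_hat:.3f} (LRT vs 0: p = {lam2.lambda_pvalue:.3f})")
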
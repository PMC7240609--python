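"""Quadrat chi-square tests of complete spatial randomness.

A CSR layout passes the two-sided test; a tightly clustered layout fails
it, and the greedy exclusion helper shows which points drive the failure.
"""

from steppescan import exclusion_helper, generate_sites, quadrat_test

window = (0.0, 0.0, 3000.0, 3000.0)

csr = generate_sites(45, window, pattern="csr", min_sep=150.0, seed=1)
res = quadrat_test(csr[["x", "y"]].to_numpy(), window)
print(f"CSR layout:       chi2 = {res.statistic:6.2f}, df = {res.df}, p = {res.p:.4f}")

clustered = generate_sites(
    45, window, pattern="clustered", cluster_sd=60.0, n_clusters=5, seed=1
)
res2 = quadrat_test(clustered[["x", "y"]].to_numpy(), window)
print(f"clustered layout: chi2 = {res2.statistic:6.2f}, df = {res2.df}, p = {res2.p:.4f}")

removed, final, ok = exclusion_helper(
    clustered[["x", "y"]].to_numpy(), window, max_remove=8
)
print(
    f"\nexclusion helper removed {len(removed)} points -> "
    f"chi2 = {final.statistic:.2f}, p = {final.p:.4f}, random = {ok}"
)
print(
    "A p above 0.05 means the counts across the 5x5 quadrats are consistent "
    "with a homogeneous Poisson process; small p flags clustering (upper "
    "tail) or excess regularity (lower tail)."
)
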
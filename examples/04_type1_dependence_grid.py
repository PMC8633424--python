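"""How metacognitive measures depend on type 1 performance.

Runs a small dependency grid (d' from ~0.25 to 4 at three metacognitive
noise levels) and prints the mean of each measure per cell. Look for:
AUROC2 and meta-d' rising with d'; M_diff sloping down; M_ratio flat at 1
for sigma_m = 0 but hump-shaped at intermediate noise.
"""

from metanoise import DependencyGridSpec, run_dependency_grid

spec = DependencyGridSpec(
    sigma_s_grid=(4.0, 1.0, 0.5, 0.33),   # d' ~ 0.25, 1, 2, 3
    sigma_m_grid=(0.0, 0.25, 0.5),
    n_subjects=50,
    n_trials=2000,
    seed=3,
)
grid = run_dependency_grid(spec, measures=("d_prime", "auroc2", "meta_d",
                                           "m_diff", "m_ratio"))
wide = grid.pivot_table(index=["sigma_m", "sigma_s"], columns="measure",
                        values="mean").round(3)
print(wide.sort_index(ascending=[True, False]))
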
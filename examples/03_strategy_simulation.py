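"""One cell of the decision model: simulate both strategies and compare.

At the registry-derived occult-metastasis prevalence (9.2%) and a 0%
not-found rate, 1,000 patients per arm are simulated with the institutional
cost distributions and the arm means compared with Welch's t-test.
"""

import numpy as np

from slnbcost import default_parameters, expected_strategy_cost, simulate_cell

params = default_parameters()  # p_occult = 316/3427, q_notfound = 0
e_slnb, e_snd = expected_strategy_cost(params)
print(f"analytic expectations: SLNB strategy R${e_slnb:,.2f}, "
      f"upfront SND R${e_snd:,.2f}")

cell = simulate_cell(params, seed=1)
print(f"simulated means (n={cell.n_per_arm}/arm): "
      f"SLNB R${cell.mean_slnb:,.2f} (SD {cell.sd_slnb:,.0f}), "
      f"SND R${cell.mean_snd:,.2f} (SD {cell.sd_snd:,.0f})")
print(f"difference R${cell.mean_diff:,.2f}, Welch t = {cell.test_statistic:.1f}, "
      f"p = {cell.p_value:.2e} -> {cell.direction}")
print("\nAt a 9.2% occult-metastasis rate the SLNB-first strategy is about")
print(f"R${cell.mean_diff:,.0f} per patient cheaper, far beyond Monte Carlo noise.")
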
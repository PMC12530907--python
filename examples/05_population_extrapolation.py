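"""Population extrapolation: scale per-patient costs to the registry series.

The registry staging counts (8,802 clinical T1-2 oral cancers; 3,427 with
pathological neck staging; 316 metastatic) give the 9.2% baseline
prevalence.  Expected per-patient strategy costs at that prevalence are
multiplied by the staged population to project total costs and savings.
"""

from slnbcost import (
    DEFAULT_POPULATION,
    default_parameters,
    expected_strategy_cost,
    extrapolate_population,
    occult_prevalence,
    projected_reduction,
)

prev = occult_prevalence(DEFAULT_POPULATION)
print(f"occult-metastasis prevalence: {100 * prev:.1f}% "
      f"({DEFAULT_POPULATION.n_metastatic}/{DEFAULT_POPULATION.n_staged})")

params = default_parameters(p_occult=prev, q_notfound=0.0)
e_slnb, e_snd = expected_strategy_cost(params)
reduction = projected_reduction(e_slnb, e_snd)
print(f"expected per-patient cost: SLNB strategy R${e_slnb:,.2f}, "
      f"upfront SND R${e_snd:,.2f} ({reduction:.2f}% reduction)")

proj = extrapolate_population(DEFAULT_POPULATION, e_slnb, e_snd, scope="staged_only")
print(f"\nover the {proj.n_patients:,} pathologically staged patients:")
print(f"  total SLNB strategy  R${proj.total_slnb_strategy / 1e6:8.2f} M")
print(f"  total upfront SND    R${proj.total_snd_strategy / 1e6:8.2f} M")
print(f"  projected savings    R${proj.savings_absolute / 1e6:8.2f} M "
      f"({proj.savings_percent:.2f}%)")
print("\nSavings scale linearly with the population; the all-cT12 scope")
print("assumes the staged-subset prevalence transports to all 8,802 patients.")
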
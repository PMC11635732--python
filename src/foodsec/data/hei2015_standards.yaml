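# HEI-2015 scoring standards (13 components, total 100 points).
#
# kind:
#   density        — amount per 1,000 kcal of the pooled intake
#   percent_energy — percent of pooled energy contributed (kcal_per_unit
#                    converts the reported amount to kcal)
#   ratio          — (mufa_g + pufa_g) / sfa_g, unitless
# direction:
#   adequacy   — score rises from 0 at min_standard to max_points at
#                max_standard
#   moderation — score falls from max_points at min_standard to 0 at
#                max_standard
components:
  total_fruits:
    amount_field: f_total_cup
    kind: density
    direction: adequacy
    max_points: 5
    min_standard: 0.0
    max_standard: 0.8      # cup eq / 1,000 kcal
  whole_fruits:
    amount_field: f_whole_cup
    kind: density
    direction: adequacy
    max_points: 5
    min_standard: 0.0
    max_standard: 0.4
  total_vegetables:
    amount_field: v_total_cup
    kind: density
    direction: adequacy
    max_points: 5
    min_standard: 0.0
    max_standard: 1.1
  greens_and_beans:
    amount_field: v_greens_beans_cup
    kind: density
    direction: adequacy
    max_points: 5
    min_standard: 0.0
    max_standard: 0.2
  whole_grains:
    amount_field: g_whole_oz
    kind: density
    direction: adequacy
    max_points: 10
    min_standard: 0.0
    max_standard: 1.5      # oz eq / 1,000 kcal
  dairy:
    amount_field: dairy_cup
    kind: density
    direction: adequacy
    max_points: 10
    min_standard: 0.0
    max_standard: 1.3
  total_protein_foods:
    amount_field: pf_total_oz
    kind: density
    direction: adequacy
    max_points: 5
    min_standard: 0.0
    max_standard: 2.5
  seafood_and_plant_proteins:
    amount_field: pf_seafood_plant_oz
    kind: density
    direction: adequacy
    max_points: 5
    min_standard: 0.0
    max_standard: 0.8
  fatty_acids:
    kind: ratio
    direction: adequacy
    max_points: 10
    min_standard: 1.2      # (MUFA + PUFA) / SFA
    max_standard: 2.5
  refined_grains:
    amount_field: g_refined_oz
    kind: density
    direction: moderation
    max_points: 10
    min_standard: 1.8
    max_standard: 4.3
  sodium:
    amount_field: sodium_g
    kind: density
    direction: moderation
    max_points: 10
    min_standard: 1.1      # g / 1,000 kcal
    max_standard: 2.0
  added_sugars:
    amount_field: add_sugars_tsp
    kind: percent_energy
    direction: moderation
    max_points: 10
    min_standard: 6.5      # % of energy
    max_standard: 26.0
    kcal_per_unit: 16.0    # kcal per teaspoon equivalent
  saturated_fats:
    amount_field: sfa_g
    kind: percent_energy
    direction: moderation
    max_points: 10
    min_standard: 8.0
    max_standard: 16.0
    kcal_per_unit: 9.0     # kcal per gram
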
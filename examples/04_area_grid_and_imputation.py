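"""Aggregate records to the FAO-area grid and fill gaps with random forests.

Cell means weight studies by sample size; missing cells are filled in two
passes — within-category forests for the well-sampled Level 2/3 fishes, then
cross-category forests predicting Level 1 / Level 4 / OSE from the completed
Level 2/3 surfaces.
"""

import seamehg as sm

config = sm.SimulationConfig(n_studies=1500, areas=sm.FAO_AREAS[:4], seed=9)
truth = sm.generate_truth(config)
records = sm.generate_literature_records(truth, config)
kept, _ = sm.apply_filters(records)
std, _ = sm.standardize_records(kept)
std, _ = sm.remove_outliers(std)
conv = sm.convert_records(std, settings=sm.MonteCarloSettings(seed=2))

series, coverage = sm.build_area_series(conv)
print(f"grid: {coverage['observed_cells']} observed / "
      f"{coverage['missing_cells']} missing cells "
      f"({len(series.areas)} areas x 5 categories x {len(series.years)} years)")

filled, report = sm.impute_all(series, sm.ImputationConfig(seed=3))
print("held-out accuracy per category (10% of observed cells):")
for _, row in report.iterrows():
    r2 = f"{row['r2']:.2f}" if row["r2" ] == row["r2"] else "  - "
    print(f"  {row['category']:<8} observed {row['n_observed']:>4} "
          f"imputed {row['n_imputed']:>4}  R2 {r2}")
print("Observed cells are never overwritten; imputed cells are flagged in",
      "the provenance tables.")
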
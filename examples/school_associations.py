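"""Behavior x environment correlations in the geohashes around schools.

The simulator couples each child's after-school place visits to the local
POI density (logistic link, beta_food = 2 by default). The association
analysis joins the suppressed indicator table with the environment table
over 7-digit cells whose centre lies within 1000 m of a school and reports
Pearson r with a Fisher-z 95% CI and a t-test p-value per behavior-
characteristic pair. A positive, significant r for %food-visits x food
density recovers the planted coupling.
"""

from geobehave import PipelineConfig, pipeline, synthetic

cfg = synthetic.SimConfig(seed=11, n_children=120, n_days=7)
city = synthetic.generate_city(cfg)
fixes = synthetic.generate_cohort(cfg, city)

pcfg = PipelineConfig()
table, env, _ = pipeline.explore(fixes, city.pois, pcfg)
report = pipeline.explain(table, env, city.schools, pcfg)

cols = ["behavior", "basis", "characteristic", "n", "r", "ci_low", "ci_high", "p"]
ok = report[report["flag"] == ""]
print(ok[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nn = school-proximal cells carrying both values; the %place-visit rows "
      "recover the generator's density coupling (r > 0, small p).")
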
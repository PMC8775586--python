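"""Full pipeline on a synthetic upper-field batch: paired channel tests.

Generates 12 upper-field scenes (UV with stronger silhouette contrast),
runs preprocessing and every per-scene statistic, then the paired sign
tests and the chromatic rank-sum tests, and prints the comparison table.
"""

from mouseview import build_param_table, default_plan, run_comparisons
from mouseview.config import PipelineConfig
from mouseview.pipeline import run_synthetic_study

cfg = PipelineConfig(sigma_list=(5.0, 10.0), acf_offsets=((50, 0), (0, 50)))
stats = run_synthetic_study(12, "up", seed=42, config=cfg, size_px=160)
table = build_param_table(stats)
results = run_comparisons(table, default_plan(cfg.sigma_list, cfg.acf_offsets))

print(f"{'parameter':26s} {'test':8s} {'n':>3s} {'stat':>5s} {'p':>10s}  stars")
for r in results:
    if r.category != "up" or r.n == 0:
        continue
    print(f"{r.parameter:26s} {r.test:8s} {r.n:3d} {r.statistic:5.0f} "
          f"{r.p_value:10.3g}  {r.stars}")
print()
print("For sign tests the statistic is the number of scenes with UV > green:")
print("0/12 on gamma (UV heavier-tailed), 12/12 on the vertical intercept b,")
print("RMS contrast and R(50,0) (UV more power, contrast and correlation) -")
print("the upper-visual-field asymmetry pattern, here by construction.")
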
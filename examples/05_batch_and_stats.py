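"""Batch workflow: synthetic cultivar corpus -> trait table -> statistics.

Generates a 3-"cultivar" fruit corpus (round, oblong, nippled), measures
every image, and runs the per-trait one-way ANOVA and Tukey-Kramer
comparisons, printing which cultivar pairs each trait separates.
"""

import tempfile
from pathlib import Path

import pandas as pd

from organmorph.pipeline import RunConfig, run_batch
from organmorph.stats import stats_tables
from organmorph.synthetic import BACKGROUND_HSB, generate_corpus

with tempfile.TemporaryDirectory() as tmp:
    imgs = Path(tmp) / "imgs"
    generate_corpus(imgs, n_per_group=6, pixels_per_cm=150.0, seed=0)
    cfg = RunConfig(organ="fruit", pixels_per_cm=150.0, hsb=BACKGROUND_HSB)
    table = run_batch(imgs, cfg, output_dir=Path(tmp) / "out")

print(f"trait table: {len(table)} specimens, "
      f"{sum(c not in ('group', 'specimen', 'qc_warnings') for c in table.columns)}"
      " trait columns")
summary, anova, pairs = stats_tables(table)

show = ["ShIdx-A", "Area-A", "NippleIdx-A", "Circ-A"]
print("\nmean +/- SE by cultivar:")
for trait in show:
    sub = summary[summary.trait == trait]
    line = "  ".join(f"{r.group}: {r['mean']:.3f}+/-{r.se:.3f}"
                     for _, r in sub.iterrows())
    print(f"  {trait:<13} {line}")

print("\nANOVA p-values and Tukey-separated pairs:")
for trait in show:
    p = anova.loc[anova.trait == trait, "p"]
    sep = pairs[pairs.trait == trait]
    sep_s = ", ".join(f"{r.group_1}!={r.group_2}" for _, r in sep.iterrows())
    p_s = f"{float(p.iloc[0]):.2e}" if len(p) else "n/a (constant)"
    print(f"  {trait:<13} p = {p_s:<10} {sep_s}")
# Every size/shape trait should separate the oblong cultivar from the round
# ones (p << 0.001); NippleIdx-A separates the nippled cultivar exactly.
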
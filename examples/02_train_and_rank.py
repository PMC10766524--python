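"""Train a small model on synthetic series and rank a held-out series.

Trains the Siamese graph attention network on five synthetic congeneric
series (~3 minutes on one CPU core), then ranks the ligands of a fresh
series zero-shot: a single randomly drawn reference ligand anchors the
pairwise ΔpIC50 predictions to absolute pIC50 values.
"""

import numpy as np

from pairbind import experiments

seed = 0
table = experiments.fixture_table()
print("potential table types:", table.alphabet)

model = experiments.train_small_model(seed, table)

hcomp, hlab, _ = experiments.series_dataset(200 + seed, table)
ligs = [(lid, hcomp[lid], hlab[lid]) for lid in hcomp]
from pairbind.inference import evaluate_zero_shot
metrics = evaluate_zero_shot(model, ligs, n_repeats=10, seed=seed)

print("held-out series, zero-shot (10 reference draws):")
for name, stat in metrics.items():
    print(f"  {name}: {stat['mean']:.3f} ± {stat['sd']:.3f}")
# Spearman rho near 1 means the model recovered the planted substituent
# contributions well enough to rank unseen analogs; rmse_pw is in pIC50
# units (multiply by 1.3588 for kcal/mol).
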
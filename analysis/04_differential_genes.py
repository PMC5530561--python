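"""Differential genes and KO groups: floor filter, Wilcoxon, q-values.

Reports how many planted effect genes were flagged at the q < 0.001
gene threshold and the direction split.
"""

import json

import pandas as pd

from _common import get_run

run = get_run()
run.stage_difftest()

res = pd.read_csv(run.path("diff_genes.tsv"), sep="\t", index_col=0)
truth = json.loads(run.path("truth.json").read_text())
effect = set(truth["effect_features"])
sig = res[res["significant"]]
print(f"{len(sig)} / {len(res)} genes significant at q < 0.001 "
      f"(pi0 = {run.manifest['metrics']['pi0_genes']:.3f})")
print(sig["direction"].value_counts().to_string())
flagged = effect & set(sig.index)
print(f"planted effect genes recovered: {len(flagged)} / {len(effect)}")
if run.path("diff_kos.tsv").exists():
    kos = pd.read_csv(run.path("diff_kos.tsv"), sep="\t", index_col=0)
    print(f"KO groups tested: {len(kos)}, significant at q < 0.005: "
          f"{int(kos['significant'].sum())}")
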
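"""Per-sample gene richness and alpha diversity of the discovery cohort."""

import pandas as pd

from _common import get_run

run = get_run()
run.stage_diversity()

table = pd.read_csv(run.path("diversity.tsv"), sep="\t", index_col=0)
labels = pd.read_csv(run.path("discovery_labels.tsv"), sep="\t", index_col=0)["group"]
summary = table.join(labels).groupby("group").mean()
print(summary.round(3).to_string())
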
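"""Species abundance from the hit table via the unique/multi partition.

Compares the partition estimator against the recorded true read
origins and writes the abundance table.
"""

import pandas as pd
from scipy import stats

from _common import get_run

run = get_run()
run.stage_abundance()

ab = pd.read_csv(run.path("species_abundance.tsv"), sep="\t", index_col=0)
lengths = pd.read_csv(run.path("genome_lengths.tsv"), sep="\t", index_col=0)["length"]
origins = pd.read_csv(run.path("true_origins.tsv"), sep="\t", index_col=0)["genome"]
true_ab = origins.value_counts().reindex(lengths.index, fill_value=0) / lengths
r = stats.pearsonr(ab["abundance"], true_ab).statistic
print(f"{len(ab)} genomes; Pearson(estimate, truth) = {r:.4f}")
print(ab.sort_values("relative", ascending=False).head().to_string())
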
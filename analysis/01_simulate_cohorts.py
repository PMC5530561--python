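"""Generate the synthetic study: references, reads, and two cohorts.

Writes toy genome lengths, a read-pair hit table with recorded true
origins, discovery/validation gene-abundance matrices with planted
cluster structure and effects, a gene match table, and a gene-to-KO
score table under results/run/.
"""

import pandas as pd

from _common import get_run

run = get_run()
run.stage_simulate()

m = pd.read_csv(run.path("discovery_abundance.tsv"), sep="\t", index_col=0)
labels = pd.read_csv(run.path("discovery_labels.tsv"), sep="\t")
print(f"discovery cohort: {m.shape[0]} genes x {m.shape[1]} samples "
      f"({(labels['group'] == 'case').sum()} cases, "
      f"{(labels['group'] == 'control').sum()} controls)")
hits = pd.read_csv(run.path("hits.tsv"), sep="\t")
n_multi = (hits[hits.target_kind == "genome"]
           .groupby("read_id")["target_id"].nunique() > 1).sum()
print(f"hit table: {hits.read_id.nunique()} read pairs, "
      f"{n_multi} multi-mapping")
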
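"""MGS and CAG clustering of the discovery cohort, scored against the
planted cluster membership."""

import json

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from _common import get_run

run = get_run()
run.stage_mgs()
run.stage_cag()

truth = json.loads(run.path("truth.json").read_text())
membership = truth["cluster_membership"]

for name in ("mgs_membership.tsv", "cag_membership.tsv"):
    df = pd.read_csv(run.path(name), sep="\t")
    covered = df[df["gene"].isin(membership)]
    if covered.empty:
        print(f"{name}: no planted genes clustered")
        continue
    ari = adjusted_rand_score([membership[g] for g in covered["gene"]],
                              covered["cluster"])
    sizes = df.groupby("cluster").size().sort_values(ascending=False)
    kinds = df.drop_duplicates("cluster")["kind"].value_counts().to_dict()
    print(f"{name}: {sizes.size} clusters {kinds}, "
          f"ARI vs planted truth = {ari:.3f}")
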
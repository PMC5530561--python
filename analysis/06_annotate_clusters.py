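"""Consensus taxonomy of the MGS/CAG clusters from the match table."""

import pandas as pd

from _common import get_run

run = get_run()
run.stage_annotate()

ann = pd.read_csv(run.path("annotations.tsv"), sep="\t", index_col=0)
annotated = ann[ann["best_label"] != "unknown"]
print(f"{len(annotated)} / {len(ann)} clusters annotated; by best rank:")
print(ann["best_rank"].fillna("unknown").value_counts().to_string())
print(ann[["size", "best_rank", "best_label"]].to_string())
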
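"""Marker panels and ROC curves on discovery and validation cohorts.

Runs the gene-mode (top differential genes, step 5) and cluster-mode
(MGS + CAG profiles, step 1) classifiers and draws their ROC curves to
results/roc_curves.png.
"""

import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from _common import RESULTS, get_run

run = get_run()
run.stage_classify()

auc = json.loads(run.path("auc_summary.json").read_text())
fig, axes = plt.subplots(1, len(auc), figsize=(5 * len(auc), 4.5), squeeze=False)
for ax, (mode, scores) in zip(axes[0], sorted(auc.items())):
    roc = pd.read_csv(run.path(f"roc_{mode}.tsv"), sep="\t")
    panel = pd.read_csv(run.path(f"panel_{mode}.tsv"), sep="\t")
    for cohort, grp in roc.groupby("cohort"):
        ax.plot(grp["fpr"], grp["tpr"],
                label=f"{cohort} (AUC {scores[cohort]:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_title(f"{mode} markers (panel of {len(panel)})")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    print(f"{mode}: panel of {len(panel)}, "
          f"discovery AUC {scores['discovery']:.3f}, "
          f"validation AUC {scores['validation']:.3f}")
fig.tight_layout()
fig.savefig(RESULTS / "roc_curves.png", dpi=120)
print(f"ROC curves written to {RESULTS / 'roc_curves.png'}")
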
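"""Plain-text (TSV/JSON/FASTA) readers and writers.

All coordinates in tabular files are 0-based half-open.  Lineages are
written rank-prefixed (``s__...;sp__...;g__...;o__...``) in match-table
TSVs and expanded to per-rank columns on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .abundance import HIT_COLUMNS
from .taxonomy import RANKS

_RANK_PREFIX = {"strain": "s", "species": "sp", "genus": "g", "order": "o"}


def read_abundance_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_abundance_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="feature")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("group").to_frame().to_csv(path, sep="\t", index_label="sample")


def read_hit_table(path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table {path} missing columns {missing}")
    return hits


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]].astype(float)


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_frame().to_csv(path, sep="\t", index_label="target")


def lineage_string(row) -> str:
    return ";".join(f"{_RANK_PREFIX[r]}__{row.get(r, '') or ''}" for r in RANKS)


def parse_lineage(s: str) -> dict:
    out = dict.fromkeys(RANKS, None)
    for token in str(s).split(";"):
        if "__" not in token:
            continue
        prefix, _, label = token.partition("__")
        for rank, p in _RANK_PREFIX.items():
            if prefix == p:
                out[rank] = label or None
    return out


def read_match_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "lineage" in df.columns:
        ranks = df["lineage"].map(parse_lineage).apply(pd.Series)
        df = pd.concat([df.drop(columns=["lineage"]), ranks], axis=1)
    return df


def write_match_table(mt: pd.DataFrame, path) -> None:
    out = mt.copy()
    out["lineage"] = out.apply(lineage_string, axis=1)
    out[["gene", "lineage", "identity", "coverage"]].to_csv(path, sep="\t", index=False)


def write_truth(truth, path) -> None:
    from dataclasses import asdict

    Path(path).write_text(json.dumps(asdict(truth), indent=1, sort_keys=True))


def write_fasta(references, path, seed: int = 0) -> None:
    """Random sequences of the reference lengths, shared regions copied
    verbatim between genome pairs so alignments would actually multi-map."""
    import numpy as np

    rng = np.random.default_rng(seed)
    seqs = {g: rng.choice(list("ACGT"), size=l) for g, l, _ in references.genomes}
    for sr in references.shared_regions:
        seqs[sr.genome_b][sr.start_b:sr.start_b + sr.length] = \
            seqs[sr.genome_a][sr.start_a:sr.start_a + sr.length]
    with open(path, "w") as fh:
        for (g, _, taxon) in references.genomes:
            fh.write(f">{g} {taxon}\n")
            s = "".join(seqs[g])
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")
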
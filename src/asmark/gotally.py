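"""Gene Ontology term tallying over a supplied gene-to-GO mapping.

Counts distinct candidate-affected genes per GO term within each of
the three namespaces (BP, CC, MF).  This is a pure tally over direct
annotations — no GO-graph ancestor propagation and no enrichment
statistics; annotation provenance is the caller's concern.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, UsageError

ASPECTS = ("BP", "CC", "MF")
GO_MAP_COLUMNS = ["gene_id", "aspect", "term_id", "term_name"]


def read_go_map(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene→GO mapping TSV with columns gene_id, aspect, term_id, term_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GO_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"GO map missing columns: {', '.join(missing)}")
    bad = set(df["aspect"]) - set(ASPECTS)
    if bad:
        raise FormatError(
            f"unknown GO aspect token(s): {', '.join(sorted(bad))} "
            f"(expected one of {', '.join(ASPECTS)})"
        )
    dups = df.duplicated(subset=["gene_id", "term_id"])
    if dups.any():
        df = df[~dups]
    return df.reset_index(drop=True)


@dataclass
class GOTally:
    """Ranked per-aspect term counts over a set of input genes."""

    per_aspect: dict = field(default_factory=dict)  # aspect -> DataFrame
    n_genes: int = 0
    n_unannotated: int = 0

    def write(self, outdir: str | os.PathLike, prefix: str = "go_tally") -> None:
        os.makedirs(outdir, exist_ok=True)
        for aspect, frame in self.per_aspect.items():
            frame.to_csv(
                os.path.join(outdir, f"{prefix}_{aspect}.tsv"), sep="\t", index=False
            )


def tally_go(
    gene_ids: Iterable[str], go_map: pd.DataFrame, top_n: int = 20
) -> GOTally:
    """Count distinct input genes per GO term, ranked within each aspect.

    Terms are sorted by count descending then term_id ascending and
    truncated to ``top_n``.  Genes absent from the mapping are counted
    in the ``n_unannotated`` bucket.
    """
    if top_n < 1:
        raise UsageError("top_n must be >= 1")
    genes = set(gene_ids)
    annotated = set(go_map["gene_id"])
    sub = go_map[go_map["gene_id"].isin(genes)]
    out = GOTally(n_genes=len(genes), n_unannotated=len(genes - annotated))
    for aspect in ASPECTS:
        a = sub[sub["aspect"] == aspect]
        counts = (
            a.groupby(["term_id", "term_name"])["gene_id"]
            .nunique()
            .reset_index(name="count")
            .sort_values(["count", "term_id"], ascending=[False, True])
            .head(top_n)
            .reset_index(drop=True)
        )
        out.per_aspect[aspect] = counts[["term_id", "term_name", "count"]]
    return out
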
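"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts travel as TSV with genes as rows and sample ids as the header;
sample metadata as a two-column TSV (sample, group); gene sets as GMT
(term id, description, then tab-separated gene ids, one term per line).
Everything else is ordinary tidy TSV handled by pandas.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:
    from .enrichment import GeneSetCollection


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample integer count TSV (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata_tsv(path: str | os.PathLike) -> pd.Series:
    """Read sample metadata (columns: sample, group) into a sample->group Series."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(meta.columns):
        raise ValueError("metadata TSV must have columns 'sample' and 'group'")
    return meta.set_index("sample")["group"]


def write_metadata_tsv(groups: pd.Series, path: str | os.PathLike) -> None:
    df = pd.DataFrame({"sample": groups.index, "group": groups.values})
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> "GeneSetCollection":
    """Read a GMT file into a GeneSetCollection.

    The description column is parsed as ``namespace|term name``; a bare
    description with no pipe is kept as the name with namespace ``BP``.
    """
    from .enrichment import GeneSet, GeneSetCollection

    terms = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs >=3 columns): {line[:80]!r}")
            term_id, desc = fields[0], fields[1]
            if "|" in desc:
                namespace, name = desc.split("|", 1)
            else:
                namespace, name = "BP", desc
            genes = frozenset(g for g in fields[2:] if g)
            terms.append(GeneSet(term_id=term_id, name=name, namespace=namespace, genes=genes))
    return GeneSetCollection(terms)


def write_gmt(collection: "GeneSetCollection", path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in collection:
            desc = f"{t.namespace}|{t.name}"
            fh.write("\t".join([t.term_id, desc, *sorted(t.genes)]) + "\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
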
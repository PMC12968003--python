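"""OTU table data model, TSV I/O, compositional transforms, and the core-OTU filter.

The :class:`OtuTable` is the universal input of the pipeline: an integer
count matrix (samples x OTUs) carrying per-OTU taxonomy (phylum required)
and per-sample metadata (restoration group, replicate, kingdom).
Downstream stages consume either raw counts, per-sample relative
abundances, or centered log-ratio (CLR) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Greengenes-style rank prefixes tolerated in lineage strings.
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "d__")


def _clean_rank(token: str) -> str:
    token = token.strip()
    for pre in _RANK_PREFIXES:
        if token.startswith(pre):
            token = token[len(pre):]
            break
    return token.strip()


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, rows = samples, columns = OTUs.
    sample_ids, otu_ids
        Unique identifiers matching the matrix dimensions.
    taxonomy
        Mapping ``otu_id -> {rank: name}``; ``phylum`` is required and may
        be the literal ``"Unclassified"``.
    metadata
        Mapping ``sample_id -> {"group": str, "replicate": int,
        "kingdom": str}``.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, dict[str, str]]
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        n, m = self.counts.shape
        if n != len(self.sample_ids) or m != len(self.otu_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(self.counts < 0):
            r, c = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[r]!r}, "
                f"OTU {self.otu_ids[c]!r}"
            )
        missing_meta = [s for s in self.sample_ids if s not in self.metadata]
        if missing_meta:
            raise ValueError(f"samples missing metadata: {missing_meta}")
        for o in self.otu_ids:
            if o not in self.taxonomy:
                raise ValueError(f"OTU missing taxonomy: {o!r}")
            self.taxonomy[o].setdefault("phylum", "Unclassified")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def phylum(self, otu_id: str) -> str:
        return self.taxonomy[otu_id].get("phylum", "Unclassified")

    def groups(self) -> pd.Series:
        """Per-sample restoration group labels, in sample order."""
        return pd.Series(
            [self.metadata[s].get("group") for s in self.sample_ids],
            index=self.sample_ids, name="group",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, keep: Sequence[str]) -> "OtuTable":
        keep = list(keep)
        idx = [self.sample_ids.index(s) for s in keep]
        return OtuTable(
            counts=self.counts[idx],
            sample_ids=keep,
            otu_ids=list(self.otu_ids),
            taxonomy={o: dict(self.taxonomy[o]) for o in self.otu_ids},
            metadata={s: dict(self.metadata[s]) for s in keep},
        )

    def select_otus(self, keep: Sequence[str]) -> "OtuTable":
        keep = list(keep)
        idx = [self.otu_ids.index(o) for o in keep]
        return OtuTable(
            counts=self.counts[:, idx],
            sample_ids=list(self.sample_ids),
            otu_ids=keep,
            taxonomy={o: dict(self.taxonomy[o]) for o in keep},
            metadata={s: dict(self.metadata[s]) for s in self.sample_ids},
        )


@dataclass
class CompositionMatrix:
    """Real-valued samples x OTUs matrix in relative or CLR coordinates."""

    values: pd.DataFrame
    kind: str  # "relative" | "clr"
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "clr"):
            raise ValueError(f"unknown composition kind: {self.kind!r}")
        sums = self.values.to_numpy().sum(axis=1)
        target = 1.0 if self.kind == "relative" else 0.0
        if not np.allclose(sums, target, atol=1e-9):
            raise ValueError(f"{self.kind} rows must sum to {target}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-delimited lineage into named ranks.

    Greengenes-style ``p__`` prefixes are stripped; empty or missing
    phylum becomes ``"Unclassified"``.
    """
    tokens = [_clean_rank(t) for t in str(lineage).split(";")]
    ranks = {r: t for r, t in zip(RANK_NAMES, tokens) if t}
    ranks.setdefault("phylum", "Unclassified")
    return ranks


def format_lineage(ranks: Mapping[str, str]) -> str:
    return ";".join(ranks.get(r, "") for r in RANK_NAMES).rstrip(";")


def read_otu_table(
    path: str | Path,
    metadata_path: str | Path,
    otus_as_rows: bool = True,
) -> OtuTable:
    """Read an abundance TSV plus a metadata TSV into a validated table.

    The abundance file has OTUs as rows (first column ``#OTU_ID``, last
    column ``taxonomy``) unless ``otus_as_rows=False``; orientation is
    declared, never guessed. Metadata columns: ``sample_id``, ``group``,
    ``replicate``, ``kingdom``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.lstrip("#").strip() for c in raw.columns]
    id_col = raw.columns[0]
    if raw[id_col].duplicated().any():
        dup = raw[id_col][raw[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate OTU id: {dup!r}")
    raw = raw.set_index(id_col)

    tax_col = next((c for c in raw.columns if c.lower() == "taxonomy"), None)
    taxonomy_raw = raw.pop(tax_col) if tax_col is not None else None

    try:
        mat = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric count in abundance table: {exc}") from exc
    if (mat < 0).any().any():
        bad = mat.lt(0)
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(f"negative count at row {r!r}, column {c!r}")

    if otus_as_rows:
        mat = mat.T  # -> samples x OTUs
    if mat.columns.duplicated().any():
        dup = mat.columns[mat.columns.duplicated()][0]
        raise ValueError(f"duplicate OTU id: {dup!r}")
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")

    meta_df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    meta_df.columns = [c.strip() for c in meta_df.columns]
    if "sample_id" not in meta_df.columns:
        raise ValueError("metadata must have a sample_id column")
    meta_df = meta_df.set_index("sample_id")
    missing = [s for s in mat.index if s not in meta_df.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    metadata = {}
    for s in mat.index:
        row = meta_df.loc[s]
        metadata[s] = {
            "group": row.get("group"),
            "replicate": int(row["replicate"]) if "replicate" in row and pd.notna(row.get("replicate")) else None,
            "kingdom": row.get("kingdom"),
        }

    if taxonomy_raw is not None:
        taxonomy = {o: parse_lineage(taxonomy_raw.loc[o]) for o in mat.columns}
    else:
        taxonomy = {o: {"phylum": "Unclassified"} for o in mat.columns}

    return OtuTable(
        counts=mat.to_numpy(),
        sample_ids=list(mat.index),
        otu_ids=list(mat.columns),
        taxonomy=taxonomy,
        metadata=metadata,
    )


def write_otu_table(table: OtuTable, path: str | Path, metadata_path: str | Path) -> None:
    """Write the OTUs-as-rows abundance TSV and the metadata TSV."""
    df = table.to_frame().T
    df.insert(len(df.columns), "taxonomy", [format_lineage(table.taxonomy[o]) for o in df.index])
    df.index.name = "#OTU_ID"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame.from_dict(table.metadata, orient="index")
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def relative_abundance(table: OtuTable) -> CompositionMatrix:
    """Divide each sample's counts by its total."""
    totals = table.counts.sum(axis=1).astype(float)
    if np.any(totals <= 0):
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample with zero total count: {bad!r}")
    vals = table.counts / totals[:, None]
    return CompositionMatrix(
        values=pd.DataFrame(vals, index=table.sample_ids, columns=table.otu_ids),
        kind="relative",
    )


def clr_transform(table: OtuTable, pseudocount: float = 1.0) -> CompositionMatrix:
    """Centered log-ratio transform on pseudocounted counts.

    Per sample: ``clr_i = ln(x_i + c) - mean_j ln(x_j + c)``. Rows sum
    to zero, mapping compositions into unconstrained Euclidean space
    where distances are Aitchison distances.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log(table.counts.astype(float) + pseudocount)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return CompositionMatrix(
        values=pd.DataFrame(clr, index=table.sample_ids, columns=table.otu_ids),
        kind="clr",
        pseudocount=pseudocount,
    )


def filter_core_otus(
    table: OtuTable,
    prevalence_min: float = 0.5,
    mean_relabund_min: float = 1e-4,
) -> OtuTable:
    """Keep OTUs present in > ``prevalence_min`` of samples AND with mean
    relative abundance > ``mean_relabund_min`` (both strictly greater).

    Defaults are the standard core-community filter: >50% prevalence and
    >0.01% mean relative abundance. May return a table with zero OTUs.
    """
    for name, v in (("prevalence_min", prevalence_min), ("mean_relabund_min", mean_relabund_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    prevalence = (table.counts > 0).mean(axis=0)
    mean_rel = relative_abundance(table).values.to_numpy().mean(axis=0)
    keep_mask = (prevalence > prevalence_min) & (mean_rel > mean_relabund_min)
    keep = [o for o, k in zip(table.otu_ids, keep_mask) if k]
    return table.select_otus(keep)


def aggregate_phylum(table: OtuTable, others_threshold: float = 0.01) -> pd.DataFrame:
    """Sum relative abundances per phylum; lump rare phyla into "Others".

    Phyla whose grand-mean relative abundance is below ``others_threshold``
    are merged. Returns a phylum x sample table whose columns sum to 1.
    """
    rel = relative_abundance(table).values
    phyla = pd.Index([table.phylum(o) for o in table.otu_ids], name="phylum")
    by_phylum = rel.T.groupby(phyla).sum()  # phylum x sample
    grand_mean = by_phylum.mean(axis=1)
    minor = grand_mean[grand_mean < others_threshold].index
    if len(minor):
        others = by_phylum.loc[minor].sum(axis=0)
        by_phylum = by_phylum.drop(index=minor)
        by_phylum.loc["Others"] = others
    return by_phylum
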
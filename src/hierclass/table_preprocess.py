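"""Expression-table (RNA-seq count) preprocessing.

Normalization shares the median-fold-change step with the spectral pipeline,
followed here by a log2(1 + x) variance stabilizing transform.  Filtering
applies the sample-hygiene rules typical of multi-cohort expression studies:
drop dubiously annotated genes and normal-tissue samples, keep one random
(seeded) sample per patient, and drop subtype groups smaller than a minimum
size (default 15) so every terminal class supports cross-validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ms_preprocess import mfc_normalize


@dataclass
class AnnotatedTable:
    """Counts plus sample metadata.

    ``counts``: samples x genes, non-negative.
    ``meta``: indexed by sample id with columns ``patient_id``,
    ``tissue_status`` ("tumor"/"normal"), ``type``, ``subtype``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.counts.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.counts.index]
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        required = {"patient_id", "tissue_status", "type", "subtype"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")

    def lineages(self) -> dict[str, tuple[str, str]]:
        return {
            sid: (str(row["type"]), str(row["subtype"]))
            for sid, row in self.meta.iterrows()
        }


def normalize_log2(table: AnnotatedTable) -> AnnotatedTable:
    """Median-fold-change normalization then log2(1 + x)."""
    normed, _ = mfc_normalize(table.counts.values)
    out = pd.DataFrame(
        np.log2(1.0 + normed), index=table.counts.index, columns=table.counts.columns
    )
    return AnnotatedTable(out, table.meta.copy())


def filter_samples(
    table: AnnotatedTable,
    min_subtype_n: int = 15,
    seed: int = 0,
    dubious_gene_pattern: str | None = r"^\?",
) -> AnnotatedTable:
    """Apply the sample/gene hygiene filters, in a fixed order.

    1. drop genes matching ``dubious_gene_pattern`` and normal-tissue samples;
    2. keep one random (seeded) sample per patient;
    3. drop subtypes with fewer than ``min_subtype_n`` samples.

    Idempotent: a second application changes nothing.
    """
    counts, meta = table.counts, table.meta
    if dubious_gene_pattern:
        rx = re.compile(dubious_gene_pattern)
        keep_genes = [g for g in counts.columns if not rx.search(str(g))]
        counts = counts[keep_genes]
    tumor = meta["tissue_status"].astype(str).str.lower() != "normal"
    counts, meta = counts.loc[tumor.values], meta.loc[tumor.values]

    rng = np.random.default_rng(seed)
    keep_ids = []
    for _, grp in meta.groupby("patient_id", sort=True):
        ids = sorted(grp.index.tolist())
        keep_ids.append(ids[int(rng.integers(len(ids)))])
    keep_ids = [s for s in meta.index if s in set(keep_ids)]  # original order
    counts, meta = counts.loc[keep_ids], meta.loc[keep_ids]

    sizes = meta.groupby(["type", "subtype"]).size()
    ok = sizes[sizes >= min_subtype_n].index
    mask = meta.set_index(["type", "subtype"]).index.isin(ok)
    counts, meta = counts.loc[mask], meta.loc[mask]
    if counts.shape[0] == 0:
        raise ValueError("filtering removed every sample")
    return AnnotatedTable(counts, meta)


def read_annotated_table(counts_path, meta_path) -> AnnotatedTable:
    """Counts CSV/TSV (samples in rows) + metadata TSV keyed by sample_id."""
    sep_c = "\t" if str(counts_path).endswith((".tsv", ".txt")) else ","
    counts = pd.read_csv(counts_path, sep=sep_c, index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return AnnotatedTable(counts, meta.loc[counts.index])
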
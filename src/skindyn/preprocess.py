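"""Table-level filters and abundance transforms.

Filter order used by the pipeline: contaminant removal -> minimum total
reads -> minimum prevalence.  Each step is taxon-wise, so the filters
commute with sample subsetting of their own input.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_io import CountTable, TaxonomyTable

__all__ = [
    "RelAbundanceTable",
    "remove_contaminants",
    "filter_taxa",
    "to_relative_abundance",
    "collapse_to_genus",
    "top_genera",
]

logger = logging.getLogger(__name__)


class RelAbundanceTable:
    """Real-valued proportions per sample; each column sums to 1."""

    def __init__(self, taxa: list[str], samples: list[str], fractions: np.ndarray):
        fractions = np.asarray(fractions, dtype=float)
        if fractions.shape != (len(taxa), len(samples)):
            raise ValueError("fraction matrix shape does not match labels")
        sums = fractions.sum(axis=0)
        if fractions.size and np.abs(sums - 1.0).max() > 1e-9:
            bad = samples[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValueError(f"sample {bad!r} proportions do not sum to 1")
        self.taxa = list(taxa)
        self.samples = list(samples)
        self.fractions = fractions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.taxa, columns=self.samples)


def remove_contaminants(counts: CountTable, controls: CountTable,
                        threshold: float = 0.05, pooled: bool = False):
    """Drop taxa that average more than ``threshold`` of reads in negative
    controls.

    The rule is strictly "greater than": a taxon whose mean control relative
    abundance equals the threshold exactly is retained.  Default averages
    per-control relative abundances; ``pooled=True`` instead pools reads
    across controls before computing one relative abundance.

    Returns ``(filtered_counts, removed_taxon_ids)``.
    """
    if controls.n_samples == 0:
        raise ValueError("no negative-control samples provided")
    ctrl_sums = controls.sample_sums()
    if (ctrl_sums == 0).any():
        bad = controls.samples[int(np.argmax(ctrl_sums == 0))]
        raise ValueError(f"zero-read control sample {bad!r}")
    if pooled:
        mean_ra = controls.taxon_sums() / ctrl_sums.sum()
    else:
        mean_ra = (controls.counts / ctrl_sums).mean(axis=1)
    ra = dict(zip(controls.taxa, mean_ra))
    removed = [t for t in counts.taxa if ra.get(t, 0.0) > threshold]
    keep = [t for t in counts.taxa if t not in set(removed)]
    logger.info("contaminant rule (>%g): removed %d taxa", threshold, len(removed))
    return counts.select_taxa(keep), removed


def filter_taxa(counts: CountTable, min_total_reads: int = 0,
                min_prevalence_fraction: float = 0.0) -> CountTable:
    """Keep taxa with total reads >= ``min_total_reads`` AND prevalence
    (fraction of samples with count > 0) >= ``min_prevalence_fraction``."""
    if min_total_reads < 0 or min_prevalence_fraction < 0:
        raise ValueError("thresholds must be >= 0")
    totals = counts.taxon_sums()
    prevalence = (counts.counts > 0).mean(axis=1) if counts.n_samples else \
        np.zeros(counts.n_taxa)
    keep_mask = (totals >= min_total_reads) & (prevalence >= min_prevalence_fraction)
    keep = [t for t, k in zip(counts.taxa, keep_mask) if k]
    return counts.select_taxa(keep)


def to_relative_abundance(counts: CountTable) -> RelAbundanceTable:
    """Column-normalize counts to proportions; zero-read samples are an error."""
    sums = counts.sample_sums()
    if (sums == 0).any():
        bad = counts.samples[int(np.argmax(sums == 0))]
        raise ValueError(f"zero-read sample {bad!r}")
    return RelAbundanceTable(counts.taxa, counts.samples, counts.counts / sums)


def collapse_to_genus(table: RelAbundanceTable,
                      taxonomy: TaxonomyTable) -> RelAbundanceTable:
    """Sum rows within genus; unclassified taxa pool into 'unclassified'.

    Genus rows are ordered by decreasing grand-mean relative abundance
    (ties by name) so output order is deterministic.
    """
    genera = taxonomy.genus_of(table.taxa)
    df = table.to_frame()
    df.index = pd.Index(genera, name="genus")
    collapsed = df.groupby(level=0, sort=False).sum()
    order = (
        collapsed.mean(axis=1)
        .to_frame("m")
        .assign(name=lambda d: d.index)
        .sort_values(["m", "name"], ascending=[False, True])
        .index.tolist()
    )
    collapsed = collapsed.loc[order]
    return RelAbundanceTable(collapsed.index.tolist(), table.samples,
                             collapsed.to_numpy())


def top_genera(genus_table: RelAbundanceTable, threshold: float = 0.01) -> list[str]:
    """Genera whose grand-mean relative abundance across all samples is
    >= ``threshold`` (inclusive)."""
    means = genus_table.fractions.mean(axis=1)
    return [g for g, m in zip(genus_table.taxa, means) if m >= threshold]
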